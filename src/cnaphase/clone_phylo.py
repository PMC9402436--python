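"""Breakpoint-coincidence clonal inference.

Cells are compared through the change points (breakpoints) of their integer
copy-number profiles: two cells sharing many breakpoints at coincident
boundaries are likely clonal relatives.  Dissimilarity between two cells is
the one-sided Fisher exact (hypergeometric upper-tail) p-value for
enrichment of shared boundaries among the N canonical boundaries; cells are
clustered hierarchically on this dissimilarity, and tree nodes are accepted
as clones when their estimated false-discovery rate — relative to a null
built by randomly interchanging change points among cells — does not exceed
a threshold t (default 0.01).

Genome-doubled (polyploid) cells are traced back to their most plausible
diploid precursor by maximal breakpoint sharing.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.stats import hypergeom

from .cn_profiling import IntegerCNProfile, BinScaffold
from .errors import InvalidConfigError

DEFAULT_MIN_DELTA = 1
DEFAULT_TOLERANCE = 1
DEFAULT_CLONE_T = 0.01
DEFAULT_NULL_N_PERM = 500


# ---------------------------------------------------------------------------
# Breakpoint matrix
# ---------------------------------------------------------------------------

@dataclass
class BreakpointMatrix:
    """Cells x canonical-boundary indicator matrix.

    ``boundary_ids`` hold the global bin-boundary index (junction between
    bin b and b+1) of the leftmost representative of each tolerance-merged
    boundary group; chromosome-terminal junctions are excluded from the
    universe.  ``n_boundaries`` (N) is the Fisher-test universe size.
    """

    cell_ids: list[str]
    matrix: np.ndarray          # (n_cells, N) in {0, 1}
    boundary_ids: np.ndarray    # (N,) global boundary indices
    tolerance: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.cell_ids), len(self.boundary_ids)):
            raise InvalidConfigError("breakpoint matrix shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_boundaries(self) -> int:
        return self.matrix.shape[1]

    @property
    def breakpoint_counts(self) -> np.ndarray:
        """Per-cell breakpoint count k_c (row sums)."""
        return self.matrix.sum(axis=1)

    def index_of(self, cell_id: str) -> int:
        return self.cell_ids.index(cell_id)


def _raw_boundaries(states: np.ndarray, internal: np.ndarray,
                    min_delta: int) -> np.ndarray:
    diffs = np.abs(np.diff(states.astype(np.int64)))
    mask = np.zeros(len(states) - 1, dtype=bool)
    mask[internal] = diffs[internal] >= min_delta
    return np.nonzero(mask)[0]


def extract_breakpoints(profiles: list[IntegerCNProfile],
                        scaffold: BinScaffold,
                        min_delta: int = DEFAULT_MIN_DELTA,
                        tolerance: int = DEFAULT_TOLERANCE
                        ) -> BreakpointMatrix:
    """Build the breakpoint indicator matrix over canonical boundaries.

    A boundary is set where the integer state changes by at least
    ``min_delta`` within a chromosome.  Boundaries from different cells
    within ``tolerance`` bins of each other are union-merged into one
    canonical boundary (leftmost representative), so shared events whose
    edges jitter by a bin still register as coincident.
    """
    n_bins = scaffold.n_bins
    for p in profiles:
        if len(p.states) != n_bins:
            raise InvalidConfigError(
                f"cell {p.cell_id}: profile has {len(p.states)} bins, "
                f"scaffold has {n_bins} — mixed scaffolds")
    internal = scaffold.internal_boundaries()
    per_cell = [_raw_boundaries(p.states, internal, min_delta)
                for p in profiles]
    pooled = np.unique(np.concatenate([b for b in per_cell] or
                                      [np.array([], dtype=np.int64)]))
    # chain consecutive boundaries with gap <= tolerance into groups
    groups: list[list[int]] = []
    for b in pooled:
        if groups and b - groups[-1][-1] <= tolerance:
            groups[-1].append(int(b))
        else:
            groups.append([int(b)])
    canonical = np.array([g[0] for g in groups], dtype=np.int64)
    lookup = {b: gi for gi, g in enumerate(groups) for b in g}
    mat = np.zeros((len(profiles), len(groups)), dtype=np.int8)
    for ci, bounds in enumerate(per_cell):
        for b in bounds:
            mat[ci, lookup[int(b)]] = 1
    return BreakpointMatrix(cell_ids=[p.cell_id for p in profiles],
                            matrix=mat, boundary_ids=canonical,
                            tolerance=tolerance)


# ---------------------------------------------------------------------------
# Fisher change-point coincidence dissimilarity
# ---------------------------------------------------------------------------

def fisher_coincidence_p(shared: int, k_a: int, k_b: int, n: int) -> float:
    """One-sided Fisher exact p-value for >= ``shared`` coincident
    boundaries when cells a and b carry k_a and k_b breakpoints among n
    canonical boundaries (hypergeometric upper tail)."""
    return float(hypergeom.sf(shared - 1, n, k_a, k_b))


def pair_dissimilarity(bp: BreakpointMatrix, a: int | str,
                       b: int | str) -> float:
    """Dissimilarity of one cell pair; smaller = more similar."""
    ia = bp.index_of(a) if isinstance(a, str) else a
    ib = bp.index_of(b) if isinstance(b, str) else b
    ka = int(bp.matrix[ia].sum())
    kb = int(bp.matrix[ib].sum())
    if ka == 0 or kb == 0:
        warnings.warn(
            f"cell pair ({bp.cell_ids[ia]}, {bp.cell_ids[ib]}): a cell has "
            "no breakpoints; dissimilarity is 1 (no evidence of relatedness)")
        return 1.0
    shared = int((bp.matrix[ia] & bp.matrix[ib]).sum())
    return fisher_coincidence_p(shared, ka, kb, bp.n_boundaries)


def pairwise_dissimilarity(bp: BreakpointMatrix) -> np.ndarray:
    """Full symmetric matrix of Fisher coincidence p-values (diagonal =
    self-dissimilarity, the minimal value of each row)."""
    return _pairwise_from_matrix(bp.matrix, bp.n_boundaries)


def _pairwise_from_matrix(mat: np.ndarray, n_boundaries: int) -> np.ndarray:
    m = mat.astype(np.int64)
    shared = m @ m.T
    k = m.sum(axis=1)
    d = hypergeom.sf(shared - 1, n_boundaries, k[:, None], k[None, :])
    d = np.asarray(d, dtype=float)
    d[k == 0, :] = 1.0
    d[:, k == 0] = 1.0
    return d


# ---------------------------------------------------------------------------
# Hierarchical tree
# ---------------------------------------------------------------------------

@dataclass
class CloneTree:
    """Dendrogram over cells with (after clone calling) per-node FDR and
    clone labels.

    ``Z`` is a scipy linkage matrix over ``cell_ids`` (sorted
    lexicographically for order-independence); internal node i corresponds
    to row i of Z and id ``n_cells + i``.
    """

    cell_ids: list[str]
    Z: np.ndarray
    linkage_method: str
    node_fdr: np.ndarray | None = None
    node_accepted: np.ndarray | None = None
    clone_labels: dict[str, int] = field(default_factory=dict)
    threshold: float | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def node_members(self, node: int) -> list[int]:
        """Leaf indices under internal node ``node`` (0-based row of Z)."""
        n = self.n_cells
        stack, leaves = [n + node], []
        while stack:
            v = stack.pop()
            if v < n:
                leaves.append(v)
            else:
                row = self.Z[v - n]
                stack.extend([int(row[0]), int(row[1])])
        return sorted(leaves)

    def to_newick(self) -> str:
        """Newick with branch lengths = parent height - child height."""
        n = self.n_cells
        heights = np.concatenate([np.zeros(n), self.Z[:, 2]])

        def rec(v: int, parent_h: float) -> str:
            bl = max(parent_h - heights[v], 0.0)
            if v < n:
                return f"{self.cell_ids[v]}:{bl:.6g}"
            a, b = int(self.Z[v - n, 0]), int(self.Z[v - n, 1])
            h = heights[v]
            return f"({rec(a, h)},{rec(b, h)}):{bl:.6g}"

        root = n + len(self.Z) - 1
        return rec(root, heights[root]) + ";"


#: p-values below this are treated as equally (maximally) similar
_LOG_SCALE_FLOOR = 1e-30


def log_scale_dissimilarity(p: np.ndarray | float) -> np.ndarray | float:
    """Monotone map of Fisher p-values onto a log-magnitude scale in
    [0, 1]: 1 + log10(max(p, 1e-30)) / 30.

    Linkage heights averaged on this scale are geometric means of the
    p-values, the canonical way to combine them; arithmetic averaging of
    raw p-values spanning twenty decades is dominated by the single worst
    pair.
    """
    return 1.0 + np.log10(np.maximum(p, _LOG_SCALE_FLOOR)) / 30.0


def build_tree(d: np.ndarray, cell_ids: list[str],
               linkage: str = "average") -> CloneTree:
    """Agglomerative clustering of the dissimilarity matrix.

    Cells are sorted lexicographically by id before linkage so the result
    is invariant to input order (ties in the many identical Fisher
    p-values then break deterministically).  Node heights are on the log
    scale of ``log_scale_dissimilarity`` (average linkage is then a
    geometric mean of p-values).
    """
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise InvalidConfigError("dissimilarity matrix must be symmetric")
    if len(cell_ids) != d.shape[0]:
        raise InvalidConfigError("cell_ids length != matrix size")
    order = np.argsort(np.asarray(cell_ids, dtype=object))
    ids = [cell_ids[i] for i in order]
    ds = log_scale_dissimilarity(d[np.ix_(order, order)])
    if len(ids) == 1:
        return CloneTree(cell_ids=ids, Z=np.empty((0, 4)),
                         linkage_method=linkage)
    iu = np.triu_indices(len(ids), k=1)
    Z = _scipy_linkage(ds[iu], method=linkage)
    return CloneTree(cell_ids=ids, Z=Z, linkage_method=linkage)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Pooled null pairwise dissimilarities from breakpoint interchange."""

    values: np.ndarray      # sorted pooled null p-values
    n_perm: int
    n_pairs_per_perm: int

    def expected_count_below(self, h: float) -> float:
        """Mean per-permutation count of null pair dissimilarities <= h."""
        return float(np.searchsorted(self.values, h, side="right")) / self.n_perm


def _interchange_once(rng: np.random.Generator, tokens: np.ndarray,
                      k_per_cell: np.ndarray) -> list[set[int]]:
    """Deal the pooled multiset of boundary tokens to cells, preserving
    each cell's count; duplicate tokens within a cell are repaired by
    swapping with another cell."""
    toks = tokens[rng.permutation(len(tokens))]
    splits = np.split(toks, np.cumsum(k_per_cell)[:-1])
    cells = [list(c) for c in splits]
    sets = [set(c) for c in cells]
    for i, c in enumerate(cells):
        if len(sets[i]) == len(c):
            continue
        counts = Counter(c)
        dups = [t for t, m in counts.items() for _ in range(m - 1)]
        for t in dups:
            done = False
            for j in rng.permutation(len(cells)):
                if j == i or done:
                    continue
                for idx_u, u in enumerate(cells[j]):
                    if u not in sets[i] and t not in sets[j]:
                        cells[j][idx_u] = t
                        cells[i][cells[i].index(t)] = u
                        sets[j].discard(u)
                        sets[j].add(t)
                        sets[i].add(u)
                        done = True
                        break
            # pathological layouts keep the duplicate; it collapses in the
            # indicator matrix and only perturbs one row sum
    return [set(c) for c in cells]


def permutation_null(bp: BreakpointMatrix,
                     n_perm: int = DEFAULT_NULL_N_PERM,
                     seed: int = 0) -> NullDistribution:
    """Null dissimilarities after random interchange of change points.

    Each permutation reassigns the pooled multiset of breakpoints uniformly
    among cells while preserving every cell's breakpoint count, then all
    pairwise Fisher dissimilarities are recomputed; the pooled sample over
    permutations estimates the no-clonal-structure distribution.
    """
    if n_perm < 1:
        raise InvalidConfigError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    colsums = bp.matrix.sum(axis=0)
    tokens = np.repeat(np.arange(bp.n_boundaries), colsums)
    k = bp.breakpoint_counts.astype(int)
    iu = np.triu_indices(bp.n_cells, k=1)
    pooled = []
    for _ in range(n_perm):
        sets = _interchange_once(rng, tokens, k)
        mat = np.zeros_like(bp.matrix)
        for i, s in enumerate(sets):
            mat[i, list(s)] = 1
        d = _pairwise_from_matrix(mat, bp.n_boundaries)
        pooled.append(d[iu])
    values = np.sort(np.concatenate(pooled))
    return NullDistribution(values=values, n_perm=n_perm,
                            n_pairs_per_perm=len(iu[0]))


# ---------------------------------------------------------------------------
# Clone calling
# ---------------------------------------------------------------------------

#: smallest cell count a tree node needs to be eligible as a clone; pairs
#: of cells are always somewhere near the bottom of the null and would be
#: accepted by selection alone
DEFAULT_MIN_CLONE_CELLS = 3


def call_clones(tree: CloneTree, d: np.ndarray, null: NullDistribution,
                t: float = DEFAULT_CLONE_T,
                min_cells: int = DEFAULT_MIN_CLONE_CELLS) -> CloneTree:
    """Label tree nodes as clones at FDR threshold ``t``.

    For each internal node at height h, the FDR estimate is the expected
    fraction of false pairs among the node's coherent pairs: the null
    per-pair rate of dissimilarities <= h (from the interchange
    permutations), scaled to the node's pair count, divided by the
    observed count of within-node pair dissimilarities <= h, clipped to
    [0, 1].  Clones are the maximal accepted nodes; cells outside every
    accepted node are singletons (label -1).

    ``d`` must be indexed like ``tree.cell_ids`` (the lexicographically
    sorted order used by build_tree) and holds raw Fisher p-values; it and
    the null sample are compared with node heights on the same log scale
    the tree was built on.
    """
    if not (0 < t <= 1):
        raise InvalidConfigError(f"threshold t must lie in (0, 1], got {t}")
    if null.values.size == 0:
        raise InvalidConfigError("null distribution is empty")
    d = log_scale_dissimilarity(np.asarray(d, dtype=float))
    null = NullDistribution(
        values=np.sort(log_scale_dissimilarity(null.values)),
        n_perm=null.n_perm, n_pairs_per_perm=null.n_pairs_per_perm)
    n = tree.n_cells
    n_nodes = len(tree.Z)
    fdr = np.ones(n_nodes)
    accepted = np.zeros(n_nodes, dtype=bool)
    for node in range(n_nodes):
        h = float(tree.Z[node, 2])
        members = tree.node_members(node)
        sub = d[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        observed = int((sub[iu] <= h).sum())
        if observed == 0 or len(members) < min_cells:
            fdr[node] = 1.0
            continue
        null_rate = null.expected_count_below(h) / null.n_pairs_per_perm
        expected_false = null_rate * len(iu[0])
        fdr[node] = min(expected_false / observed, 1.0)
        accepted[node] = fdr[node] <= t

    labels: dict[str, int] = {cid: -1 for cid in tree.cell_ids}
    clone_counter = 0

    def assign(v: int):
        nonlocal clone_counter
        if v < n:
            return
        node = v - n
        if accepted[node]:
            for leaf in tree.node_members(node):
                labels[tree.cell_ids[leaf]] = clone_counter
            clone_counter += 1
            return
        assign(int(tree.Z[node, 0]))
        assign(int(tree.Z[node, 1]))

    if n_nodes:
        assign(n + n_nodes - 1)
    return CloneTree(cell_ids=tree.cell_ids, Z=tree.Z,
                     linkage_method=tree.linkage_method, node_fdr=fdr,
                     node_accepted=accepted, clone_labels=labels, threshold=t)


# ---------------------------------------------------------------------------
# WGD precursor tracing
# ---------------------------------------------------------------------------

def trace_wgd_precursors(profiles: list[IntegerCNProfile],
                         bp: BreakpointMatrix,
                         clone_tree: CloneTree | None = None,
                         t: float = DEFAULT_CLONE_T) -> pd.DataFrame:
    """Match each polyploid cell to the diploid cell sharing the most
    breakpoints (its inferred pre-doubling precursor).

    Returns one row per polyploid cell: the best-matching diploid cell,
    shared breakpoint count, Fisher dissimilarity of the pair, whether the
    link is supported (p <= t), the fraction of the polyploid cell's
    breakpoints inherited from the match, and (when a labelled tree is
    given) the precursor's clone label.
    """
    by_id = {p.cell_id: p for p in profiles}
    diploid = [c for c in bp.cell_ids
               if c in by_id and by_id[c].ploidy_label == "diploid"]
    polyploid = [c for c in bp.cell_ids
                 if c in by_id and by_id[c].ploidy_label == "polyploid"]
    cols = ["polyploid_cell", "precursor_cell", "shared_breakpoints",
            "dissimilarity", "supported", "inherited_fraction",
            "precursor_clone"]
    if not diploid:
        warnings.warn("no diploid cells present; no precursor links")
        return pd.DataFrame(columns=cols)
    labels = clone_tree.clone_labels if clone_tree is not None else {}
    rows = []
    for pc in polyploid:
        ip = bp.index_of(pc)
        kp = int(bp.matrix[ip].sum())
        best = None
        for dc in sorted(diploid):
            idx = bp.index_of(dc)
            kd = int(bp.matrix[idx].sum())
            shared = int((bp.matrix[ip] & bp.matrix[idx]).sum())
            p = (fisher_coincidence_p(shared, kp, kd, bp.n_boundaries)
                 if kp and kd else 1.0)
            key = (-shared, p, dc)
            if best is None or key < best[0]:
                best = (key, dc, shared, p)
        _, dc, shared, p = best
        rows.append({"polyploid_cell": pc, "precursor_cell": dc,
                     "shared_breakpoints": shared, "dissimilarity": p,
                     "supported": bool(shared > 0 and p <= t),
                     "inherited_fraction": shared / kp if kp else 0.0,
                     "precursor_clone": labels.get(dc, -1)})
    return pd.DataFrame(rows, columns=cols)
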