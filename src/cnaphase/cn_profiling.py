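"""Per-cell absolute copy-number calling from sparse-WGS bin counts.

The chain implemented here turns a matrix of per-bin read counts (one column
per cell) into absolute integer copy-number profiles:

    scaffold -> QC -> GC correction (LOWESS) -> circular binary segmentation
             -> quantal (least-squares) ploidy fit -> integer states

Bins are equal-length intervals per chromosome (0-based, half-open), the
coordinate frame shared by every downstream module.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import DegenerateProfileError, InvalidConfigError

# ---------------------------------------------------------------------------
# Chromosome presets (reference assembly sizes in bp)
# ---------------------------------------------------------------------------

#: mm9 chromosome sizes; the mouse scaffold partitions these into 5,000 bins
#: of roughly 600 kb.
MOUSE_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 197195432, "chr2": 181748087, "chr3": 159599783,
    "chr4": 155630120, "chr5": 152537259, "chr6": 149517037,
    "chr7": 152524553, "chr8": 131738871, "chr9": 124076172,
    "chr10": 129993255, "chr11": 121843856, "chr12": 121257530,
    "chr13": 120284312, "chr14": 125194864, "chr15": 103494974,
    "chr16": 98319150, "chr17": 95272651, "chr18": 90772031,
    "chr19": 61342430, "chrX": 166650296,
}

#: hg19 chromosome sizes; the human scaffold uses 20,000 bins.
HUMAN_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

MOUSE_N_BINS = 5000
HUMAN_N_BINS = 20000

DEFAULT_MIN_READS = 250_000
DEFAULT_LOWESS_FRACTION = 0.3
DEFAULT_CBS_ALPHA = 0.01
DEFAULT_CBS_N_PERM = 1000
DEFAULT_MIN_SEG_BINS = 3
#: quantal ploidy grid: multipliers tried when mapping ratios to integers
DEFAULT_Q_GRID = np.round(np.arange(1.5, 6.0 + 1e-9, 0.05), 10)
#: fitted mean copy number at or above which a cell is labelled polyploid
POLYPLOID_PLOIDY_MIN = 3.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScaffold:
    """Ordered genomic bins with GC fraction — the coordinate frame.

    Bins are 0-based half-open, non-overlapping, sorted by (chrom, start),
    equal length within a chromosome to within one base.
    """

    chrom: np.ndarray      # per-bin chromosome name (object dtype)
    start: np.ndarray      # per-bin start (int64)
    end: np.ndarray        # per-bin end, half-open (int64)
    gc: np.ndarray         # per-bin GC fraction in [0, 1]

    def __post_init__(self):
        n = len(self.chrom)
        if not (len(self.start) == len(self.end) == len(self.gc) == n):
            raise InvalidConfigError("scaffold arrays must share one length")
        if np.any(self.gc < 0) or np.any(self.gc > 1):
            raise InvalidConfigError("gc_fraction must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.chrom)

    @property
    def chrom_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_slices(self) -> dict[str, slice]:
        """Bin-index range of each chromosome, in scaffold order."""
        out: dict[str, slice] = {}
        lo = 0
        chroms = self.chrom
        for i in range(1, self.n_bins + 1):
            if i == self.n_bins or chroms[i] != chroms[lo]:
                out[str(chroms[lo])] = slice(lo, i)
                lo = i
        return out

    def chrom_bin_counts(self) -> dict[str, int]:
        return {c: s.stop - s.start for c, s in self.chrom_slices().items()}

    def internal_boundaries(self) -> np.ndarray:
        """Global boundary indices b (junction bin b | bin b+1) that lie
        strictly inside a chromosome.  Chromosome-terminal junctions are
        never part of the breakpoint universe."""
        same = self.chrom[:-1] == self.chrom[1:]
        return np.nonzero(same)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start,
             "end": self.end, "gc": self.gc}
        )


@dataclass
class CellCountProfile:
    """Raw per-bin read counts for one cell."""

    cell_id: str
    counts: np.ndarray
    qc_pass: bool = True
    qc_reason: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise InvalidConfigError(f"negative counts for cell {self.cell_id}")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class RatioProfile:
    """GC-corrected, mean-1 normalized per-bin ratios for one cell."""

    cell_id: str
    ratios: np.ndarray
    lowess_fraction: float


@dataclass
class SegmentedProfile:
    """Piecewise-constant summary of a ratio profile.

    ``seg_chrom``/``seg_start``/``seg_end`` are per-segment (bin indices,
    half-open); ``seg_mean`` is the mean ratio over each segment.
    """

    cell_id: str
    seg_chrom: np.ndarray
    seg_start: np.ndarray
    seg_end: np.ndarray
    seg_mean: np.ndarray
    #: mean over the central portion of each segment (edges trimmed);
    #: boundary-localization errors contaminate segment edges, so the core
    #: mean is the robust location used by the quantal fit
    seg_core_mean: np.ndarray | None = None
    #: standard error of the core mean (ratio units); estimated from the
    #: within-segment scatter by segment_profile, or a nominal small value
    #: for hand-built profiles
    seg_se: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return len(self.seg_mean)

    def lengths(self) -> np.ndarray:
        return (self.seg_end - self.seg_start).astype(np.int64)

    def core_means(self) -> np.ndarray:
        if self.seg_core_mean is not None:
            return self.seg_core_mean
        return self.seg_mean

    def standard_errors(self, nominal_cv: float = 0.02) -> np.ndarray:
        if self.seg_se is not None:
            return self.seg_se
        return nominal_cv * np.maximum(self.core_means(), 0.05) / np.sqrt(
            self.lengths())

    def binwise_means(self) -> np.ndarray:
        """Per-bin segment mean (length = scaffold size)."""
        n = int(self.seg_end[-1])
        out = np.empty(n, dtype=float)
        for s, e, m in zip(self.seg_start, self.seg_end, self.seg_mean):
            out[int(s):int(e)] = m
        return out


@dataclass
class IntegerCNProfile:
    """Absolute integer copy-number states for one cell."""

    cell_id: str
    multiplier: float          # q: ratio -> copies scale
    ploidy: float              # mean integer state across bins
    states: np.ndarray         # per-bin nonnegative integers
    fit_error: float           # weighted residual sum of squares at q
    segments: SegmentedProfile = field(repr=False, default=None)

    @property
    def ploidy_label(self) -> str:
        return "polyploid" if self.ploidy >= POLYPLOID_PLOIDY_MIN else "diploid"


# ---------------------------------------------------------------------------
# Scaffold construction
# ---------------------------------------------------------------------------

def apportion_bins(chrom_lengths: dict[str, int], n_bins: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n_bins`` across chromosomes,
    proportional to length, every chromosome receiving at least one bin."""
    names = list(chrom_lengths)
    if n_bins < len(names):
        raise InvalidConfigError(
            f"n_bins={n_bins} is fewer than {len(names)} chromosomes")
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    if np.any(lengths <= 0):
        raise InvalidConfigError("chromosome lengths must be positive")
    quota = n_bins * lengths / lengths.sum()
    base = np.floor(quota).astype(int)
    base = np.maximum(base, 1)
    # largest remainders get the leftover bins; deficits are taken from the
    # chromosomes whose floor most overshot their quota
    while base.sum() < n_bins:
        frac = quota - base
        base[int(np.argmax(frac))] += 1
    while base.sum() > n_bins:
        frac = quota - base
        candidates = np.where(base > 1)[0]
        base[candidates[int(np.argmin(frac[candidates]))]] -= 1
    return dict(zip(names, (int(b) for b in base)))


def synthetic_gc_curve(n_bins: int) -> np.ndarray:
    """Deterministic smooth GC-fraction track used when no GC table is given.

    Two incommensurate sine components give per-bin values spread over
    roughly 0.34-0.50, enough dynamic range for the LOWESS correction to be
    exercised.
    """
    i = np.arange(n_bins, dtype=float)
    return 0.42 + 0.05 * np.sin(2 * np.pi * i / 137.0) \
               + 0.03 * np.sin(2 * np.pi * i / 29.0)


def build_scaffold(chrom_lengths: dict[str, int], n_bins: int,
                   gc_source: np.ndarray | None = None) -> BinScaffold:
    """Partition a genome into ``n_bins`` equal-length bins per chromosome.

    Per-chromosome bin counts follow largest-remainder apportionment on
    chromosome length; within a chromosome bins are equal to within one
    base.  ``gc_source`` may supply per-bin GC fractions; otherwise a
    deterministic synthetic curve is used.
    """
    counts = apportion_bins(chrom_lengths, n_bins)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for name, k in counts.items():
        length = chrom_lengths[name]
        edges = np.round(np.linspace(0, length, k + 1)).astype(np.int64)
        chroms.extend([name] * k)
        starts.extend(edges[:-1].tolist())
        ends.extend(edges[1:].tolist())
    if gc_source is None:
        gc = synthetic_gc_curve(n_bins)
    else:
        gc = np.asarray(gc_source, dtype=float)
        if len(gc) != n_bins:
            raise InvalidConfigError(
                f"gc_source has {len(gc)} values for {n_bins} bins")
    return BinScaffold(chrom=np.array(chroms, dtype=object),
                       start=np.array(starts, dtype=np.int64),
                       end=np.array(ends, dtype=np.int64),
                       gc=gc)


def mouse_scaffold() -> BinScaffold:
    """Default mouse preset: 5,000 bins of ~600 kb."""
    return build_scaffold(MOUSE_CHROM_LENGTHS, MOUSE_N_BINS)


def human_scaffold() -> BinScaffold:
    """Default human preset: 20,000 bins."""
    return build_scaffold(HUMAN_CHROM_LENGTHS, HUMAN_N_BINS)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(profiles: list[CellCountProfile],
              min_reads: int = DEFAULT_MIN_READS
              ) -> tuple[list[CellCountProfile], list[CellCountProfile]]:
    """Partition cells by the minimum-read-count rule (boundary inclusive:
    ``total_reads >= min_reads`` passes)."""
    if min_reads < 0:
        raise InvalidConfigError("min_reads must be nonnegative")
    kept, excluded = [], []
    for p in profiles:
        if p.total_reads >= min_reads:
            p.qc_pass = True
            kept.append(p)
        else:
            p.qc_pass = False
            p.qc_reason = f"total_reads {p.total_reads} < {min_reads}"
            excluded.append(p)
    return kept, excluded


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

def gc_correct(profile: CellCountProfile, scaffold: BinScaffold,
               lowess_fraction: float = DEFAULT_LOWESS_FRACTION
               ) -> RatioProfile:
    """Divide counts by a LOWESS fit of count against GC fraction, then
    rescale to mean exactly 1.

    The fitted trend is floored at 1e-6 x the mean count so an (unusual)
    nonpositive fit cannot flip ratio signs.
    """
    counts = np.asarray(profile.counts, dtype=float)
    if len(counts) != scaffold.n_bins:
        raise InvalidConfigError(
            f"cell {profile.cell_id}: {len(counts)} counts for "
            f"{scaffold.n_bins} bins")
    mean_count = counts.mean()
    if mean_count <= 0:
        raise DegenerateProfileError(
            f"cell {profile.cell_id}: all-zero counts")
    fitted = _sm_lowess(counts, scaffold.gc, frac=lowess_fraction,
                        return_sorted=False)
    fitted = np.maximum(fitted, 1e-6 * mean_count)
    ratios = counts / fitted
    ratios /= ratios.mean()
    return RatioProfile(cell_id=profile.cell_id, ratios=ratios,
                        lowess_fraction=lowess_fraction)


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------
# The change-point statistic for the circular arc (i, j] within a segment of
# length m is the mean-shift z score
#     Z(i, j) = |S_j - S_i - k/m S_m| / sqrt(k (m - k) / m),   k = j - i,
# whose maximum over all arcs is compared with the same maximum on random
# within-segment permutations of the data (the variance factor cancels in
# the comparison, so none is estimated).  Splitting is recursive; accepted
# arcs contribute both endpoints as change points.

_PERM_BATCH = 50
_EARLY_ACCEPT_MIN = 200
#: second-pass refinement: re-test long segments at this relaxed level
_REFINE_ALPHA = 0.05
_REFINE_MIN_LEN = 30


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Maximal circular mean-shift statistic and its arc (i, j)."""
    m = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    xbar = S[m] / m
    best, bi, bj = -1.0, 0, 0
    for k in range(1, m):
        d = S[k:] - S[:m + 1 - k]          # arc sums, starts i = 0..m-k
        z = np.abs(d - k * xbar) / np.sqrt(k * (m - k) / m)
        idx = int(np.argmax(z))
        if z[idx] > best:
            best, bi, bj = float(z[idx]), idx, idx + k
    return best, bi, bj


def _perm_max_stats(x: np.ndarray, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    """Max arc statistic for ``n`` random permutations of ``x``."""
    m = len(x)
    P = rng.permuted(np.tile(x, (n, 1)), axis=1)
    S = np.concatenate((np.zeros((n, 1)), np.cumsum(P, axis=1)), axis=1)
    xbar = S[:, m] / m
    best = np.zeros(n)
    for k in range(1, m):
        d = S[:, k:] - S[:, :m + 1 - k]
        z = np.abs(d - k * xbar[:, None]) / np.sqrt(k * (m - k) / m)
        np.maximum(best, z.max(axis=1), out=best)
    return best


def _arc_is_significant(x: np.ndarray, obs: float, alpha: float,
                        n_perm: int, rng: np.random.Generator) -> bool:
    """Sequential permutation test with early stopping.

    Stops rejecting as soon as enough permutations exceed the observed
    statistic to make p > alpha certain, and accepts early when none of the
    first ``_EARLY_ACCEPT_MIN`` permutations reach it.
    """
    stop_exceed = int(np.floor(alpha * (n_perm + 1)))  # exceed >= this => p > alpha
    done = exceed = 0
    while done < n_perm:
        b = min(_PERM_BATCH, n_perm - done)
        exceed += int((_perm_max_stats(x, rng, b) >= obs).sum())
        done += b
        if exceed >= stop_exceed:
            return False
        if done >= _EARLY_ACCEPT_MIN and exceed == 0:
            return True
    return (exceed + 1) / (n_perm + 1) <= alpha


def _split_recursive(x: np.ndarray, lo: int, hi: int, alpha: float,
                     n_perm: int, rng: np.random.Generator,
                     out: list[int]) -> None:
    m = hi - lo
    if m < 2:
        return
    seg = x[lo:hi]
    if np.ptp(seg) == 0:
        return
    obs, i, j = _max_arc_stat(seg)
    if not _arc_is_significant(seg, obs, alpha, n_perm, rng):
        return
    cuts = sorted({c for c in (i, j) if 0 < c < m})
    if not cuts:
        return
    pieces = [lo] + [lo + c for c in cuts] + [hi]
    for c in cuts:
        out.append(lo + c)
    for a, b in zip(pieces[:-1], pieces[1:]):
        _split_recursive(x, a, b, alpha, n_perm, rng, out)


def _refine_changepoints(x: np.ndarray, cuts: list[int],
                         window: int = 3) -> list[int]:
    """Nudge each change point to the exact two-segment least-squares
    optimum within +/- ``window`` bins, holding its neighbours fixed."""
    cuts = sorted(cuts)
    for idx, c in enumerate(cuts):
        left = cuts[idx - 1] if idx > 0 else 0
        right = cuts[idx + 1] if idx + 1 < len(cuts) else len(x)
        lo = max(left + 1, c - window)
        hi = min(right - 1, c + window)
        best_p, best_sse = c, np.inf
        for p in range(lo, hi + 1):
            a, b = x[left:p], x[p:right]
            sse = (((a - a.mean()) ** 2).sum() if len(a) else 0.0) \
                + (((b - b.mean()) ** 2).sum() if len(b) else 0.0)
            if sse < best_sse - 1e-12:
                best_p, best_sse = p, sse
        cuts[idx] = best_p
    return sorted(set(cuts))


def _merge_short_segments(x: np.ndarray, cuts: list[int],
                          min_seg_bins: int) -> list[int]:
    """Drop boundaries of segments shorter than ``min_seg_bins``, merging
    each into the neighbour with the nearest mean."""
    while True:
        edges = [0] + sorted(cuts) + [len(x)]
        lengths = np.diff(edges)
        if len(lengths) == 1:
            return sorted(cuts)
        short = [s for s in range(len(lengths)) if lengths[s] < min_seg_bins]
        if not short:
            return sorted(cuts)
        s = min(short, key=lambda t: lengths[t])
        mean_s = x[edges[s]:edges[s + 1]].mean()
        neighbours = []
        if s > 0:
            neighbours.append((abs(mean_s - x[edges[s - 1]:edges[s]].mean()),
                               edges[s]))       # drop left boundary
        if s < len(lengths) - 1:
            neighbours.append((abs(mean_s - x[edges[s + 1]:edges[s + 2]].mean()),
                               edges[s + 1]))   # drop right boundary
        cuts = [c for c in cuts if c != min(neighbours)[1]]


def segment_profile(ratio: RatioProfile, scaffold: BinScaffold,
                    alpha: float = DEFAULT_CBS_ALPHA,
                    n_perm: int = DEFAULT_CBS_N_PERM,
                    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
                    seed: int = 0) -> SegmentedProfile:
    """Circular binary segmentation of a ratio profile, per chromosome.

    Recursively accepts the maximal circular arc when its permutation
    p-value is at most ``alpha`` (``n_perm`` within-segment permutations),
    refines accepted boundaries by local least squares, and merges segments
    shorter than ``min_seg_bins`` into the neighbour of nearest mean.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    seg_chrom, seg_start, seg_end, seg_mean = [], [], [], []
    for name, sl in scaffold.chrom_slices().items():
        x = ratio.ratios[sl]
        cuts: list[int] = []
        _split_recursive(x, 0, len(x), alpha, n_perm, rng, cuts)
        # second pass at a relaxed level inside long segments: a greedy
        # first split placed off a true boundary halves the power of later
        # tests, so borderline change points are re-sought locally where
        # the multiple-comparison burden is smaller
        edges = [0] + sorted(set(cuts)) + [len(x)]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a >= _REFINE_MIN_LEN:
                _split_recursive(x, a, b, _REFINE_ALPHA,
                                 min(n_perm, 300), rng, cuts)
        cuts = _refine_changepoints(x, sorted(set(cuts)))
        cuts = _merge_short_segments(x, cuts, min_seg_bins)
        edges = [0] + cuts + [len(x)]
        for a, b in zip(edges[:-1], edges[1:]):
            seg_chrom.append(name)
            seg_start.append(sl.start + a)
            seg_end.append(sl.start + b)
            seg_mean.append(float(x[a:b].mean()))
    seg_start = np.array(seg_start, dtype=np.int64)
    seg_end = np.array(seg_end, dtype=np.int64)
    seg_mean = np.array(seg_mean, dtype=float)
    # robust global per-bin relative noise estimate
    lengths = seg_end - seg_start
    binwise = np.repeat(seg_mean, lengths)
    rel_resid = (ratio.ratios - binwise) / np.maximum(binwise, 0.1)
    tau = max(1.4826 * float(np.median(np.abs(rel_resid))), 0.01)
    # core (edge-trimmed) mean and SE per segment: boundary-localization
    # errors contaminate segment edges, so location/scale for the quantal
    # fit come from the central third; the SE takes the larger of the
    # empirical core scatter and the global noise model (short segments
    # have unreliable empirical sd; contaminated segments have inflated sd
    # and are correctly downweighted)
    core_mean = np.empty(len(seg_mean))
    seg_se = np.empty(len(seg_mean))
    for k, (s, e) in enumerate(zip(seg_start, seg_end)):
        trim = (e - s) // 3 if e - s >= 6 else 0
        core = ratio.ratios[s + trim:e - trim]
        m = float(core.mean())
        emp_sd = float(core.std(ddof=1)) if len(core) > 1 else 0.0
        core_mean[k] = m
        seg_se[k] = max(emp_sd, tau * max(m, 0.05)) / np.sqrt(len(core))
    return SegmentedProfile(cell_id=ratio.cell_id,
                            seg_chrom=np.array(seg_chrom, dtype=object),
                            seg_start=seg_start, seg_end=seg_end,
                            seg_mean=seg_mean, seg_core_mean=core_mean,
                            seg_se=seg_se)


# ---------------------------------------------------------------------------
# Quantal ploidy fit
# ---------------------------------------------------------------------------

#: smallest-adequate-q slack: accept the smallest grid q whose error is
#: within  a * sqrt(2 max(err_min, n)) + b  of the minimum
_Q_SLACK_SCALE = 1.0
_Q_SLACK_ABS = 5.0
#: cap on a single segment's squared normalized residual (z^2)
_Q_OUTLIER_CAP = 25.0
#: segments with SE above this resolve no integer lattice on the grid and
#: are excluded from the multiplier search (they still receive states)
_Q_INFO_SE_MAX_STATE = 0.35


def ploidy_fit_error(q: float, seg_mean: np.ndarray,
                     seg_se: np.ndarray) -> float:
    """Quantal residual of multiplier ``q`` on segment (core) means.

    Each segment's distance from the nearest integer copy state is
    normalized by the standard error of its mean on the copy scale
    (q x se), capped per segment:

        sum_s min( ((q m_s - round(q m_s)) / max(q se_s, eps))^2 , cap ) .

    The SE normalization makes candidate multipliers comparable: on an
    absolute scale the noise term grows with q^2 and the fit of a doubled
    genome collapses onto its q/2 harmonic, while a purely relative scale
    lets large q win through round-to-nearest capture of noisy segments.
    The cap keeps a single mis-segmented (outlier) segment from vetoing an
    otherwise well-supported multiplier.
    """
    scaled = q * seg_mean
    sigma = np.maximum(q * seg_se, 1e-6)
    resid = (scaled - np.round(scaled)) / sigma
    return float(np.minimum(resid * resid, _Q_OUTLIER_CAP).sum())


def fit_ploidy(seg: SegmentedProfile,
               q_grid: np.ndarray | None = None) -> IntegerCNProfile:
    """Least-squares quantal fit of the ratio-to-copies multiplier q.

    Segments precise enough to resolve the integer lattice are scored with
    the capped, SE-normalized quantal residual over the grid; the residual
    scale is self-calibrated at the best-fitting q (the median absolute
    normalized residual is set to its half-normal expectation, absorbing
    correlated normalization error that survives within-segment
    averaging).  The fit returns the smallest q whose error lies within a
    small slack of the global minimum, so ties break toward smaller q.
    The parsimony direction is forced: a profile explained by states c is
    explained exactly as well by 2c, so the data alone cannot separate q
    from 2q and the smaller multiplier is the defensible choice; a
    genuinely doubled genome carrying odd-state segments rejects q/2
    through their half-integer residuals.  Integer states are the rounded
    scaled segment core means (clipped at zero); ploidy is the mean state
    across bins.
    """
    if q_grid is None:
        q_grid = DEFAULT_Q_GRID
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size == 0:
        raise InvalidConfigError("q_grid is empty")
    if np.any(np.diff(q_grid) <= 0):
        raise InvalidConfigError("q_grid must be strictly increasing")
    means = seg.core_means()
    se = seg.standard_errors()
    informative = se <= _Q_INFO_SE_MAX_STATE / q_grid.max()
    if not informative.any():
        informative = np.ones_like(informative, dtype=bool)
    mm, ss = means[informative], se[informative]
    errors = np.array([ploidy_fit_error(q, mm, ss) for q in q_grid])
    q1 = float(q_grid[int(np.argmin(errors))])
    scaled = q1 * mm
    z = np.abs(scaled - np.round(scaled)) / np.maximum(q1 * ss, 1e-6)
    calibration = max(float(np.median(z)) / 0.674, 1.0)
    ss = ss * calibration
    errors = np.array([ploidy_fit_error(q, mm, ss) for q in q_grid])
    emin = float(errors.min())
    n_info = int(informative.sum())
    cutoff = emin + _Q_SLACK_SCALE * np.sqrt(2.0 * max(emin, n_info)) \
        + _Q_SLACK_ABS
    best = int(np.argmax(errors <= cutoff))    # first adequate -> smallest q
    q = float(q_grid[best])
    per_seg_states = np.maximum(np.round(q * means), 0).astype(np.int64)
    states = np.repeat(per_seg_states, seg.lengths())
    return IntegerCNProfile(cell_id=seg.cell_id, multiplier=q,
                            ploidy=float(states.mean()), states=states,
                            fit_error=float(errors[best]), segments=seg)


# ---------------------------------------------------------------------------
# Batch driver
# ---------------------------------------------------------------------------

def stable_cell_seed(root_seed: int, cell_id: str) -> int:
    """Deterministic per-cell child seed from a root seed and the cell id.

    Stable across sessions (SHA-256, not Python's salted hash) so adding
    cells to a batch never perturbs existing ones.
    """
    h = hashlib.sha256(f"{root_seed}:{cell_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def call_cells(matrix: pd.DataFrame, scaffold: BinScaffold,
               min_reads: int = DEFAULT_MIN_READS,
               lowess_fraction: float = DEFAULT_LOWESS_FRACTION,
               alpha: float = DEFAULT_CBS_ALPHA,
               n_perm: int = DEFAULT_CBS_N_PERM,
               min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
               q_grid: np.ndarray | None = None,
               seed: int = 0,
               ) -> tuple[list[IntegerCNProfile], pd.DataFrame]:
    """Run the full per-cell chain over a bin-count matrix (columns=cells).

    Per-cell failures (QC exclusion, degenerate counts) are recorded in the
    report and never abort the batch.  Returns the successful integer
    profiles and a per-cell report with columns: cell_id, total_reads,
    qc_pass, status, n_segments, multiplier, ploidy, ploidy_label.
    """
    profiles: list[IntegerCNProfile] = []
    rows = []
    for cell_id in matrix.columns:
        counts = matrix[cell_id].to_numpy()
        row = {"cell_id": cell_id, "total_reads": int(counts.sum()),
               "qc_pass": False, "status": "", "n_segments": 0,
               "multiplier": np.nan, "ploidy": np.nan, "ploidy_label": ""}
        try:
            cell = CellCountProfile(cell_id=str(cell_id), counts=counts)
            kept, _ = qc_filter([cell], min_reads=min_reads)
            if not kept:
                row["status"] = cell.qc_reason
                rows.append(row)
                continue
            row["qc_pass"] = True
            ratio = gc_correct(cell, scaffold, lowess_fraction)
            segmented = segment_profile(
                ratio, scaffold, alpha=alpha, n_perm=n_perm,
                min_seg_bins=min_seg_bins,
                seed=stable_cell_seed(seed, str(cell_id)))
            profile = fit_ploidy(segmented, q_grid=q_grid)
            profiles.append(profile)
            row.update(status="ok", n_segments=segmented.n_segments,
                       multiplier=profile.multiplier, ploidy=profile.ploidy,
                       ploidy_label=profile.ploidy_label)
        except DegenerateProfileError as exc:
            row["status"] = f"degenerate: {exc}"
        rows.append(row)
    return profiles, pd.DataFrame(rows)
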