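"""Population-level CNA statistics.

Event classification relative to a ploidy-dependent reference state (2 for
diploid cells, 4 for polyploid cells), CORE-style recurrence scoring,
gain/deletion frequency tracks with the +/-0.1 designation threshold,
per-bin and per-segment (cf/purity) homogeneity scores, event-class
enrichment tests, and small flow-cytometry/genotyping calculators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cn_profiling import BinScaffold, IntegerCNProfile
from .errors import InvalidConfigError

DEFAULT_THETA = 0.1
#: a high-state interval counts as a (focal) amplification rather than a
#: plain gain when its state reaches twice the reference and it spans at
#: most this many bins
AMPLIFICATION_MAX_BINS = 10
#: cf/purity values are clipped here; raw values are kept in a diagnostic
#: column
CF_PURITY_CLIP = 1.25
DEFAULT_CORE_N_PERM = 500
DEFAULT_LOH_RPKM_FRACTION = 0.2

REFERENCE_STATE = {"diploid": 2, "polyploid": 4}


# ---------------------------------------------------------------------------
# Event classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNAEvent:
    """One maximal constant-state interval deviating from the reference."""

    cell_id: str
    chrom: str
    start_bin: int       # global bin index, half-open interval
    end_bin: int
    state: int
    event_class: str     # deletion | gain | amplification
    reference: int       # rho: 2 (diploid) or 4 (polyploid)


def classify_events(profile: IntegerCNProfile, scaffold: BinScaffold,
                    ploidy_label: str | None = None) -> list[CNAEvent]:
    """Cut a profile into CNA events relative to its reference state.

    Maximal runs of bins with a constant state different from rho (2 for
    diploid, 4 for polyploid cells) become events; states below rho are
    deletions, states above are gains, and a gain is promoted to
    amplification when state >= 2 rho and the run spans at most
    ``AMPLIFICATION_MAX_BINS`` bins.
    """
    label = ploidy_label or profile.ploidy_label
    if label not in REFERENCE_STATE:
        raise InvalidConfigError(f"unknown ploidy label {label!r}")
    rho = REFERENCE_STATE[label]
    states = profile.states
    events: list[CNAEvent] = []
    for chrom, sl in scaffold.chrom_slices().items():
        run_start = None
        prev = None
        for i in range(sl.start, sl.stop + 1):
            s = int(states[i]) if i < sl.stop else None
            if run_start is not None and (s != prev or i == sl.stop):
                if prev != rho:
                    span = i - run_start
                    if prev < rho:
                        cls = "deletion"
                    elif prev >= 2 * rho and span <= AMPLIFICATION_MAX_BINS:
                        cls = "amplification"
                    else:
                        cls = "gain"
                    events.append(CNAEvent(
                        cell_id=profile.cell_id, chrom=chrom,
                        start_bin=run_start, end_bin=i, state=prev,
                        event_class=cls, reference=rho))
                run_start = i
                prev = s
            elif run_start is None:
                run_start, prev = i, s
    return events


def events_to_profile(events: list[CNAEvent], n_bins: int,
                      reference: int) -> np.ndarray:
    """Reassemble an integer profile from events plus reference fill (the
    inverse of classify_events for a single cell)."""
    out = np.full(n_bins, reference, dtype=np.int64)
    for ev in events:
        out[ev.start_bin:ev.end_bin] = ev.state
    return out


# ---------------------------------------------------------------------------
# CORE-style recurrence
# ---------------------------------------------------------------------------

def _jaccard(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    union = max(a_end, b_end) - min(a_start, b_start)
    return inter / union


def interval_score(start: int, end: int, chrom: str,
                   events: list[CNAEvent]) -> float:
    """Sum over cells of the best Jaccard overlap between the candidate
    interval and that cell's events (same chromosome)."""
    best_by_cell: dict[str, float] = {}
    for ev in events:
        if ev.chrom != chrom:
            continue
        j = _jaccard(start, end, ev.start_bin, ev.end_bin)
        if j > best_by_cell.get(ev.cell_id, 0.0):
            best_by_cell[ev.cell_id] = j
    return sum(best_by_cell.values())


def _greedy_cores(events: list[CNAEvent], max_cores: int
                  ) -> list[tuple[str, int, int, float]]:
    pool = list(events)
    cores = []
    while pool and len(cores) < max_cores:
        candidates = sorted({(ev.chrom, ev.start_bin, ev.end_bin)
                             for ev in pool})
        scored = [(interval_score(s, e, c, pool), c, s, e)
                  for c, s, e in candidates]
        score, chrom, start, end = max(
            scored, key=lambda r: (r[0], -r[2], r[3]))
        if score <= 0:
            break
        cores.append((chrom, start, end, score))
        # peel off: drop each cell's best-overlapping event with the core
        drop: dict[str, tuple[float, int]] = {}
        for idx, ev in enumerate(pool):
            if ev.chrom != chrom:
                continue
            j = _jaccard(start, end, ev.start_bin, ev.end_bin)
            if j > 0 and (ev.cell_id not in drop or j > drop[ev.cell_id][0]):
                drop[ev.cell_id] = (j, idx)
        to_drop = {idx for _, idx in drop.values()}
        pool = [ev for idx, ev in enumerate(pool) if idx not in to_drop]
    return cores


def core_recurrence(events: list[CNAEvent], scaffold: BinScaffold,
                    event_class: str, n_perm: int = DEFAULT_CORE_N_PERM,
                    seed: int = 0, max_cores: int = 10) -> pd.DataFrame:
    """Greedy cores of recurrent same-class events with permutation p-values.

    The candidate set is the event intervals themselves; each core is the
    interval maximizing the Jaccard-sum score, after which the events it
    explains are removed and the search repeats.  Significance compares
    each core's score with the null distribution of top-core scores after
    relocating every event uniformly within its chromosome (lengths and
    per-cell event counts preserved).
    """
    sel = [ev for ev in events if ev.event_class == event_class]
    cols = ["chrom", "start_bin", "end_bin", "event_class", "score", "p_value"]
    if not sel:
        return pd.DataFrame(columns=cols)
    cores = _greedy_cores(sel, max_cores)
    rng = np.random.default_rng(seed)
    ranges = {c: (sl.start, sl.stop) for c, sl in scaffold.chrom_slices().items()}
    null_top = np.empty(n_perm)
    for i in range(n_perm):
        permuted = []
        for ev in sel:
            lo, hi = ranges[ev.chrom]
            length = ev.end_bin - ev.start_bin
            s = int(rng.integers(lo, hi - length + 1))
            permuted.append(CNAEvent(
                cell_id=ev.cell_id, chrom=ev.chrom, start_bin=s,
                end_bin=s + length, state=ev.state,
                event_class=ev.event_class, reference=ev.reference))
        top = _greedy_cores(permuted, 1)
        null_top[i] = top[0][3] if top else 0.0
    rows = []
    for chrom, start, end, score in cores:
        p = (1 + int((null_top >= score).sum())) / (n_perm + 1)
        rows.append({"chrom": chrom, "start_bin": start, "end_bin": end,
                     "event_class": event_class, "score": score,
                     "p_value": p})
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Frequency track
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTrack:
    """Per-bin gain/deletion designation frequencies across samples."""

    gain_freq: np.ndarray
    del_freq: np.ndarray
    theta: float
    n_samples: int


def frequency_track(segment_values: np.ndarray,
                    theta: float = DEFAULT_THETA) -> FrequencyTrack:
    """Designate gained/deleted bins per sample and count frequencies.

    ``segment_values`` is samples x bins of segmented copy-number values;
    each sample is centred to mean 1, then a bin is gained when its centred
    value >= 1 + theta and deleted when <= 1 - theta (boundary inclusive).
    """
    if theta <= 0:
        raise InvalidConfigError("theta must be positive")
    v = np.atleast_2d(np.asarray(segment_values, dtype=float))
    means = v.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        raise InvalidConfigError("sample mean must be positive for centring")
    centred = v / means
    gained = centred >= 1.0 + theta
    deleted = centred <= 1.0 - theta
    n = v.shape[0]
    return FrequencyTrack(gain_freq=gained.mean(axis=0),
                          del_freq=deleted.mean(axis=0),
                          theta=theta, n_samples=n)


# ---------------------------------------------------------------------------
# Homogeneity
# ---------------------------------------------------------------------------

def bin_homogeneity(states_matrix: np.ndarray) -> np.ndarray:
    """Per-bin frequency of the major (modal) integer copy-number state.

    ``states_matrix`` is cells x bins; h_b = (count of cells carrying the
    modal state at bin b) / n cells, so h_b = 1 means the state is fixed
    in the population and h_b >= 1/n always.
    """
    m = np.atleast_2d(np.asarray(states_matrix))
    if m.shape[0] < 1:
        raise InvalidConfigError("at least one cell required")
    mode = stats.mode(m, axis=0, keepdims=False)
    return mode.count / m.shape[0]


def class_frequency_track(profiles: list[IntegerCNProfile]
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin fraction of cells deleted / gained relative to each cell's
    own reference state (2 or 4 by fitted ploidy label)."""
    dels = np.zeros(len(profiles[0].states))
    gains = np.zeros_like(dels)
    for p in profiles:
        rho = REFERENCE_STATE[p.ploidy_label]
        dels += p.states < rho
        gains += p.states > rho
    return dels / len(profiles), gains / len(profiles)


@dataclass
class HomogeneityReport:
    """cf/purity homogeneity of bulk segments, by event class."""

    table: pd.DataFrame          # per-segment, with cf_purity + raw column
    ks_statistic: float
    ks_p_value: float
    ks_applicable: bool


def segment_homogeneity(segments: pd.DataFrame) -> HomogeneityReport:
    """Normalized clonality (cf/purity) of bulk segments and the
    two-sample Kolmogorov-Smirnov contrast between gains and deletions.

    ``segments`` needs columns cf, purity and event_class (gain/deletion
    labels); cf/purity is clipped at ``CF_PURITY_CLIP`` with the raw value
    kept in ``cf_purity_raw``.  Values near 1 indicate clonal
    (homogeneous) alterations.
    """
    required = {"cf", "purity", "event_class"}
    missing = required - set(segments.columns)
    if missing:
        raise InvalidConfigError(f"segment table lacks columns {sorted(missing)}")
    if np.any(segments["purity"] <= 0):
        raise InvalidConfigError("purity must be positive")
    if np.any(segments["cf"] < 0):
        raise InvalidConfigError("cf must be nonnegative")
    table = segments.copy()
    raw = table["cf"] / table["purity"]
    table["cf_purity_raw"] = raw
    table["cf_purity"] = np.minimum(raw, CF_PURITY_CLIP)
    gains = table.loc[table["event_class"].isin(["gain", "amplification"]),
                      "cf_purity"].to_numpy()
    dels = table.loc[table["event_class"] == "deletion",
                     "cf_purity"].to_numpy()
    if len(gains) and len(dels):
        ks = stats.ks_2samp(gains, dels)
        return HomogeneityReport(table, float(ks.statistic),
                                 float(ks.pvalue), True)
    return HomogeneityReport(table, float("nan"), float("nan"), False)


# ---------------------------------------------------------------------------
# Event-count enrichment tests
# ---------------------------------------------------------------------------

def compare_event_counts(counts: pd.DataFrame, group_col: str = "group",
                         class_cols: tuple[str, ...] = ("deletion", "gain",
                                                        "amplification")
                         ) -> pd.DataFrame:
    """Two-group comparison of per-cell event counts by class.

    Returns, per class: group means/medians, the two-sided t statistic and
    p-value, and the two-sided Mann-Whitney U and p-value (exact
    enumeration for small tie-free samples, normal approximation with tie
    correction otherwise).  A class with zero variance in both groups has
    no defined t-test and is reported as not applicable (NaN).
    """
    groups = sorted(counts[group_col].unique())
    if len(groups) != 2:
        raise InvalidConfigError(f"exactly two groups required, got {groups}")
    g1 = counts[counts[group_col] == groups[0]]
    g2 = counts[counts[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise InvalidConfigError("each group needs at least 2 cells")
    rows = []
    for cls in class_cols:
        if cls not in counts.columns:
            continue
        x = g1[cls].to_numpy(dtype=float)
        y = g2[cls].to_numpy(dtype=float)
        row = {"event_class": cls,
               f"mean_{groups[0]}": x.mean(), f"mean_{groups[1]}": y.mean(),
               f"median_{groups[0]}": float(np.median(x)),
               f"median_{groups[1]}": float(np.median(y))}
        if x.var() == 0 and y.var() == 0:
            row.update(t_statistic=np.nan, t_p_value=np.nan)
        else:
            tt = stats.ttest_ind(x, y)
            row.update(t_statistic=float(tt.statistic),
                       t_p_value=float(tt.pvalue))
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = ("exact" if max(len(x), len(y)) <= 20 and not ties
                  else "asymptotic")
        mwu = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        row.update(u_statistic=float(mwu.statistic),
                   u_p_value=float(mwu.pvalue), u_method=method)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Small calculators
# ---------------------------------------------------------------------------

def ploidy_from_dapi(median_diploid_area: float,
                     median_polyploid_area: float) -> float:
    """Median ploidy of a polyploid DAPI gate: 2 x (polyploid median /
    diploid median), taking the diploid distribution as ploidy 2."""
    if median_diploid_area <= 0 or median_polyploid_area <= 0:
        raise InvalidConfigError("DAPI medians must be positive")
    return 2.0 * median_polyploid_area / median_diploid_area


def marker_rpkm(counts: np.ndarray, lengths_bp: np.ndarray,
                total_mapped_reads: float) -> np.ndarray:
    """RPKM = count / (feature length in kb x total mapped reads in
    millions), for marker-locus coverage genotyping."""
    counts = np.asarray(counts, dtype=float)
    lengths_bp = np.asarray(lengths_bp, dtype=float)
    if np.any(lengths_bp <= 0):
        raise InvalidConfigError("feature lengths must be positive")
    if total_mapped_reads <= 0:
        raise InvalidConfigError("total mapped reads must be positive")
    return counts / ((lengths_bp / 1e3) * (total_mapped_reads / 1e6))


def loh_call(marker_a_rpkm: float, marker_b_rpkm: float,
             fraction: float = DEFAULT_LOH_RPKM_FRACTION) -> bool:
    """LOH-positive when the lost-allele marker's RPKM falls below
    ``fraction`` of the retained-allele marker's RPKM."""
    return marker_a_rpkm < fraction * marker_b_rpkm
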