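"""Synthetic clonal-evolution generator.

Emulates the four ordered phases of p53-driven copy-number evolution:

  1. LOH      — each SP founder lineage acquires a contiguous one-copy
                deletion on the designated "chr11 analog" spanning the
                p53-locus bin, with founder-specific breakpoints;
  2. DELETION_ACCUM — diploid descendants accumulate further deletions
                (the only event class available while diploid);
  3. POST_WGD — with some probability a rearranged diploid lineage doubles
                its whole genome (profile x 2);
  4. gains / focal amplifications — applied only after doubling, across
                successive post-WGD generations so late gains are
                subclonal within the polyploid population.

DP (p53-intact) cells stay flat diploid, save for a small-probability
whole-chromosome gain channel.  The generator emits ground-truth lineages
and noisy negative-binomial bin-count matrices so the whole calling /
phylogeny / landscape chain is testable without sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cn_profiling import (BinScaffold, MOUSE_CHROM_LENGTHS, apportion_bins,
                           build_scaffold, stable_cell_seed)
from .errors import InvalidConfigError

PHASE_LOH = "LOH"
PHASE_DELETION = "DELETION_ACCUM"
PHASE_POST_WGD = "POST_WGD"
PHASE_DP = "DP"          # marker-class background, outside the SP phase model

_MIN_DELETION_BINS = 5   # deletions: log-uniform between this and a chromosome
_MIN_GAIN_BINS = 20      # post-WGD gains are broad (arm-scale and larger)
_AMP_MAX_BINS = 5        # focal amplifications span 1..5 bins
_EDGE_CLEARANCE = 2      # event edges keep this many bins from existing breaks


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study conditions for the synthetic clonal-evolution generator.

    Defaults emulate the mouse setting: 5,000 bins of ~600 kb, ~10^6 reads
    per cell, per-bin coefficient of variation ~0.3, 100 SP cells carrying
    three independent LOH founder lineages, and 10-20% of SP cells in
    genome-doubled lineages (default target 0.15).
    """

    n_bins: int = 5000
    #: per-chromosome *bin* counts, in scaffold order; sum must equal n_bins
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: apportion_bins(MOUSE_CHROM_LENGTHS, 5000))
    n_dp_cells: int = 20
    n_sp_cells: int = 100
    reads_per_cell_mean: float = 1_000_000.0
    dispersion: float = 0.085
    gc_bias_strength: float = 0.4
    n_loh_lineages: int = 3
    deletions_per_phase: float = 3.0
    wgd_probability: float = 0.4
    polyploid_fraction_target: float = 0.15
    gains_post_wgd_rate: float = 4.0
    losses_post_wgd_rate: float = 2.0
    focal_amp_rate: float = 1.0
    dp_gain_probability: float = 0.1
    n_deletion_generations: int = 2
    n_postwgd_generations: int = 2
    loh_chrom: str | None = None
    seed: int = 0

    def __post_init__(self):
        counts = {"n_bins": self.n_bins, "n_dp_cells": self.n_dp_cells,
                  "n_sp_cells": self.n_sp_cells,
                  "n_loh_lineages": self.n_loh_lineages,
                  "n_deletion_generations": self.n_deletion_generations,
                  "n_postwgd_generations": self.n_postwgd_generations}
        for name, v in counts.items():
            if v <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {v}")
        for name in ("wgd_probability", "polyploid_fraction_target",
                     "dp_gain_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("reads_per_cell_mean",):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        for name in ("dispersion", "gc_bias_strength", "deletions_per_phase",
                     "gains_post_wgd_rate", "losses_post_wgd_rate",
                     "focal_amp_rate"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if sum(self.chrom_lengths.values()) != self.n_bins:
            raise InvalidConfigError(
                "sum of per-chromosome bin counts "
                f"({sum(self.chrom_lengths.values())}) != n_bins ({self.n_bins})")
        if self.n_loh_lineages > self.n_sp_cells:
            raise InvalidConfigError(
                f"n_loh_lineages ({self.n_loh_lineages}) exceeds n_sp_cells "
                f"({self.n_sp_cells})")

    @classmethod
    def mouse_default(cls, n_bins: int = 5000, **overrides) -> "SimConfig":
        """Mouse-style config at an arbitrary bin resolution."""
        overrides.setdefault(
            "chrom_lengths", apportion_bins(MOUSE_CHROM_LENGTHS, n_bins))
        return cls(n_bins=n_bins, **overrides)

    def designated_loh_chrom(self) -> str:
        if self.loh_chrom is not None:
            if self.loh_chrom not in self.chrom_lengths:
                raise InvalidConfigError(
                    f"loh_chrom {self.loh_chrom!r} not in chrom_lengths")
            return self.loh_chrom
        names = list(self.chrom_lengths)
        if "chr11" in self.chrom_lengths:
            return "chr11"
        return names[min(10, len(names) - 1)]


def sim_scaffold(config: SimConfig, bin_size: int = 600_000) -> BinScaffold:
    """Scaffold matching a SimConfig: each chromosome spans
    bin_count x bin_size bases, partitioned back into exactly those bins."""
    bp = {c: k * bin_size for c, k in config.chrom_lengths.items()}
    return build_scaffold(bp, config.n_bins)


# ---------------------------------------------------------------------------
# Truth records
# ---------------------------------------------------------------------------

@dataclass
class TrueLineage:
    lineage_id: str
    parent_id: str | None
    phase_label: str                      # LOH | DELETION_ACCUM | POST_WGD | DP
    true_profile: np.ndarray              # per-bin integer copy number
    breakpoint_set: np.ndarray            # sorted internal boundary indices
    is_polyploid: bool = False
    founder_loh_breakpoints: tuple[int, int] | None = None   # (start, end) bins
    marker_class: str = "SP"
    founder_id: str | None = None
    diploid_ancestor_id: str | None = None   # recorded at the WGD event


@dataclass
class TruthBundle:
    """Complete ground truth for one simulated dataset."""

    config: SimConfig
    lineages: dict[str, TrueLineage]
    cell_assignments: dict[str, str]         # cell id -> lineage id
    events: list[dict]                       # lineage/class/phase/coords

    def profile_of(self, cell_id: str) -> np.ndarray:
        return self.lineages[self.cell_assignments[cell_id]].true_profile

    def lineage_of(self, cell_id: str) -> TrueLineage:
        return self.lineages[self.cell_assignments[cell_id]]

    def true_ploidy(self, cell_id: str) -> float:
        return float(self.profile_of(cell_id).mean())

    def cell_ids(self) -> list[str]:
        return list(self.cell_assignments)

    def to_json_dict(self) -> dict:
        return {
            "lineages": [
                {"lineage_id": lin.lineage_id, "parent_id": lin.parent_id,
                 "phase_label": lin.phase_label,
                 "marker_class": lin.marker_class,
                 "founder_id": lin.founder_id,
                 "is_polyploid": lin.is_polyploid,
                 "diploid_ancestor_id": lin.diploid_ancestor_id,
                 "founder_loh_breakpoints": (
                     list(lin.founder_loh_breakpoints)
                     if lin.founder_loh_breakpoints else None),
                 "breakpoint_set": [int(b) for b in lin.breakpoint_set],
                 "true_profile": [int(s) for s in lin.true_profile]}
                for lin in self.lineages.values()],
            "cell_assignments": dict(self.cell_assignments),
            "events": self.events,
        }


# ---------------------------------------------------------------------------
# Lineage simulation
# ---------------------------------------------------------------------------

def _chrom_ranges(config: SimConfig) -> dict[str, tuple[int, int]]:
    out, lo = {}, 0
    for name, k in config.chrom_lengths.items():
        out[name] = (lo, lo + k)
        lo += k
    return out


def profile_breakpoints(profile: np.ndarray,
                        chrom_ranges: dict[str, tuple[int, int]]) -> np.ndarray:
    """Internal boundary indices b where the state changes between bin b and
    b+1 within one chromosome."""
    diffs = np.nonzero(np.diff(profile))[0]
    terminal = {hi - 1 for _, hi in chrom_ranges.values()}
    return np.array(sorted(b for b in diffs if b not in terminal), dtype=np.int64)


def _clear_of_breakpoints(edges: tuple[int, int], existing: np.ndarray) -> bool:
    if len(existing) == 0:
        return True
    s, e = edges
    # boundary indices introduced by an event [s, e): s-1 and e-1
    for b in (s - 1, e - 1):
        if np.any(np.abs(existing - b) < _EDGE_CLEARANCE):
            return False
    return True


def _draw_interval(rng: np.random.Generator,
                   chrom_ranges: dict[str, tuple[int, int]],
                   min_bins: int, max_bins: int | None = None
                   ) -> tuple[str, int, int]:
    """Chromosome (weighted by size) and a log-uniform-length interval.

    Chromosomes shorter than ``min_bins`` are not eligible; on scaffolds
    where none is long enough the whole largest chromosome is used.
    """
    names = [n for n, (lo, hi) in chrom_ranges.items() if hi - lo >= min_bins]
    if not names:
        name = max(chrom_ranges, key=lambda n: chrom_ranges[n][1]
                   - chrom_ranges[n][0])
        lo, hi = chrom_ranges[name]
        return name, lo, hi
    sizes = np.array([chrom_ranges[n][1] - chrom_ranges[n][0]
                      for n in names], float)
    name = names[int(rng.choice(len(names), p=sizes / sizes.sum()))]
    lo, hi = chrom_ranges[name]
    top = hi - lo if max_bins is None else min(max_bins, hi - lo)
    length = int(round(np.exp(rng.uniform(np.log(min_bins), np.log(top)))))
    length = int(np.clip(length, min_bins, top))
    start = int(rng.integers(lo, hi - length + 1))
    return name, start, start + length


def _apply_event(lineage: TrueLineage, rng: np.random.Generator,
                 chrom_ranges: dict[str, tuple[int, int]],
                 kind: str, phase: str, events: list[dict],
                 max_attempts: int = 60) -> bool:
    """Sample and apply one event, rejecting intervals whose edges fall
    near existing breakpoints of the lineage (keeps ancestral breakpoints
    intact, so descendant breakpoint sets are supersets)."""
    prof = lineage.true_profile
    for _ in range(max_attempts):
        if kind == "deletion":
            chrom, s, e = _draw_interval(rng, chrom_ranges, _MIN_DELETION_BINS)
            delta = -1
            if prof[s:e].min() < 1:
                continue
        elif kind == "postwgd_loss":
            chrom, s, e = _draw_interval(rng, chrom_ranges, _MIN_GAIN_BINS)
            delta = -1
            if prof[s:e].min() < 3:   # shed only from doubled material
                continue
        elif kind == "gain":
            chrom, s, e = _draw_interval(rng, chrom_ranges, _MIN_GAIN_BINS)
            delta = 1
        elif kind == "amplification":
            chrom, s, e = _draw_interval(rng, chrom_ranges, 1, _AMP_MAX_BINS)
            # push the interval to at least twice the doubled reference
            delta = int(rng.integers(4, 9))
        else:  # whole-chromosome gain (DP background channel)
            names = list(chrom_ranges)
            chrom = names[int(rng.integers(len(names)))]
            s, e = chrom_ranges[chrom]
            delta = 1
        if kind != "chrom_gain" and not _clear_of_breakpoints(
                (s, e), lineage.breakpoint_set):
            continue
        prof[s:e] += delta
        lineage.breakpoint_set = profile_breakpoints(prof, chrom_ranges)
        events.append({"lineage_id": lineage.lineage_id, "chrom": chrom,
                       "start_bin": int(s), "end_bin": int(e),
                       "class": {"chrom_gain": "gain",
                                 "postwgd_loss": "deletion"}.get(kind, kind),
                       "delta": int(delta), "phase": phase})
        return True
    return False


def simulate_lineages(config: SimConfig) -> TruthBundle:
    """Simulate the four-phase clonal structure and assign cells.

    SP founders each carry a distinct contiguous LOH deletion spanning the
    p53-locus bin of the designated chromosome; deletion generations add
    deletions only; doubled lineages (per-founder Bernoulli
    ``wgd_probability``) copy 2x their terminal diploid ancestor and then
    accumulate gains/amplifications across post-WGD generations.  Cells
    sample the terminal diploid lineage of each founder (post-sweep
    populations) and, for the polyploid fraction, the post-WGD generations.
    """
    rng = np.random.default_rng(config.seed)
    ranges = _chrom_ranges(config)
    n_bins = config.n_bins
    lineages: dict[str, TrueLineage] = {}
    events: list[dict] = []

    loh_chrom = config.designated_loh_chrom()
    loh_lo, loh_hi = ranges[loh_chrom]
    p53_bin = (loh_lo + loh_hi) // 2

    seen_loh: set[tuple[int, int]] = set()
    terminal_diploid: dict[str, str] = {}    # founder id -> terminal lineage id
    postwgd_by_founder: dict[str, list[str]] = {}

    for f in range(config.n_loh_lineages):
        founder_id = f"SPL{f}"
        for _ in range(1000):
            s = int(rng.integers(loh_lo, p53_bin + 1))
            e = int(rng.integers(p53_bin + 1, loh_hi + 1))
            if (s, e) not in seen_loh:
                break
        seen_loh.add((s, e))
        prof = np.full(n_bins, 2, dtype=np.int64)
        prof[s:e] -= 1
        founder = TrueLineage(
            lineage_id=founder_id, parent_id=None, phase_label=PHASE_LOH,
            true_profile=prof,
            breakpoint_set=profile_breakpoints(prof, ranges),
            founder_loh_breakpoints=(s, e), founder_id=founder_id)
        events.append({"lineage_id": founder_id, "chrom": loh_chrom,
                       "start_bin": s, "end_bin": e, "class": "deletion",
                       "delta": -1, "phase": PHASE_LOH})
        lineages[founder_id] = founder

        parent = founder
        for g in range(config.n_deletion_generations):
            child = TrueLineage(
                lineage_id=f"{founder_id}.D{g + 1}",
                parent_id=parent.lineage_id, phase_label=PHASE_DELETION,
                true_profile=parent.true_profile.copy(),
                breakpoint_set=parent.breakpoint_set.copy(),
                founder_loh_breakpoints=founder.founder_loh_breakpoints,
                founder_id=founder_id)
            for _ in range(rng.poisson(config.deletions_per_phase)):
                _apply_event(child, rng, ranges, "deletion",
                             PHASE_DELETION, events)
            lineages[child.lineage_id] = child
            parent = child
        terminal_diploid[founder_id] = parent.lineage_id

        if rng.random() < config.wgd_probability:
            ancestor = parent
            wgd_parent = ancestor
            for g in range(config.n_postwgd_generations):
                prof = (2 * ancestor.true_profile.copy() if g == 0
                        else wgd_parent.true_profile.copy())
                child = TrueLineage(
                    lineage_id=f"{founder_id}.W{g + 1}",
                    parent_id=wgd_parent.lineage_id,
                    phase_label=PHASE_POST_WGD, true_profile=prof,
                    breakpoint_set=profile_breakpoints(prof, ranges),
                    is_polyploid=True,
                    founder_loh_breakpoints=founder.founder_loh_breakpoints,
                    founder_id=founder_id,
                    diploid_ancestor_id=ancestor.lineage_id)
                for _ in range(rng.poisson(config.gains_post_wgd_rate)):
                    _apply_event(child, rng, ranges, "gain",
                                 PHASE_POST_WGD, events)
                # doubled genomes also shed copies: measured polyploid DNA
                # content sits below 4n, so losses accompany the gains
                for _ in range(rng.poisson(config.losses_post_wgd_rate)):
                    _apply_event(child, rng, ranges, "postwgd_loss",
                                 PHASE_POST_WGD, events)
                for _ in range(rng.poisson(config.focal_amp_rate)):
                    _apply_event(child, rng, ranges, "amplification",
                                 PHASE_POST_WGD, events)
                lineages[child.lineage_id] = child
                wgd_parent = child

    # collect post-WGD lineage ids per founder
    for lid, lin in lineages.items():
        if lin.phase_label == PHASE_POST_WGD:
            postwgd_by_founder.setdefault(lin.founder_id, [])
            postwgd_by_founder[lin.founder_id].append(lid)

    # DP background: flat diploid, plus an optional whole-chromosome-gain
    # lineage with small probability
    dp_main = TrueLineage(
        lineage_id="DP0", parent_id=None, phase_label=PHASE_DP,
        true_profile=np.full(n_bins, 2, dtype=np.int64),
        breakpoint_set=np.array([], dtype=np.int64), marker_class="DP",
        founder_id="DP0")
    lineages["DP0"] = dp_main
    dp_ids = ["DP0"]
    if rng.random() < config.dp_gain_probability:
        dp_gain = TrueLineage(
            lineage_id="DP1", parent_id="DP0", phase_label=PHASE_DP,
            true_profile=dp_main.true_profile.copy(),
            breakpoint_set=np.array([], dtype=np.int64), marker_class="DP",
            founder_id="DP0")
        _apply_event(dp_gain, rng, ranges, "chrom_gain", PHASE_DP, events)
        lineages["DP1"] = dp_gain
        dp_ids.append("DP1")

    # --- cell assignment -------------------------------------------------
    assignments: dict[str, str] = {}
    postwgd_all = [lid for ids in postwgd_by_founder.values() for lid in ids]
    n_poly = (int(round(config.polyploid_fraction_target * config.n_sp_cells))
              if postwgd_all else 0)
    diploid_pool = list(terminal_diploid.values())
    for i in range(config.n_sp_cells):
        cid = f"SP{i:03d}"
        if i < n_poly:
            assignments[cid] = postwgd_all[int(rng.integers(len(postwgd_all)))]
        else:
            assignments[cid] = diploid_pool[i % len(diploid_pool)]
    for i in range(config.n_dp_cells):
        cid = f"DP{i:03d}"
        if len(dp_ids) > 1 and rng.random() < 0.3:
            assignments[cid] = dp_ids[1]
        else:
            assignments[cid] = dp_ids[0]

    return TruthBundle(config=config, lineages=lineages,
                       cell_assignments=assignments, events=events)


# ---------------------------------------------------------------------------
# Read-count emission
# ---------------------------------------------------------------------------

def gc_bias_factor(gc: np.ndarray, strength: float) -> np.ndarray:
    """Quadratic GC-bias multiplier, 1 at GC=0.45, floored at 0.05."""
    return np.maximum(1.0 - strength * 25.0 * (np.asarray(gc) - 0.45) ** 2,
                      0.05)


def profiles_to_counts(truth: TruthBundle, scaffold: BinScaffold,
                       config: SimConfig | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw noisy bin counts for every cell in the truth bundle.

    Per-bin expectations are proportional to true copy number x GC-bias
    factor, normalized to a Poisson total around ``reads_per_cell_mean``;
    overdispersion enters through a gamma-Poisson mixture with variance
    ``mu + dispersion mu^2``.  Each cell uses an independent stream derived
    by stable hashing of its id, so adding cells never perturbs existing
    ones.  Returns (bin x cell count matrix, per-cell metadata).
    """
    if config is None:
        config = truth.config
    if scaffold.n_bins != config.n_bins:
        raise InvalidConfigError(
            f"scaffold has {scaffold.n_bins} bins, config expects "
            f"{config.n_bins}")
    bias = gc_bias_factor(scaffold.gc, config.gc_bias_strength)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for cell_id in truth.cell_ids():
        lin = truth.lineage_of(cell_id)
        rng = np.random.default_rng(stable_cell_seed(config.seed, cell_id))
        lam = lin.true_profile * bias
        p = lam / lam.sum()
        total = rng.poisson(config.reads_per_cell_mean)
        mu = total * p
        if config.dispersion > 0:
            mult = rng.gamma(shape=1.0 / config.dispersion,
                             scale=config.dispersion, size=scaffold.n_bins)
            counts = rng.poisson(mu * mult)
        else:
            counts = rng.poisson(mu)
        columns[cell_id] = counts.astype(np.int64)
        meta_rows.append({"cell_id": cell_id,
                          "marker_class": lin.marker_class,
                          "lineage_id": lin.lineage_id,
                          "founder_id": lin.founder_id,
                          "is_polyploid": bool(lin.is_polyploid),
                          "true_ploidy": float(lin.true_profile.mean()),
                          "total_reads": int(counts.sum())})
    matrix = pd.DataFrame(columns)
    meta = pd.DataFrame(meta_rows)
    return matrix, meta


def simulate_dataset(config: SimConfig
                     ) -> tuple[TruthBundle, BinScaffold, pd.DataFrame,
                                pd.DataFrame]:
    """Convenience: lineages + scaffold + counts in one call."""
    truth = simulate_lineages(config)
    scaffold = sim_scaffold(config)
    matrix, meta = profiles_to_counts(truth, scaffold, config)
    return truth, scaffold, matrix, meta


def two_clone_benchmark(seed: int, n_per_clone: int = 30,
                        deletions_per_clone: int = 5
                        ) -> tuple[TruthBundle, SimConfig]:
    """Fixed-design benchmark: two clonal lineages with disjoint deletion
    signatures under the default noise model.

    Each clone carries ``deletions_per_clone`` one-copy deletions (~25
    bins each) on its own set of chromosomes — ten breakpoints per clone,
    none shared between clones.  Used to validate clone calling at a known
    answer.
    """
    config = SimConfig.mouse_default(
        n_sp_cells=2 * n_per_clone, n_dp_cells=1, n_loh_lineages=2,
        seed=seed)
    rng = np.random.default_rng(seed)
    ranges = _chrom_ranges(config)
    chrom_names = list(ranges)
    lineages: dict[str, TrueLineage] = {}
    assignments: dict[str, str] = {}
    for ci, clone in enumerate("AB"):
        profile = np.full(config.n_bins, 2, dtype=np.int64)
        # odd/even chromosomes keep the two signatures disjoint
        for k in range(deletions_per_clone):
            lo, hi = ranges[chrom_names[2 * k + ci]]
            width = int(rng.integers(20, 31))
            start = int(rng.integers(lo + 5, hi - width - 5))
            profile[start:start + width] = 1
        lin = TrueLineage(
            lineage_id=f"clone{clone}", parent_id=None,
            phase_label=PHASE_DELETION, true_profile=profile,
            breakpoint_set=profile_breakpoints(profile, ranges),
            founder_id=f"clone{clone}")
        lineages[lin.lineage_id] = lin
        for i in range(n_per_clone):
            assignments[f"{clone}{i:03d}"] = lin.lineage_id
    return TruthBundle(config=config, lineages=lineages,
                       cell_assignments=assignments, events=[]), config
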