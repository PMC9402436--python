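"""File formats, pipeline configuration and the stage orchestrator.

Formats: bin-count matrix TSV (scaffold columns then one column per cell),
chrom-sizes TSV, SEG (1-based inclusive), BED (0-based half-open), Newick,
and JSON for config / truth / run reports.  Every writer has a paired
reader that reproduces the in-memory values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import clone_phylo, cna_landscape, cn_profiling, sim_evolution
from .cn_profiling import BinScaffold, IntegerCNProfile, SegmentedProfile
from .errors import FormatError, InvalidConfigError

log = logging.getLogger("cnaphase")

_SCAFFOLD_COLS = ["chrom", "start", "end", "gc"]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_chrom_sizes(chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError("chrom-sizes rows need 2 columns "
                                  f"(chrom, length), got {len(parts)}",
                                  path=path, line=i)
            try:
                out[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError(f"non-integer length {parts[1]!r}",
                                  path=path, line=i) from None
    if not out:
        raise FormatError("empty chrom-sizes file", path=path)
    return out


def write_counts_matrix(matrix: pd.DataFrame, scaffold: BinScaffold,
                        path) -> None:
    """Bin-count TSV: chrom, start, end, gc, then one column per cell."""
    df = scaffold.to_frame()
    for c in matrix.columns:
        df[c] = matrix[c].to_numpy()
    df.to_csv(path, sep="\t", index=False)


def read_counts_matrix(path) -> tuple[BinScaffold, pd.DataFrame]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"unreadable TSV: {exc}", path=path) from exc
    missing = [c for c in _SCAFFOLD_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"bin-count matrix lacks columns {missing}",
                          path=path, line=1)
    if df[_SCAFFOLD_COLS + list(df.columns[4:])].isna().any().any():
        bad = int(np.nonzero(df.isna().any(axis=1).to_numpy())[0][0]) + 2
        raise FormatError("missing values (truncated row?)", path=path,
                          line=bad)
    scaffold = BinScaffold(chrom=df["chrom"].to_numpy(dtype=object),
                           start=df["start"].to_numpy(dtype=np.int64),
                           end=df["end"].to_numpy(dtype=np.int64),
                           gc=df["gc"].to_numpy(dtype=float))
    counts = df.drop(columns=_SCAFFOLD_COLS)
    return scaffold, counts


def write_cn_matrix(profiles: list[IntegerCNProfile], scaffold: BinScaffold,
                    path) -> None:
    """Integer copy-number states TSV: chrom, start, end, then cells."""
    df = scaffold.to_frame().drop(columns="gc")
    for p in profiles:
        df[p.cell_id] = p.states
    df.to_csv(path, sep="\t", index=False)


def read_cn_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("chrom", "start", "end"):
        if c not in df.columns:
            raise FormatError(f"integer-CN matrix lacks column {c!r}",
                              path=path, line=1)
    return df


def write_seg(profiles: list[IntegerCNProfile] | list[SegmentedProfile],
              scaffold: BinScaffold, path) -> None:
    """SEG (1-based inclusive): sample, chrom, start, end, num_bins,
    seg_mean."""
    rows = []
    for p in profiles:
        seg = p.segments if isinstance(p, IntegerCNProfile) else p
        for c, s, e, m in zip(seg.seg_chrom, seg.seg_start, seg.seg_end,
                              seg.seg_mean):
            rows.append({"sample": seg.cell_id, "chrom": c,
                         "start": int(scaffold.start[s]) + 1,
                         "end": int(scaffold.end[e - 1]),
                         "num_bins": int(e - s), "seg_mean": m})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "chrom", "start", "end", "num_bins", "seg_mean"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"SEG file lacks columns {sorted(missing)}",
                          path=path, line=1)
    return df


def write_events_bed(events: list[cna_landscape.CNAEvent],
                     scaffold: BinScaffold, path) -> None:
    """BED (0-based half-open): name = cell|class, score = state."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(f"{ev.chrom}\t{scaffold.start[ev.start_bin]}\t"
                     f"{scaffold.end[ev.end_bin - 1]}\t"
                     f"{ev.cell_id}|{ev.event_class}\t{ev.state}\t.\n")


def write_cores_bed(cores: pd.DataFrame, scaffold: BinScaffold, path) -> None:
    with open(path, "w") as fh:
        for _, row in cores.iterrows():
            fh.write(f"{row.chrom}\t{scaffold.start[row.start_bin]}\t"
                     f"{scaffold.end[row.end_bin - 1]}\t"
                     f"{row.event_class}\t{row.score:.4f}\t.\n")


def write_newick(tree: clone_phylo.CloneTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise FormatError(f"unparseable Newick: {exc}", path=path) from exc


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage parameters, JSON round-trippable.

    Defaults equal the documented per-module defaults: 250,000-read QC
    floor, CBS alpha 0.01 with 1,000 permutations, ploidy grid 1.5-6.0
    step 0.05, clone threshold t = 0.01, designation threshold 0.1.
    """

    sim: dict = field(default_factory=dict)     # SimConfig overrides
    min_reads: int = cn_profiling.DEFAULT_MIN_READS
    lowess_fraction: float = cn_profiling.DEFAULT_LOWESS_FRACTION
    cbs_alpha: float = cn_profiling.DEFAULT_CBS_ALPHA
    cbs_n_perm: int = cn_profiling.DEFAULT_CBS_N_PERM
    min_seg_bins: int = cn_profiling.DEFAULT_MIN_SEG_BINS
    q_min: float = 1.5
    q_max: float = 6.0
    q_step: float = 0.05
    clone_min_delta: int = clone_phylo.DEFAULT_MIN_DELTA
    clone_tolerance: int = clone_phylo.DEFAULT_TOLERANCE
    clone_n_perm: int = clone_phylo.DEFAULT_NULL_N_PERM
    clone_t: float = clone_phylo.DEFAULT_CLONE_T
    theta: float = cna_landscape.DEFAULT_THETA
    core_n_perm: int = cna_landscape.DEFAULT_CORE_N_PERM
    seed: int = 0

    def q_grid(self) -> np.ndarray:
        return np.round(np.arange(self.q_min, self.q_max + 1e-9,
                                  self.q_step), 10)

    def sim_config(self) -> sim_evolution.SimConfig:
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        if "n_bins" in kwargs and "chrom_lengths" not in kwargs:
            return sim_evolution.SimConfig.mouse_default(**kwargs)
        return sim_evolution.SimConfig(**kwargs)

    def to_json(self, path) -> None:
        write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = read_json(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Stage drivers
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, out_dir: Path) -> dict:
    sim_cfg = config.sim_config()
    truth, scaffold, matrix, meta = sim_evolution.simulate_dataset(sim_cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_counts_matrix(matrix, scaffold, out_dir / "counts.tsv")
    meta.to_csv(out_dir / "cell_metadata.tsv", sep="\t", index=False)
    write_json(truth.to_json_dict(), out_dir / "truth.json")
    counts = {"cells_simulated": len(truth.cell_assignments),
              "lineages": len(truth.lineages),
              "events": len(truth.events),
              "polyploid_lineages": sum(l.is_polyploid
                                        for l in truth.lineages.values())}
    log.info("simulate: %s", counts)
    return counts


def run_profile(config: PipelineConfig, out_dir: Path
                ) -> tuple[list[IntegerCNProfile], BinScaffold, dict]:
    scaffold, matrix = read_counts_matrix(out_dir / "counts.tsv")
    profiles, report = cn_profiling.call_cells(
        matrix, scaffold, min_reads=config.min_reads,
        lowess_fraction=config.lowess_fraction, alpha=config.cbs_alpha,
        n_perm=config.cbs_n_perm, min_seg_bins=config.min_seg_bins,
        q_grid=config.q_grid(), seed=config.seed)
    report.to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)
    if profiles:
        write_cn_matrix(profiles, scaffold, out_dir / "cn.tsv")
        write_seg(profiles, scaffold, out_dir / "segments.seg")
    counts = {"cells_in": int(matrix.shape[1]),
              "cells_qc_pass": int(report["qc_pass"].sum()),
              "cells_called": len(profiles),
              "cells_dropped": int(matrix.shape[1]) - len(profiles)}
    log.info("profile: %s", counts)
    if not profiles:
        raise InvalidConfigError(
            "profile stage kept 0 cells (QC floor above all simulated "
            "totals?); pipeline stopped")
    return profiles, scaffold, counts


def run_clones(config: PipelineConfig, profiles: list[IntegerCNProfile],
               scaffold: BinScaffold, out_dir: Path
               ) -> tuple[clone_phylo.CloneTree, dict]:
    bp = clone_phylo.extract_breakpoints(
        profiles, scaffold, min_delta=config.clone_min_delta,
        tolerance=config.clone_tolerance)
    d = clone_phylo.pairwise_dissimilarity(bp)
    tree = clone_phylo.build_tree(d, bp.cell_ids)
    order = [bp.index_of(c) for c in tree.cell_ids]
    d_sorted = d[np.ix_(order, order)]
    null = clone_phylo.permutation_null(bp, n_perm=config.clone_n_perm,
                                        seed=config.seed)
    tree = clone_phylo.call_clones(tree, d_sorted, null, t=config.clone_t)
    labelled = clone_phylo.trace_wgd_precursors(profiles, bp, tree,
                                                t=config.clone_t)
    write_newick(tree, out_dir / "tree.nwk")
    pd.DataFrame({"cell_id": tree.cell_ids,
                  "clone": [tree.clone_labels[c] for c in tree.cell_ids]}
                 ).to_csv(out_dir / "clones.tsv", sep="\t", index=False)
    labelled.to_csv(out_dir / "wgd_precursors.tsv", sep="\t", index=False)
    pd.DataFrame(d, index=bp.cell_ids, columns=bp.cell_ids).to_csv(
        out_dir / "dissimilarity.tsv", sep="\t")
    n_clones = len({v for v in tree.clone_labels.values() if v >= 0})
    counts = {"cells": len(tree.cell_ids), "canonical_boundaries":
              bp.n_boundaries, "clones_called": n_clones,
              "nodes_accepted": int(tree.node_accepted.sum()),
              "precursor_links": int(len(labelled))}
    log.info("clones: %s", counts)
    return tree, counts


def run_landscape(config: PipelineConfig, profiles: list[IntegerCNProfile],
                  scaffold: BinScaffold, out_dir: Path) -> dict:
    events = []
    for p in profiles:
        events.extend(cna_landscape.classify_events(p, scaffold))
    write_events_bed(events, scaffold, out_dir / "events.bed")
    all_cores = []
    for cls in ("deletion", "gain", "amplification"):
        cores = cna_landscape.core_recurrence(
            events, scaffold, cls, n_perm=config.core_n_perm,
            seed=config.seed)
        all_cores.append(cores)
    cores = pd.concat(all_cores, ignore_index=True)
    write_cores_bed(cores, scaffold, out_dir / "cores.bed")
    values = np.vstack([p.segments.binwise_means() for p in profiles])
    track = cna_landscape.frequency_track(values, theta=config.theta)
    pd.DataFrame({"chrom": scaffold.chrom, "start": scaffold.start,
                  "end": scaffold.end, "gain_freq": track.gain_freq,
                  "del_freq": track.del_freq}).to_csv(
        out_dir / "frequency.tsv", sep="\t", index=False)
    states = np.vstack([p.states for p in profiles])
    h = cna_landscape.bin_homogeneity(states)
    pd.DataFrame({"chrom": scaffold.chrom, "start": scaffold.start,
                  "end": scaffold.end, "homogeneity": h}).to_csv(
        out_dir / "homogeneity.tsv", sep="\t", index=False)
    by_class = {"deletion": 0, "gain": 0, "amplification": 0}
    for ev in events:
        by_class[ev.event_class] += 1
    counts = {"events": len(events), "cores_found": int(len(cores)),
              **{f"events_{k}": v for k, v in by_class.items()}}
    write_json({"event_counts": by_class,
                "mean_homogeneity": float(h.mean())},
               out_dir / "landscape_stats.json")
    log.info("landscape: %s", counts)
    return counts


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """simulate -> profile -> clones -> landscape, with a machine-readable
    run report.  Stage failures propagate with the stage name attached."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed,
                    "stages": {}}
    t0 = time.time()
    stage = "simulate"
    try:
        report["stages"]["simulate"] = run_simulate(config, out_dir)
        stage = "profile"
        profiles, scaffold, counts = run_profile(config, out_dir)
        report["stages"]["profile"] = counts
        stage = "clones"
        _, counts = run_clones(config, profiles, scaffold, out_dir)
        report["stages"]["clones"] = counts
        stage = "landscape"
        report["stages"]["landscape"] = run_landscape(config, profiles,
                                                      scaffold, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    report["elapsed_seconds"] = round(time.time() - t0, 3)
    write_json(report, out_dir / "run_report.json")
    return report
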