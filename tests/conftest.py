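"""Shared fixtures.

The expensive end-to-end simulations are session-scoped and shared across
tests; everything is generated programmatically at fixed seeds.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import cnaphase as cp


@pytest.fixture(scope="session")
def tiny_scaffold():
    """Two equal chromosomes, ten bins of 200 bases."""
    return cp.build_scaffold({"A": 1000, "B": 1000}, 10)


@pytest.fixture(scope="session")
def small_sim():
    """Small, fast simulation (600 bins, 12 SP + 3 DP cells)."""
    cfg = cp.SimConfig.mouse_default(
        n_bins=600, n_sp_cells=12, n_dp_cells=3, wgd_probability=1.0,
        polyploid_fraction_target=0.3, seed=101)
    truth, scaffold, matrix, meta = cp.simulate_dataset(cfg)
    return cfg, truth, scaffold, matrix, meta


@pytest.fixture(scope="session")
def default_run():
    """The default study conditions (5,000 bins, 100 SP + 20 DP cells),
    profiled and clone-called end to end.  Expensive; computed once."""
    cfg = cp.SimConfig()
    truth, scaffold, matrix, meta = cp.simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles, report = cp.call_cells(matrix, scaffold, seed=1)
        bp = cp.extract_breakpoints(profiles, scaffold)
        d = cp.pairwise_dissimilarity(bp)
        tree = cp.build_tree(d, bp.cell_ids)
        order = [bp.index_of(c) for c in tree.cell_ids]
        null = cp.permutation_null(bp, n_perm=500, seed=5)
        tree = cp.call_clones(tree, d[np.ix_(order, order)], null, t=0.01)
        links = cp.trace_wgd_precursors(profiles, bp, tree)
    return {
        "config": cfg, "truth": truth, "scaffold": scaffold,
        "matrix": matrix, "meta": meta, "profiles": profiles,
        "report": report, "bp": bp, "d": d, "tree": tree, "links": links,
    }
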