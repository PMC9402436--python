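"""Event classification, CORE recurrence, frequency/homogeneity statistics."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import cnaphase as cp
from cnaphase.cna_landscape import CNAEvent, events_to_profile, _greedy_cores
from cnaphase.cn_profiling import IntegerCNProfile
from cnaphase.errors import InvalidConfigError


def _profile(states, cell_id="c", ploidy=None):
    states = np.asarray(states, dtype=np.int64)
    if ploidy is None:
        ploidy = float(states.mean())
    return IntegerCNProfile(cell_id=cell_id, multiplier=ploidy, ploidy=ploidy,
                            states=states, fit_error=0.0, segments=None)


class TestClassifyEvents:
    def test_polyploid_reference_is_four(self):
        sc = cp.build_scaffold({"A": 6000}, 60)
        states = np.full(60, 4)
        states[10:20] = 3
        states[30:40] = 5
        events = cp.classify_events(_profile(states, ploidy=3.9), sc)
        by_state = {ev.state: ev.event_class for ev in events}
        assert by_state == {3: "deletion", 5: "gain"}
        assert all(ev.reference == 4 for ev in events)

    def test_flat_diploid_yields_no_events(self, tiny_scaffold):
        events = cp.classify_events(_profile([2] * 10, ploidy=2.0),
                                    tiny_scaffold)
        assert events == []

    def test_focal_high_state_is_amplification(self):
        sc = cp.build_scaffold({"A": 6000}, 60)
        states = np.full(60, 2)
        states[20:23] = 9
        events = cp.classify_events(_profile(states, ploidy=2.1), sc)
        assert [ev.event_class for ev in events] == ["amplification"]

    def test_broad_high_state_is_gain(self):
        sc = cp.build_scaffold({"A": 6000}, 60)
        states = np.full(60, 2)
        states[20:40] = 9     # 20 bins: too broad for the focal rule
        events = cp.classify_events(_profile(states, ploidy=2.3), sc)
        assert [ev.event_class for ev in events] == ["gain"]

    def test_events_do_not_cross_chromosomes(self, tiny_scaffold):
        states = np.array([1] * 5 + [1] * 5)
        events = cp.classify_events(_profile(states, ploidy=2.0),
                                    tiny_scaffold)
        assert len(events) == 2
        assert {ev.chrom for ev in events} == {"A", "B"}

    def test_classification_roundtrip_reassembles_profile(self):
        sc = cp.build_scaffold({"A": 5000, "B": 5000}, 100)
        rng = np.random.default_rng(6)
        for _ in range(20):
            states = np.full(100, 2)
            for _ in range(rng.integers(1, 6)):
                s = rng.integers(0, 90)
                e = s + rng.integers(1, 10)
                states[s:e] = rng.integers(0, 7)
            events = cp.classify_events(_profile(states, ploidy=2.0), sc)
            rebuilt = events_to_profile(events, 100, reference=2)
            assert np.array_equal(rebuilt, states)


def _event(cell, chrom, s, e, state=1, cls="deletion", ref=2):
    return CNAEvent(cell_id=cell, chrom=chrom, start_bin=s, end_bin=e,
                    state=state, event_class=cls, reference=ref)


class TestCoreRecurrence:
    def test_shared_deletion_dominates(self):
        sc = cp.build_scaffold({"A": 150000}, 500)
        events = [_event(f"c{i}", "A", 100, 200) for i in range(8)]
        events += [_event("c8", "A", 300, 350), _event("c9", "A", 400, 420)]
        cores = cp.core_recurrence(events, sc, "deletion", n_perm=50, seed=0)
        top = cores.iloc[0]
        assert (top.start_bin, top.end_bin) == (100, 200)
        assert top.score == pytest.approx(8.0)
        assert top.p_value < 0.05

    def test_no_events_empty_result(self, tiny_scaffold):
        cores = cp.core_recurrence([], tiny_scaffold, "deletion")
        assert cores.empty

    def test_single_event_in_all_cells_scores_n(self, tiny_scaffold):
        events = [_event(f"c{i}", "A", 1, 4) for i in range(5)]
        cores = cp.core_recurrence(events, tiny_scaffold, "deletion",
                                   n_perm=20, seed=0)
        assert cores.iloc[0].score == pytest.approx(5.0)

    def test_greedy_top_core_matches_exhaustive_search(self):
        sc = cp.build_scaffold({"A": 30000, "B": 30000}, 200)
        rng = np.random.default_rng(7)
        chrom_of = {"A": (0, 100), "B": (100, 200)}
        events = []
        for c in range(15):
            for _ in range(rng.integers(1, 4)):
                chrom = rng.choice(["A", "B"])
                lo, hi = chrom_of[chrom]
                s = int(rng.integers(lo, hi - 10))
                e = s + int(rng.integers(3, 10))
                events.append(_event(f"c{c}", chrom, s, e))
        greedy = _greedy_cores(events, 1)[0]

        # independent plain-python scorer over the full candidate set
        def oracle_score(chrom, s, e):
            best_per_cell = {}
            for ev in events:
                if ev.chrom != chrom:
                    continue
                inter = min(e, ev.end_bin) - max(s, ev.start_bin)
                if inter <= 0:
                    continue
                union = max(e, ev.end_bin) - min(s, ev.start_bin)
                j = inter / union
                best_per_cell[ev.cell_id] = max(
                    best_per_cell.get(ev.cell_id, 0.0), j)
            return sum(best_per_cell.values())

        best = max(oracle_score(ev.chrom, ev.start_bin, ev.end_bin)
                   for ev in events)
        assert greedy[3] == pytest.approx(best)
        assert oracle_score(greedy[0], greedy[1], greedy[2]) == \
            pytest.approx(best)


class TestFrequencyTrack:
    def test_designation_threshold_boundary(self):
        track = cp.frequency_track(np.array([[1.05, 1.12, 1.10, 0.90, 0.83]]),
                                   theta=0.1)
        # centring rescales; reproduce it for the expectation
        v = np.array([1.05, 1.12, 1.10, 0.90, 0.83])
        c = v / v.mean()
        assert np.array_equal(track.gain_freq, (c >= 1.1).astype(float))
        assert np.array_equal(track.del_freq, (c <= 0.9).astype(float))

    def test_exact_threshold_is_inclusive(self):
        # construct a sample already centred at mean 1 with one bin at
        # exactly 1 + theta and one at exactly 1 - theta
        values = np.array([[1.1, 0.9, 1.0, 1.0]])
        assert values.mean() == 1.0
        track = cp.frequency_track(values, theta=0.1)
        assert track.gain_freq.tolist() == [1.0, 0.0, 0.0, 0.0]
        assert track.del_freq.tolist() == [0.0, 1.0, 0.0, 0.0]

    def test_identical_samples_with_deletion(self):
        row = np.ones(20)
        row[5:10] = 0.5
        values = np.tile(row, (4, 1))
        track = cp.frequency_track(values, theta=0.1)
        centred = row / row.mean()
        assert np.array_equal(track.del_freq, (centred <= 0.9).astype(float))
        assert track.gain_freq.sum() == (centred >= 1.1).sum()

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(InvalidConfigError):
            cp.frequency_track(np.ones((1, 4)), theta=0.0)


class TestBinHomogeneity:
    @pytest.mark.parametrize("column,expected", [
        ([2, 2, 3], 2 / 3),
        ([2, 2, 2], 1.0),
        ([2, 2, 3, 3], 0.5),
    ])
    def test_modal_state_frequency(self, column, expected):
        m = np.array(column)[:, None]
        assert cp.bin_homogeneity(m)[0] == pytest.approx(expected)

    def test_bounds(self):
        rng = np.random.default_rng(8)
        m = rng.integers(0, 6, size=(7, 40))
        h = cp.bin_homogeneity(m)
        assert np.all(h >= 1 / 7) and np.all(h <= 1)
        assert np.all((h == 1) == (np.ptp(m, axis=0) == 0))


class TestSegmentHomogeneity:
    def test_clonal_segments_score_one(self):
        df = pd.DataFrame({"cf": [0.6, 0.6, 0.6], "purity": [0.6] * 3,
                           "event_class": ["gain", "deletion", "deletion"]})
        rep = cp.segment_homogeneity(df)
        assert np.allclose(rep.table["cf_purity"], 1.0)
        assert rep.ks_statistic == pytest.approx(0.0)

    def test_subclonal_gains_detected_by_ks(self):
        rng = np.random.default_rng(9)
        dels = pd.DataFrame({"cf": 0.7 * np.ones(50) + rng.normal(0, 0.01, 50),
                             "purity": 0.7, "event_class": "deletion"})
        gains = pd.DataFrame({"cf": 0.7 * rng.uniform(0.2, 1.0, 50),
                              "purity": 0.7, "event_class": "gain"})
        rep = cp.segment_homogeneity(pd.concat([dels, gains]))
        assert rep.ks_applicable
        assert rep.ks_p_value < 0.005

    def test_single_class_marks_ks_not_applicable(self):
        df = pd.DataFrame({"cf": [0.5, 0.4], "purity": [0.5, 0.5],
                           "event_class": ["deletion", "deletion"]})
        rep = cp.segment_homogeneity(df)
        assert not rep.ks_applicable

    def test_clipping_keeps_raw_column(self):
        df = pd.DataFrame({"cf": [1.0], "purity": [0.5],
                           "event_class": ["gain"]})
        rep = cp.segment_homogeneity(df)
        assert rep.table.iloc[0].cf_purity == pytest.approx(1.25)
        assert rep.table.iloc[0].cf_purity_raw == pytest.approx(2.0)

    def test_nonpositive_purity_rejected(self):
        df = pd.DataFrame({"cf": [0.5], "purity": [0.0],
                           "event_class": ["gain"]})
        with pytest.raises(InvalidConfigError):
            cp.segment_homogeneity(df)


def _mwu_two_sided_exact_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank splits."""
    pooled = sorted(x + y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b) \
        + 0.5 * sum(1 for a in x for b in y if a == b)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for a in xs for b in ys if a > b) \
            + 0.5 * sum(1 for a in xs for b in ys if a == b)
        mu = len(x) * len(y) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestCompareEventCounts:
    def _frame(self, g1, g2):
        rows = [{"group": "a", "gain": v} for v in g1]
        rows += [{"group": "b", "gain": v} for v in g2]
        return pd.DataFrame(rows)

    def test_identical_groups_mwu_p_one(self):
        res = cp.compare_event_counts(self._frame([1, 2, 3], [1, 2, 3]),
                                      class_cols=("gain",))
        assert res.iloc[0].u_p_value == pytest.approx(1.0)

    def test_separated_groups_match_exact_enumeration(self):
        res = cp.compare_event_counts(self._frame([1, 2, 3], [11, 12, 13]),
                                      class_cols=("gain",))
        oracle = _mwu_two_sided_exact_oracle([1, 2, 3], [11, 12, 13])
        assert oracle == pytest.approx(2 / comb(6, 3))    # = 0.1
        assert res.iloc[0].u_p_value == pytest.approx(oracle)

    def test_random_inputs_match_reference_library(self):
        from scipy import stats
        rng = np.random.default_rng(10)
        for _ in range(50):
            x = rng.poisson(4, rng.integers(5, 30)).astype(float)
            y = rng.poisson(6, rng.integers(5, 30)).astype(float)
            res = cp.compare_event_counts(
                self._frame(x.tolist(), y.tolist()), class_cols=("gain",))
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = ("exact" if max(len(x), len(y)) <= 20 and not ties
                      else "asymptotic")
            ref_u = stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method=method)
            ref_t = stats.ttest_ind(x, y)
            assert res.iloc[0].u_p_value == pytest.approx(ref_u.pvalue,
                                                          abs=1e-8)
            assert res.iloc[0].t_p_value == pytest.approx(ref_t.pvalue,
                                                          abs=1e-8)

    def test_degenerate_variance_reported_not_applicable(self):
        res = cp.compare_event_counts(self._frame([2, 2, 2], [2, 2, 2]),
                                      class_cols=("gain",))
        assert np.isnan(res.iloc[0].t_statistic)

    def test_exactly_two_groups_required(self):
        df = pd.DataFrame({"group": ["a"] * 4, "gain": [1, 2, 3, 4]})
        with pytest.raises(InvalidConfigError):
            cp.compare_event_counts(df, class_cols=("gain",))


class TestSmallCalculators:
    @pytest.mark.parametrize("dip,poly,expected", [
        (100.0, 200.0, 4.0), (100.0, 190.0, 3.8), (37.5, 37.5, 2.0)])
    def test_dapi_ploidy(self, dip, poly, expected):
        assert cp.ploidy_from_dapi(dip, poly) == pytest.approx(expected)

    def test_dapi_nonpositive_rejected(self):
        with pytest.raises(InvalidConfigError):
            cp.ploidy_from_dapi(0.0, 100.0)

    def test_rpkm_formula(self):
        rpkm = cp.marker_rpkm(np.array([100]), np.array([1000]), 1_000_000)
        assert rpkm[0] == pytest.approx(100.0)

    def test_loh_calls(self):
        assert cp.loh_call(0.0, 50.0)          # lost marker
        assert not cp.loh_call(50.0, 50.0)     # retained
        assert not cp.loh_call(0.0, 0.0)       # no evidence

    def test_rpkm_input_validation(self):
        with pytest.raises(InvalidConfigError):
            cp.marker_rpkm(np.array([1]), np.array([0]), 1e6)
        with pytest.raises(InvalidConfigError):
            cp.marker_rpkm(np.array([1]), np.array([100]), 0)
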