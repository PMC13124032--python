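"""Welch t, peri-event windows, composite merging, window scan, sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nof1gest import (
    EventRecord,
    event_window_test,
    matched_symptom_pairs,
    merge_overlapping_events,
    sample_qualifying_events,
    tile_windows,
    variability_flag,
    welch_t,
    window_scan,
)
from nof1gest.events import SKIP_BASELINE, SKIP_PERI, EventWindowTest


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0

    def test_hand_computed(self):
        res = welch_t([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.df == pytest.approx(4.0)

    def test_zero_variance_equal_means(self):
        res = welch_t([5.0, 5.0], [5.0, 5.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_zero_variance_unequal_means_infinite(self):
        res = welch_t([5.0, 5.0], [4.0, 4.0])
        assert np.isinf(res.t) and res.t > 0 and res.p == 0.0

    def test_matches_scipy_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(0, rng.uniform(0.5, 3), rng.integers(3, 30))
            b = rng.normal(1, rng.uniform(0.5, 3), rng.integers(3, 30))
            ours = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-9)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejects = sum(
            welch_t(rng.normal(size=15), rng.normal(size=23)).p < 0.05
            for _ in range(2000))
        assert 0.035 <= rejects / 2000 <= 0.065


def _series(values_by_day, feature="hrv", pid="P1"):
    return pd.DataFrame({
        "participant_id": pid, "feature": feature,
        "day_rel_delivery": list(values_by_day),
        "value": list(values_by_day.values())})


def _event(day, pid="P1", label="fever"):
    return EventRecord(pid, label, "biweekly_symptom", day)


class TestEventWindowTest:
    def test_insufficient_baseline_skipped(self):
        # baseline window [-130, -107) holds only 1 day of data
        series = _series({d: 50.0 for d in range(-108, -85)})
        res = event_window_test(series, _event(-100))
        assert res.skipped and res.skipped_reason == SKIP_BASELINE

    def test_insufficient_peri_skipped(self):
        series = _series({d: 50.0 for d in range(-130, -104)})
        res = event_window_test(series, _event(-100))
        assert res.skipped_reason == SKIP_PERI

    def test_windows_and_orientation(self):
        # baseline [-130, -107) constant 50; peri [-107, -93] at 40
        vals = {d: 50.0 for d in range(-130, -107)}
        vals.update({d: 40.0 for d in range(-107, -92)})
        rng = np.random.default_rng(3)
        vals = {d: v + rng.normal(0, 1.0) for d, v in vals.items()}
        res = event_window_test(_series(vals), _event(-100))
        assert not res.skipped
        assert res.baseline_n == 23 and res.peri_n == 15
        assert res.t_statistic < 0          # peri minus baseline, shift down
        assert res.p_value < 0.001

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(300):
            vals = {d: rng.normal(50, 2) for d in range(-130, -92)}
            pvals.append(event_window_test(_series(vals), _event(-100)).p_value)
        assert 0.01 <= np.mean(np.array(pvals) < 0.05) <= 0.11

    def test_postpartum_days_never_enter_peri_window(self):
        vals = {d: 50.0 for d in range(-40, 8)}
        vals[-1] = 49.0     # avoid zero variance
        res = event_window_test(_series(vals), _event(-2))
        # peri window [-9, 0]: days 1..5 excluded by truncation
        assert res.peri_n == 10

    def test_missing_values_excluded_from_counts(self):
        vals = {d: 50.0 for d in range(-130, -92)}
        for d in range(-107, -99):
            vals[d] = np.nan
        res = event_window_test(_series(vals), _event(-100))
        assert res.peri_n == 15 - 8


class TestMergeOverlappingEvents:
    def _frame(self, days, pid="P1", label="fever"):
        return pd.DataFrame({
            "participant_id": pid, "label": label,
            "event_class": "biweekly_symptom", "day_rel_delivery": days})

    def test_disjoint_windows_untouched(self):
        merged = merge_overlapping_events(self._frame([-100, -80]))
        assert [e.day_rel_delivery for e in merged] == [-100, -80]
        assert all(e.n_members == 1 for e in merged)

    def test_overlapping_windows_merge_to_rounded_mean(self):
        merged = merge_overlapping_events(self._frame([-100, -95]))
        assert len(merged) == 1
        assert merged[0].day_rel_delivery == -97   # mean -97.5 toward delivery
        assert merged[0].n_members == 2

    def test_single_event_unchanged(self):
        merged = merge_overlapping_events(self._frame([-50]))
        assert len(merged) == 1
        assert merged[0].day_rel_delivery == -50

    def test_transitive_chain_merges_once(self):
        merged = merge_overlapping_events(self._frame([-120, -110, -100]))
        assert len(merged) == 1
        assert merged[0].day_rel_delivery == -110

    def test_composite_label_joins_members(self):
        df = pd.concat([self._frame([-100], label="fever"),
                        self._frame([-95], label="infection")])
        merged = merge_overlapping_events(df)
        assert merged[0].label == "fever+infection"

    def test_idempotent(self):
        df = self._frame([-120, -112, -90, -60, -52])
        once = merge_overlapping_events(df)
        again = merge_overlapping_events(pd.DataFrame({
            "participant_id": [e.participant_id for e in once],
            "label": [e.label for e in once],
            "event_class": [e.event_class for e in once],
            "day_rel_delivery": [e.day_rel_delivery for e in once]}))
        assert ([e.day_rel_delivery for e in again]
                == [e.day_rel_delivery for e in once])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-270, -1), min_size=1, max_size=10),
           st.randoms(use_true_random=False))
    def test_order_invariant(self, days, rnd):
        shuffled = list(days)
        rnd.shuffle(shuffled)
        a = merge_overlapping_events(self._frame(days))
        b = merge_overlapping_events(self._frame(shuffled))
        assert ([e.day_rel_delivery for e in a]
                == [e.day_rel_delivery for e in b])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-270, -1), min_size=2, max_size=10,
                    unique=True))
    def test_merged_events_have_disjoint_windows(self, days):
        merged = merge_overlapping_events(self._frame(days))
        ds = sorted(e.day_rel_delivery for e in merged)
        assert all(b - a > 14 for a, b in zip(ds, ds[1:]))


class TestWindowTiling:
    def test_covers_span_without_gaps_or_overlaps(self):
        wins = tile_windows((-270, 0), 14)
        assert wins[0][0] == -270 and wins[-1][1] == 0
        for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
            assert e1 == s2
        assert sum(e - s for s, e in wins) == 270

    def test_last_window_truncated(self):
        wins = tile_windows((-270, 0), 14)
        assert len(wins) == 20
        assert wins[-1] == (-4, 0)

    def test_every_day_maps_to_exactly_one_window(self):
        wins = tile_windows((-270, 0), 14)
        for day in range(-270, 0):
            hits = [i for i, (s, e) in enumerate(wins) if s <= day < e]
            assert len(hits) == 1


class TestVariabilityFlag:
    def test_identical_ts_not_flagged(self):
        sd, thr, flag = variability_flag([2.0, 2.0, 2.0])
        assert sd == 0.0 and thr == 0.0 and flag is False

    def test_hand_computed_outlier_flagged(self):
        t = [0.0] * 9 + [10.0]
        sd, thr, flag = variability_flag(t)
        assert sd == pytest.approx(3.162, abs=1e-3)
        assert thr == pytest.approx(6.325, abs=1e-3)
        assert flag is True

    def test_matches_bruteforce_pairwise_rule(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            t = rng.normal(0, 2, rng.integers(2, 13))
            sd, thr, flag = variability_flag(t)
            brute = any(abs(a - b) > thr
                        for i, a in enumerate(t) for b in t[i + 1:])
            assert flag == brute


def _scan_fixture(t_targets, rng):
    """Cohort where participant i's single event produces a strong shift."""
    obs, evs = [], []
    for i, _ in enumerate(t_targets):
        pid = f"P{i}"
        vals = {d: rng.normal(50, 1) for d in range(-140, -80)}
        obs.append(_series(vals, pid=pid))
        evs.append({"participant_id": pid, "label": "fever",
                    "event_class": "biweekly_symptom",
                    "day_rel_delivery": -100})
    return pd.concat(obs, ignore_index=True), pd.DataFrame(evs)


class TestWindowScan:
    def test_no_events_all_not_assessable(self):
        rng = np.random.default_rng(6)
        obs = _series({d: rng.normal(50, 1) for d in range(-270, 0)})
        empty = pd.DataFrame(columns=["participant_id", "label",
                                      "event_class", "day_rel_delivery"])
        scan = window_scan(obs, empty, "hrv")
        assert len(scan) == 20
        assert all(r.status == "not assessable" for r in scan)
        assert not any(r.high_variability for r in scan)

    def test_events_collected_into_correct_window(self):
        rng = np.random.default_rng(7)
        obs, evs = _scan_fixture([0, 0, 0], rng)
        scan = window_scan(obs, evs, "hrv")
        # day -100 lies in window [-102, -88)
        (win,) = [r for r in scan if r.start_day <= -100 < r.end_day]
        assert len(win.t_by_participant) == 3
        assert win.status == "ok"
        others = [r for r in scan if r is not win]
        assert all(len(r.t_by_participant) == 0 for r in others)

    def test_single_contributor_not_assessable(self):
        rng = np.random.default_rng(8)
        obs, evs = _scan_fixture([0], rng)
        scan = window_scan(obs, evs, "hrv")
        assert all(r.status == "not assessable" for r in scan)


class TestSampleQualifyingEvents:
    def _test(self, pid, day, p):
        t = EventWindowTest(_event(day, pid=pid), "hrv", 20, 15)
        t.p_value, t.t_statistic = p, 2.0
        return t

    def test_no_qualifying_events_empty(self):
        tests = [self._test("P1", -50, 0.8), self._test("P2", -60, 0.3)]
        assert sample_qualifying_events(tests, seed=0) == []

    def test_single_qualifier_always_selected(self):
        tests = [self._test("P1", -50, 0.01), self._test("P1", -90, 0.9)]
        sel = sample_qualifying_events(tests, seed=0)
        assert len(sel) == 1 and sel[0].event.day_rel_delivery == -50

    def test_seed_determinism_and_variation(self):
        tests = [self._test("P1", d, 0.01) for d in range(-200, -50, 15)]
        a = sample_qualifying_events(tests, seed=5)
        b = sample_qualifying_events(tests, seed=5)
        assert [t.event.day_rel_delivery for t in a] == \
            [t.event.day_rel_delivery for t in b]
        picks = {sample_qualifying_events(tests, seed=s)[0]
                 .event.day_rel_delivery for s in range(10)}
        assert len(picks) > 1

    def test_skipped_tests_never_qualify(self):
        t = self._test("P1", -50, 0.01)
        t.skipped_reason = SKIP_PERI
        assert sample_qualifying_events([t], seed=0) == []


class TestMatchedSymptomPairs:
    def _events(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "label",
                                           "event_class", "day_rel_delivery"])

    def test_no_shared_labels_empty(self):
        evs = self._events([("P1", "fever", "biweekly_symptom", -100),
                            ("P2", "infection", "adverse_event", -100)])
        assert matched_symptom_pairs(evs).empty

    def test_same_label_same_window_one_pair(self):
        evs = self._events([("P1", "fever", "biweekly_symptom", -100),
                            ("P2", "fever", "biweekly_symptom", -95)])
        pairs = matched_symptom_pairs(evs)
        assert len(pairs) == 1
        assert set(pairs.iloc[0][["participant_a", "participant_b"]]) == \
            {"P1", "P2"}

    def test_same_label_different_window_no_pair(self):
        evs = self._events([("P1", "fever", "biweekly_symptom", -100),
                            ("P2", "fever", "biweekly_symptom", -50)])
        assert matched_symptom_pairs(evs).empty

    def test_three_sharers_give_three_pairs(self):
        evs = self._events([(f"P{i}", "fever", "biweekly_symptom", -100 + i)
                            for i in range(3)])
        assert len(matched_symptom_pairs(evs)) == 3
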