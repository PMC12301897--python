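"""Two-threshold gap biomarker and longitudinal change-rate statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eegage import (ClassError, ThresholdPair, age_threshold_proxy,
                    change_rates, classify_gaps, optimize_thresholds,
                    transition_rate, transition_rates_all)
from eegage.biomarker import bacc_of_rule
from eegage.errors import PatternError


def _brute_force_best(gaps, labels):
    """Independent O(m^2) search over all candidate pairs."""
    gaps = np.asarray(gaps, float)
    labels = np.asarray(labels, bool)
    uniq = np.unique(gaps)
    cands = [-np.inf] + list((uniq[:-1] + uniq[1:]) / 2) + [np.inf]
    best = -1.0
    for lo, hi in itertools.combinations_with_replacement(cands, 2):
        pred_path = ~((gaps >= lo) & (gaps <= hi))
        sens = (pred_path & labels).sum() / labels.sum()
        spec = (~pred_path & ~labels).sum() / (~labels).sum()
        best = max(best, 0.5 * (sens + spec))
    return best


class TestOptimizeThresholds:
    def test_separable(self):
        gaps = np.array([-1.0, 0.0, 1.0, -10.0, 10.0])
        labels = np.array([False, False, False, True, True])
        pair, b = optimize_thresholds(gaps, labels)
        assert b == 1.0
        assert -10 < pair.lo < -1
        assert 1 < pair.hi < 10

    def test_never_below_chance_on_training_data(self):
        rng = np.random.default_rng(0)
        gaps = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        _, b = optimize_thresholds(gaps, labels)
        assert b >= 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gaps = rng.normal(size=12)
        labels = np.concatenate([np.zeros(6, bool), np.ones(6, bool)])
        rng.shuffle(labels)
        if labels.all() or not labels.any():
            return
        _, b = optimize_thresholds(gaps, labels)
        assert b == pytest.approx(_brute_force_best(gaps, labels))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        gaps = rng.normal(size=40)
        labels = rng.random(40) < 0.4
        _, b0 = optimize_thresholds(gaps, labels)
        for f in (np.exp, lambda x: x ** 3, lambda x: 2 * x + 7):
            _, b1 = optimize_thresholds(f(gaps), labels)
            assert b1 == pytest.approx(b0)

    def test_one_class_errors(self):
        with pytest.raises(ClassError):
            optimize_thresholds([1.0, 2.0], [True, True])


class TestClassifyGaps:
    def test_infinite_pair_all_np(self):
        pair = ThresholdPair(-np.inf, np.inf)
        assert not classify_gaps(pair, [-1e9, 0.0, 1e9]).any()

    def test_boundary_is_non_pathological(self):
        pair = ThresholdPair(-2.0, 3.0)
        out = classify_gaps(pair, [-2.0, 3.0, 3.0001])
        assert list(out) == [False, False, True]

    def test_roundtrip_reproduces_achieved_bacc(self):
        rng = np.random.default_rng(1)
        gaps = np.concatenate([rng.normal(0, 1, 30), rng.normal(4, 2, 30)])
        labels = np.concatenate([np.zeros(30, bool), np.ones(30, bool)])
        pair, b = optimize_thresholds(gaps, labels)
        assert bacc_of_rule(pair, gaps, labels) == pytest.approx(b)


class TestAgeThresholdProxy:
    def test_fully_separated(self):
        ages = np.array([20, 25, 30, 70, 75, 80.0])
        labels = np.array([False] * 3 + [True] * 3)
        cut, b = age_threshold_proxy(ages, labels)
        assert b == 1.0
        assert 30 < cut < 70

    def test_identical_distributions_near_chance(self):
        ages = np.tile(np.arange(30, 70, 1.0), 2)
        labels = np.array([False] * 40 + [True] * 40)
        _, b = age_threshold_proxy(ages, labels)
        assert b == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_single_cut_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(20, 80, 15)
        labels = rng.random(15) < 0.5
        if labels.all() or not labels.any():
            return
        _, b = age_threshold_proxy(ages, labels)
        uniq = np.unique(ages)
        cands = [-np.inf] + list((uniq[:-1] + uniq[1:]) / 2) + [np.inf]
        best = max(
            0.5 * (((ages > t) & labels).sum() / labels.sum()
                   + ((ages <= t) & ~labels).sum() / (~labels).sum())
            for t in cands)
        assert b == pytest.approx(best)


def _gap_df(rows):
    return pd.DataFrame(rows, columns=["subject_id", "date_days", "pathology",
                                       "gap_corrected"])


class TestChangeRates:
    def test_simple_slope(self):
        df = _gap_df([("s", 0, False, 2.0), ("s", 731, False, 4.0)])
        out = change_rates(df)
        assert out["rate"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_same_day_averaging(self):
        df = _gap_df([("s", 0, False, 1.0), ("s", 0, False, 3.0),
                      ("s", 365, False, 4.0)])
        out = change_rates(df)
        assert out["rate"].iloc[0] == pytest.approx(2.0, abs=5e-3)

    def test_single_date_skipped(self):
        df = _gap_df([("s", 0, False, 1.0), ("s", 0, False, 2.0)])
        assert len(change_rates(df)) == 0

    def test_grouped_by_status(self):
        df = _gap_df([("s", 0, False, 0.0), ("s", 365, False, 1.0),
                      ("s", 0, True, 0.0), ("s", 365, True, 3.0)])
        out = change_rates(df).set_index("pathology")
        assert out.loc[False, "rate"] == pytest.approx(1.0, abs=5e-3)
        assert out.loc[True, "rate"] == pytest.approx(3.0, abs=2e-2)

    def test_hand_oracle_five_subjects(self):
        rng = np.random.default_rng(3)
        rows, expected = [], {}
        for i in range(5):
            dates = np.sort(rng.choice(np.arange(0, 2000, 30), 3, replace=False))
            gaps = rng.normal(size=3)
            for d, g in zip(dates, gaps):
                rows.append((f"s{i}", int(d), False, float(g)))
            r1 = (gaps[1] - gaps[0]) / ((dates[1] - dates[0]) / 365.25)
            r2 = (gaps[2] - gaps[1]) / ((dates[2] - dates[1]) / 365.25)
            expected[f"s{i}"] = (r1 + r2) / 2
        out = change_rates(_gap_df(rows)).set_index("subject_id")
        for sid, exp in expected.items():
            assert out.loc[sid, "rate"] == pytest.approx(exp)


class TestTransitionRate:
    def test_simple(self):
        df = _gap_df([("s", 0, False, 0.0), ("s", 731, True, 3.0)])
        assert transition_rate(df) == pytest.approx(1.5, abs=2e-3)

    def test_same_day_averaging_each_side(self):
        df = _gap_df([("s", 0, False, 1.0), ("s", 0, False, 3.0),
                      ("s", 365, True, 5.0)])
        assert transition_rate(df) == pytest.approx(3.0, abs=2e-2)

    def test_flip_pair_sharing_date_errors(self):
        df = _gap_df([("s", 0, False, 0.0), ("s", 0, True, 3.0)])
        with pytest.raises(PatternError):
            transition_rate(df)

    def test_multi_flip_errors(self):
        df = _gap_df([("s", 0, False, 0.0), ("s", 10, True, 1.0),
                      ("s", 20, False, 2.0)])
        with pytest.raises(PatternError):
            transition_rate(df)

    def test_uses_flip_adjacent_pair_only(self):
        df = _gap_df([("s", 0, False, 0.0), ("s", 365, False, 9.0),
                      ("s", 731, True, 11.0)])
        # rate from (365, 9.0) -> (731, 11.0), not from the first recording
        assert transition_rate(df) == pytest.approx(2.0, abs=1e-2)

    def test_transition_rates_all_directions(self):
        rows = [("a", 0, False, 0.0), ("a", 365, True, 2.0),
                ("b", 0, True, 4.0), ("b", 365, False, 1.0),
                ("c", 0, False, 0.0), ("c", 365, False, 1.0)]
        out = transition_rates_all(_gap_df(rows)).set_index("subject_id")
        assert out.loc["a", "direction"] == "TNPP"
        assert out.loc["b", "direction"] == "TPNP"
        assert "c" not in out.index
        assert out.loc["a", "rate"] == pytest.approx(2.0, abs=4e-3)
        assert out.loc["b", "rate"] == pytest.approx(-3.0, abs=6e-3)
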