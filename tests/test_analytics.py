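import math

import numpy as np
import pandas as pd
import pytest

from nafc.analytics import (
    HickFit,
    ImplicitThresholdSeries,
    SATPoint,
    belief_gap,
    classify_dynamics,
    hicks_law_fit,
    iia_distances,
    implicit_threshold,
    mean_sat_curve,
    offset_decrease,
    renormalize_added_option,
    sat_points,
)
from nafc.belief_geometry import log_odds
from nafc.landscape import AcceptanceSet
from nafc.trial_engine import RewardEstimate


def _estimate(mean_error, mean_T, mean_reward=-1.0, std=0.5):
    return RewardEstimate(
        mean_reward=mean_reward,
        reward_std=std,
        mean_error=mean_error,
        mean_T=mean_T,
        n_trials=100,
        n_unterminated=0,
    )


def _accset(members, family="curve", cost_ratio=0.04):
    return AcceptanceSet(
        delta=0.02, r_max=-1.0, members=members, family=family, cost_ratio=cost_ratio
    )


class TestSatPoints:
    def test_singleton(self):
        acc = _accset({(0.7, 5.0, 0.0): _estimate(0.1, 8.0)})
        pts = sat_points({0.04: acc})
        assert len(pts) == 1
        assert pts[0].mean_T == 8.0
        assert pts[0].cost_ratio == 0.04

    def test_equal_reward_distinct_points(self):
        acc = _accset(
            {
                (0.7, 5.0, 0.0): _estimate(0.10, 8.0),
                (0.8, -5.0, 0.0): _estimate(0.06, 9.0),
            }
        )
        pts = sat_points({0.04: acc})
        assert len(pts) == 2
        assert {(p.mean_error, p.mean_T) for p in pts} == {(0.10, 8.0), (0.06, 9.0)}

    def test_manual_table(self):
        sets = {
            0.001: _accset({(0.9, 0.0, 0.0): _estimate(0.02, 20.0)}),
            0.1: _accset({(0.4, 0.0, 0.0): _estimate(0.3, 2.0)}),
        }
        pts = sat_points(sets)
        assert [(p.cost_ratio, p.mean_T) for p in pts] == [(0.001, 20.0), (0.1, 2.0)]

    def test_empty_set_yields_no_points(self):
        assert sat_points({0.04: _accset({})}) == []


class TestMeanSatCurve:
    def test_identical_families_share_mean(self):
        pts = [
            SATPoint(0.04, fam, 0.7, 0.0, 0.0, mean_error=0.1, mean_T=5.0)
            for fam in ("curve", "power", "oscil")
        ]
        curve = mean_sat_curve(pts)
        assert len(curve) == 1
        assert curve.mean_T[0] == pytest.approx(5.0)
        assert curve.mean_error[0] == pytest.approx(0.1)
        assert bool(curve.degenerate[0])

    def test_two_cost_ratios_manual_means(self):
        pts = [
            SATPoint(0.01, "curve", 0.8, 0.0, 0.0, 0.05, 10.0),
            SATPoint(0.01, "curve", 0.85, 5.0, 0.0, 0.07, 12.0),
            SATPoint(0.1, "curve", 0.5, 0.0, 0.0, 0.2, 3.0),
        ]
        curve = mean_sat_curve(pts)
        assert len(curve) == 2
        assert curve.mean_T.tolist() == pytest.approx([11.0, 3.0])
        assert curve.mean_error.tolist() == pytest.approx([0.06, 0.2])
        assert not curve.degenerate.any()

    def test_family_balanced_weighting(self):
        # duplicating one family's points changes only that family's mean,
        # which enters the curve as one vote among families
        base = [
            SATPoint(0.04, "curve", 0.7, 0.0, 0.0, 0.1, 4.0),
            SATPoint(0.04, "power", 0.7, 0.0, 0.0, 0.2, 8.0),
        ]
        dup = base + [SATPoint(0.04, "curve", 0.7, 0.0, 0.0, 0.1, 4.0)]
        c1, c2 = mean_sat_curve(base), mean_sat_curve(dup)
        assert c1.mean_T[0] == pytest.approx(c2.mean_T[0]) == pytest.approx(6.0)


class TestImplicitThreshold:
    def _df(self, Ts, beliefs):
        return pd.DataFrame(
            {"T": Ts, "crossing_belief": beliefs, "terminated": [True] * len(Ts)}
        )

    def test_constant_series_static(self):
        Ts = np.repeat([1, 2, 3, 4], 10)
        df = self._df(Ts, np.full(len(Ts), 0.9))
        s = implicit_threshold(df, min_count=5)
        assert s.category == "static"
        np.testing.assert_allclose(s.transformed_threshold, log_odds(0.9), atol=1e-12)

    def test_collapsing_constructed(self):
        Ts = np.repeat([1, 2, 3, 4, 5], 10)
        beliefs = np.repeat([0.95, 0.9, 0.85, 0.8, 0.75], 10)
        s = implicit_threshold(self._df(Ts, beliefs), min_count=5)
        assert s.category == "collapsing"

    def test_increasing_constructed(self):
        Ts = np.repeat([1, 2, 3, 4, 5], 10)
        beliefs = np.repeat([0.75, 0.8, 0.85, 0.9, 0.95], 10)
        s = implicit_threshold(self._df(Ts, beliefs), min_count=5)
        assert s.category == "increasing"

    def test_grouping_and_min_count(self):
        df = self._df([1] * 6 + [2] * 6 + [3] * 6 + [9] * 2, [0.8] * 18 + [0.99] * 2)
        s = implicit_threshold(df, min_count=5)
        assert s.times.tolist() == [1, 2, 3]  # sparse T=9 dropped
        assert s.counts.tolist() == [6, 6, 6]

    def test_empty_series_flagged(self):
        df = pd.DataFrame({"T": [5], "crossing_belief": [np.nan], "terminated": [False]})
        s = implicit_threshold(df)
        assert len(s.times) == 0
        assert s.category is None

    def test_transform_is_log_odds(self):
        df = self._df([1] * 5 + [2] * 5, [0.7] * 5 + [0.8] * 5)
        s = implicit_threshold(df, min_count=5)
        np.testing.assert_allclose(
            s.transformed_threshold, [log_odds(0.7), log_odds(0.8)], atol=1e-12
        )


class TestClassifyDynamics:
    def _series(self, times, values, counts=None):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        counts = np.ones(len(times), dtype=int) if counts is None else np.asarray(counts)
        from scipy.special import expit

        return ImplicitThresholdSeries(
            times=times,
            mean_crossing_belief=expit(values),
            transformed_threshold=values,
            counts=counts,
        )

    def test_exact_constant(self):
        assert classify_dynamics(self._series([1, 2, 3, 4], [2.0] * 4)) == "static"

    def test_exact_positive_slope(self):
        assert classify_dynamics(self._series([1, 2, 3, 4], [1.0, 1.5, 2.0, 2.5])) == "increasing"

    def test_exact_negative_slope(self):
        assert classify_dynamics(self._series([1, 2, 3, 4], [2.5, 2.0, 1.5, 1.0])) == "collapsing"

    def test_insufficient_points(self):
        with pytest.raises(ValueError):
            classify_dynamics(self._series([1, 2], [1.0, 1.0]))

    def test_noisy_zero_slope_operating_characteristics(self):
        # known-noise null series: static at >= 90% of replicates
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            times = np.arange(1, 21, dtype=float)
            vals = 2.0 + rng.normal(scale=0.1, size=20)
            if classify_dynamics(self._series(times, vals)) == "static":
                hits += 1
        assert hits >= 90


class TestHicksFit:
    def test_exact_log_linear(self):
        a, b = 5.0, 2.0
        data = {n: a + b * math.log(n) for n in (2, 3, 4, 6)}
        fit = hicks_law_fit(data)
        assert fit.a == pytest.approx(a, abs=1e-10)
        assert fit.b == pytest.approx(b, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_input(self):
        fit = hicks_law_fit({2: 7.0, 3: 7.0, 4: 7.0})
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_insufficient(self):
        with pytest.raises(ValueError):
            hicks_law_fit({2: 1.0, 3: 2.0})


class TestNormalizationIdentities:
    def test_renormalize_no_third_option(self):
        assert renormalize_added_option(0.6, 0.4, 0.0) == pytest.approx((0.6, 0.4, 0.0))

    def test_renormalize_substitution(self):
        out = renormalize_added_option(0.6, 0.4, 0.5)
        assert out == pytest.approx((0.4, 0.26667, 0.33333), abs=1e-5)

    def test_renormalize_sums_to_one(self, rng):
        for _ in range(100):
            p0 = rng.uniform(0, 1)
            p2 = rng.uniform(0, 1)
            assert sum(renormalize_added_option(p0, 1 - p0, p2)) == pytest.approx(1.0)

    def test_renormalize_precondition(self):
        with pytest.raises(ValueError):
            renormalize_added_option(0.6, 0.6, 0.1)

    def test_belief_gap_no_third(self):
        assert belief_gap(0.6, 0.4, 0.0) == pytest.approx(0.2)

    def test_belief_gap_substitution(self):
        assert belief_gap(0.6, 0.4, 0.5) == pytest.approx(0.13333, abs=1e-5)

    def test_belief_gap_decreasing_in_p2(self):
        gaps = [belief_gap(0.6, 0.4, p2) for p2 in np.linspace(0, 1, 11)]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_iia_distances_no_third(self):
        d_T, d = iia_distances(0.5, 0.0, 0.8)
        assert d_T == pytest.approx(0.3)
        assert d == pytest.approx(0.5 - 1 / 3)

    def test_iia_d_zero_at_third(self):
        _, d = iia_distances(1 / 3, 0.0, 0.5)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_iia_monotone_in_p2(self, rng):
        # finite differences at 100 random points
        for _ in range(100):
            Pi = rng.uniform(0.05, 0.95)
            P2 = rng.uniform(0.0, 0.9)
            T = rng.uniform(0.4, 0.95)
            h = 1e-6
            dT0, d0 = iia_distances(Pi, P2, T)
            dT1, d1 = iia_distances(Pi, P2 + h, T)
            assert dT1 > dT0
            assert d1 < d0

    @pytest.mark.parametrize("n,expected", [(2, 1 / 6), (3, 1 / 12)])
    def test_offset_decrease_values(self, n, expected):
        assert offset_decrease(n) == pytest.approx(expected, abs=1e-12)

    def test_offset_decrease_identity(self):
        for n in range(2, 101):
            assert offset_decrease(n) == pytest.approx(1 / n - 1 / (n + 1), abs=1e-15)

    def test_offset_decrease_invalid(self):
        with pytest.raises(ValueError):
            offset_decrease(1)

    def test_hickfit_r2_validation(self):
        with pytest.raises(ValueError):
            HickFit(a=1.0, b=1.0, r_squared=1.5)
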