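"""Robust trend fit, delay summaries, ANOVA, and pairwise t-tests."""

import numpy as np
import pytest
from scipy import stats as sps

from eegrt.io import EventTable
from eegrt.stats import (
    anova_oneway,
    huber_rlm,
    pairwise_ttests,
    summarize_delays,
)

from .oracles import ols_slope_intercept, welch_t_pvalue


class TestHuberRlm:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 10, 20)
        fit = huber_rlm(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.converged

    def test_clean_line_matches_ols(self):
        """Tiny Gaussian noise leaves nothing for the robust weights to do,
        so the robust slope matches ordinary least squares."""
        rng = np.random.default_rng(0)
        x = np.linspace(0, 100, 50)
        y = 2.0 * x + 1.0 + 1e-4 * rng.standard_normal(50)
        fit = huber_rlm(x, y)
        ols_slope, _ = ols_slope_intercept(x, y)
        assert fit.slope == pytest.approx(ols_slope, rel=1e-6)

    def test_large_tuning_constant_reduces_to_ols(self):
        """c -> infinity never downweights, so IRLS converges to OLS even on
        outlier-ridden data."""
        rng = np.random.default_rng(1)
        x = np.linspace(0, 50, 40)
        y = 0.5 * x + rng.standard_normal(40)
        y[7] += 40.0
        fit = huber_rlm(x, y, tuning_c=1e9)
        ols_slope, ols_icpt = ols_slope_intercept(x, y)
        assert fit.slope == pytest.approx(ols_slope, rel=1e-6)
        assert fit.intercept == pytest.approx(ols_icpt, rel=1e-6)

    def test_outlier_downweighted_and_slope_more_accurate(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 100, 50)
        true_slope = 0.3
        y = true_slope * x + 0.5 + 0.5 * rng.standard_normal(50)
        y[45] += 60.0  # gross outlier
        robust = huber_rlm(x, y)
        ols_slope, _ = ols_slope_intercept(x, y)
        assert abs(robust.slope - true_slope) < abs(ols_slope - true_slope)
        assert robust.weights[45] < 1.0
        assert np.all((robust.weights > 0) & (robust.weights <= 1))

    def test_matches_statsmodels_rlm(self):
        """Cross-check against the established IRLS implementation."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        x = np.linspace(0, 7200, 48)
        y = 0.6 + 1e-5 * x + 0.1 * rng.standard_normal(48)
        y[10] += 1.5
        ours = huber_rlm(x, y)
        theirs = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT()).fit()
        assert ours.slope == pytest.approx(theirs.params[1], rel=1e-4)
        assert ours.intercept == pytest.approx(theirs.params[0], rel=1e-4)

    def test_planted_drift_recovered(self):
        """A 1e-5 s/s drift over a 2-h session is recovered within 20%
        (averaged over 50 seeds)."""
        slopes = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            x = np.sort(rng.uniform(0, 7200, 48))
            y = 0.55 + 1e-5 * x + 0.02 * rng.standard_normal(48)
            slopes.append(huber_rlm(x, y).slope)
        assert np.mean(slopes) == pytest.approx(1e-5, rel=0.2)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            huber_rlm(np.ones(10), np.arange(10.0))

    def test_non_convergence_raises_with_trace(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 1, 30)
        y = rng.standard_normal(30) * 5
        with pytest.raises(RuntimeError, match="converge"):
            huber_rlm(x, y, max_iter=1)


class TestSummarizeDelays:
    def _events(self, delays, onsets=None):
        delays = np.asarray(delays, dtype=float)
        if onsets is None:
            onsets = 150.0 * np.arange(1, len(delays) + 1)
        return EventTable(cue_onset_s=onsets, response_s=onsets + delays)

    def test_order_statistics(self):
        s = summarize_delays(self._events([0.5, 0.4, 0.6]))
        assert (s.min_s, s.median_s, s.max_s) == pytest.approx((0.4, 0.5, 0.6))
        assert s.n_epochs == 3
        assert s.min_s <= s.median_s <= s.max_s

    def test_constant_delays_have_zero_sd_and_slope(self):
        s = summarize_delays(self._events([0.5] * 10))
        assert s.sd_s == 0.0
        assert s.slope_s_per_s == 0.0

    def test_sd_uses_n_minus_one(self):
        d = [0.4, 0.5, 0.6, 0.7]
        s = summarize_delays(self._events(d))
        assert s.sd_s == pytest.approx(np.std(d, ddof=1))


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        g = np.array([0.1, 0.2, 0.3])
        f_stat, p = anova_oneway([g, g.copy(), g.copy()])
        assert f_stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_hand_computed_sums_of_squares(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([6.0, 7, 8])]
        f_stat, p = anova_oneway(groups)
        # independent arithmetic: group means 2,3,7; grand mean 4
        ss_between = 3 * ((2 - 4) ** 2 + (3 - 4) ** 2 + (7 - 4) ** 2)  # 42
        ss_within = 6.0  # each group contributes 2
        f_expected = (ss_between / 2) / (ss_within / 6)
        assert f_stat == pytest.approx(f_expected, abs=1e-9)
        assert p == pytest.approx(sps.f.sf(f_expected, 2, 6), abs=1e-12)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.standard_normal(20) + mu for mu in (0.0, 0.2, 0.5)]
        f_stat, p = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert f_stat == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_equal_squared_pooled_t(self, rng):
        a, b = rng.standard_normal(15), rng.standard_normal(12) + 0.3
        f_stat, _ = anova_oneway([a, b])
        t_stat = sps.ttest_ind(a, b, equal_var=True).statistic
        assert f_stat == pytest.approx(t_stat**2, abs=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        groups = [rng.standard_normal(10) + mu for mu in (0.0, 0.4)]
        f0, _ = anova_oneway(groups)
        f_shift, _ = anova_oneway([g + 7.0 for g in groups])
        f_scale, _ = anova_oneway([3.0 * g for g in groups])
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)

    def test_degenerate_nonidentical_groups_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            anova_oneway([np.array([1.0, 1.0]), np.array([2.0, 2.0])])


class TestPairwiseTtests:
    def test_self_comparison_paired_gives_one(self):
        g = np.array([0.1, 0.2, 0.3, 0.4])
        table = pairwise_ttests({"a": g, "b": g.copy()}, paired=True)
        assert table.loc["a", "b"] == 1.0

    def test_hand_fixture_matches_direct_formula(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([3.0, 4, 5, 6])
        table = pairwise_ttests({"a": a, "b": b})
        assert table.loc["a", "b"] == pytest.approx(welch_t_pvalue(a, b), abs=1e-9)
        assert table.loc["b", "a"] == table.loc["a", "b"]
        assert np.isnan(table.loc["a", "a"])

    def test_length_mismatch_in_paired_mode(self):
        with pytest.raises(ValueError, match="equal lengths"):
            pairwise_ttests({"a": np.arange(4.0), "b": np.arange(5.0)}, paired=True)

    def test_type_i_error_calibration(self):
        """Two independent null samples: p < 0.05 should occur ~5% of the
        time over 500 simulations."""
        hits = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            a, b = rng.standard_normal(200), rng.standard_normal(200)
            if pairwise_ttests({"a": a, "b": b}).loc["a", "b"] < 0.05:
                hits += 1
        assert 0.03 <= hits / 500 <= 0.07

    def test_holm_correction_orders_correctly(self, rng):
        groups = {
            "a": rng.standard_normal(30),
            "b": rng.standard_normal(30) + 2.0,
            "c": rng.standard_normal(30),
        }
        raw = pairwise_ttests(groups)
        holm = pairwise_ttests(groups, correction="holm")
        assert (holm.fillna(0) >= raw.fillna(0) - 1e-15).all().all()
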