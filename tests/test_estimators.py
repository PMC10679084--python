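import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from leukomr.estimators import (
    cochran_q,
    egger,
    funnel_scatter_data,
    ivw,
    leave_one_out,
    or_ci,
    wald_p_from_or_ci,
    wald_ratio,
    weighted_median,
)
from leukomr.harmonize import harmonized_set_from_arrays

from conftest import make_hset


def hset_from_ratios(ratios, weights, beta_x=None):
    """Build a harmonized set whose Wald ratios and IVW weights are exactly
    the given values: beta_x = 1, beta_y = ratio, se_y = 1/sqrt(w)."""
    ratios = np.asarray(ratios, dtype=float)
    weights = np.asarray(weights, dtype=float)
    j = len(ratios)
    bx = np.ones(j) if beta_x is None else np.asarray(beta_x, dtype=float)
    return harmonized_set_from_arrays(
        [f"rs{i}" for i in range(j)],
        bx, np.full(j, 0.01),
        ratios * bx, np.abs(bx) / np.sqrt(weights),
    )


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,theta,se",
        [(0.2, 0.1, 0.02, 0.5, 0.1), (0.2, 0.0, 0.02, 0.0, 0.1),
         (-0.1, 0.05, 0.01, -0.5, 0.1)],
    )
    def test_first_order_ratio(self, bx, by, sy, theta, se):
        class Row:
            beta_x, beta_y, se_x, se_y, snp_id = bx, by, 0.01, sy, "rs1"

        r = wald_ratio(Row)
        assert r.theta_j == pytest.approx(theta)
        assert r.se_j == pytest.approx(se)

    def test_zero_beta_x_rejected(self):
        class Row:
            beta_x, beta_y, se_x, se_y, snp_id = 0.0, 0.1, 0.01, 0.02, "rs1"

        with pytest.raises(ValueError):
            wald_ratio(Row)

    def test_second_order_se_exceeds_first_order(self):
        class Row:
            beta_x, beta_y, se_x, se_y, snp_id = 0.2, 0.1, 0.05, 0.02, "rs1"

        assert wald_ratio(Row, second_order=True).se_j > wald_ratio(Row).se_j


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        h = hset_from_ratios([0.4], [25.0])
        est, het = ivw(h, model="fixed")
        assert est.theta == pytest.approx(0.4)
        assert est.se == pytest.approx(1 / np.sqrt(25))
        assert het.pval == 1.0

    def test_identical_ratios_zero_heterogeneity(self):
        h = hset_from_ratios([0.2, 0.2, 0.2], [100, 25, 4])
        fixed, het = ivw(h, model="fixed")
        rand, _ = ivw(h, model="random")
        assert fixed.theta == pytest.approx(0.2)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert rand.dispersion == 1.0
        assert rand.se == pytest.approx(fixed.se)

    def test_matches_weighted_mean_oracle(self):
        ratios, weights = [0.1, 0.3, 0.5], [100.0, 25.0, 4.0]
        est, het = ivw(hset_from_ratios(ratios, weights), model="fixed")
        # independent closed-form oracle
        num = sum(w * t for w, t in zip(weights, ratios))
        den = sum(weights)
        theta_o = num / den
        q_o = sum(w * (t - theta_o) ** 2 for w, t in zip(weights, ratios))
        assert est.theta == pytest.approx(theta_o, rel=1e-12)
        assert est.se == pytest.approx(den ** -0.5, rel=1e-12)
        assert het.q == pytest.approx(q_o, rel=1e-12)

    def test_random_inflates_se_under_heterogeneity(self):
        h = hset_from_ratios([0.0, 0.2, 0.6, 1.0], [100, 100, 100, 100])
        fixed, het = ivw(h, model="fixed")
        rand, _ = ivw(h, model="random")
        assert rand.dispersion == pytest.approx(np.sqrt(het.q / 3))
        assert rand.se > fixed.se
        assert rand.theta == fixed.theta

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10), seed=st.integers(0, 50))
    def test_invariant_to_order_and_weight_rescale(self, scale, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.normal(0.3, 0.2, 6)
        weights = rng.uniform(1, 50, 6)
        base, _ = ivw(hset_from_ratios(ratios, weights), model="fixed")
        perm = rng.permutation(6)
        scrambled, _ = ivw(
            hset_from_ratios(ratios[perm], weights[perm] * scale), model="fixed"
        )
        assert scrambled.theta == pytest.approx(base.theta, rel=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            ivw(hset_from_ratios([], []))


class TestEgger:
    def test_exact_proportional_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = harmonized_set_from_arrays(
            ["a", "b", "c", "d"], bx, np.full(4, 0.01), 0.3 * bx, np.full(4, 0.05)
        )
        res = egger(h)
        assert res.slope.theta == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = harmonized_set_from_arrays(
            ["a", "b", "c", "d"], bx, np.full(4, 0.01),
            0.1 + 0.3 * bx, np.full(4, 0.05)
        )
        res = egger(h)
        assert res.intercept == pytest.approx(0.1, abs=1e-12)
        assert res.slope.theta == pytest.approx(0.3, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        bx = rng.uniform(0.05, 0.5, 8)
        by = 0.05 + 0.4 * bx + rng.normal(0, 0.02, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        h = harmonized_set_from_arrays(
            [f"s{i}" for i in range(8)], bx, np.full(8, 0.01), by, sy
        )
        res = egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-9)
        assert res.slope.theta == pytest.approx(fit.params[1], rel=1e-9)
        # statsmodels scales by RSS/(J-2) without the floor; here the fit is
        # noisy enough that the dispersion exceeds 1, so SEs agree too
        if res.slope.dispersion > 1:
            assert res.slope.se == pytest.approx(fit.bse[1], rel=1e-9)
            assert res.intercept_pval == pytest.approx(fit.pvalues[0], rel=1e-9)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.5, 6)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.02, 6)
        sy = np.full(6, 0.03)
        h1 = harmonized_set_from_arrays(list("abcdef"), bx, np.full(6, 0.01), by, sy)
        flip = np.array([1, -1, 1, -1, 1, -1.0])
        h2 = harmonized_set_from_arrays(
            list("abcdef"), bx * flip, np.full(6, 0.01), by * flip, sy
        )
        r1, r2 = egger(h1), egger(h2)
        assert r2.slope.theta == pytest.approx(r1.slope.theta, rel=1e-12)
        assert r2.intercept == pytest.approx(r1.intercept, rel=1e-12)

    def test_slope_with_zero_intercept_equals_ivw_fixed(self):
        # constrained refit: weighted through-origin regression == IVW-fixed
        h = make_hset(j=8, seed=6)
        bx = h.rows["beta_x"].to_numpy()
        by = h.rows["beta_y"].to_numpy()
        w = 1 / h.rows["se_y"].to_numpy() ** 2
        constrained = np.sum(w * bx * by) / np.sum(w * bx**2)
        est, _ = ivw(h, model="fixed")
        assert constrained == pytest.approx(est.theta, rel=1e-12)

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError):
            egger(hset_from_ratios([0.1, 0.2], [1, 1]))


class TestWeightedMedian:
    def test_equal_weights_middle_order_statistic(self):
        est = weighted_median(hset_from_ratios([0.1, 0.2, 0.9], [5, 5, 5]), seed=1)
        assert est.theta == pytest.approx(0.2)

    def test_dominant_instrument_pulls_estimate(self):
        est = weighted_median(
            hset_from_ratios([0.1, 0.2, 0.9], [10, 1, 1]), seed=1
        )
        assert abs(est.theta - 0.1) < abs(est.theta - 0.2)

    def test_matches_cumulative_weight_oracle(self):
        ratios = [0.05, 0.20, 0.40, 0.80]
        weights = [4.0, 1.0, 2.0, 3.0]
        est = weighted_median(hset_from_ratios(ratios, weights), seed=1)
        # hand oracle: sort, s_k = (cum - w/2)/total, linear interpolation
        order = np.argsort(ratios)
        t = np.asarray(ratios)[order]
        w = np.asarray(weights)[order]
        s = (np.cumsum(w) - w / 2) / np.sum(w)
        lo = np.searchsorted(s, 0.5) - 1
        expected = t[lo] + (t[lo + 1] - t[lo]) * (0.5 - s[lo]) / (s[lo + 1] - s[lo])
        assert est.theta == pytest.approx(expected, rel=1e-12)

    def test_equal_weights_odd_j_equals_sample_median(self):
        rng = np.random.default_rng(7)
        ratios = rng.normal(0.3, 0.1, 9)
        est = weighted_median(hset_from_ratios(ratios, np.full(9, 3.0)), seed=1)
        assert est.theta == pytest.approx(np.median(ratios), rel=1e-9)

    def test_bootstrap_se_reproducible_and_seeded(self):
        h = make_hset(j=12, seed=8)
        a = weighted_median(h, n_boot=500, seed=42)
        b = weighted_median(h, n_boot=500, seed=42)
        c = weighted_median(h, n_boot=500, seed=43)
        assert a.se == b.se
        assert a.se != c.se

    def test_small_bootstrap_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            weighted_median(make_hset(j=5), n_boot=50, seed=1)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        from leukomr.estimators import RatioEstimate

        ratios = [RatioEstimate(f"s{i}", 0.3, 0.1) for i in range(4)]
        res = cochran_q(ratios, 0.3)
        assert res.q == pytest.approx(0.0)
        assert res.pval == pytest.approx(1.0)

    def test_two_point_arithmetic(self):
        from leukomr.estimators import RatioEstimate

        ratios = [RatioEstimate("a", 0.0, 1.0), RatioEstimate("b", 1.0, 1.0)]
        res = cochran_q(ratios, 0.5)
        assert res.q == pytest.approx(0.5)
        assert res.df == 1

    def test_null_rejection_rate_calibrated(self):
        # homogeneous instruments: Q ~ chi2(J-1), so 5% rejections
        rng = np.random.default_rng(9)
        n_reps, j = 2000, 10
        rejections = 0
        from leukomr.estimators import RatioEstimate

        for _ in range(n_reps):
            se = rng.uniform(0.05, 0.2, j)
            theta = rng.normal(0.3, se)
            ratios = [
                RatioEstimate(f"s{i}", theta[i], se[i]) for i in range(j)
            ]
            w = 1 / se**2
            pooled = np.sum(w * theta) / np.sum(w)
            if cochran_q(ratios, pooled).pval < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_reps < 0.07


class TestLeaveOneOut:
    def test_homogeneous_ratios_all_equal(self):
        h = hset_from_ratios([0.3, 0.3, 0.3, 0.3], [10, 20, 30, 40])
        table = leave_one_out(h)
        assert len(table) == 4
        np.testing.assert_allclose(table["theta"], 0.3)

    def test_outlier_exclusion_moves_estimate_most(self):
        h = hset_from_ratios([0.3, 0.31, 0.29, 0.30, 2.0], [10, 10, 10, 10, 10])
        table = leave_one_out(h)
        full, _ = ivw(h, model="random")
        shifts = (table["theta"] - full.theta).abs()
        assert table.loc[shifts.idxmax(), "excluded_snp"] == "rs4"

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            leave_one_out(hset_from_ratios([0.1, 0.2], [1, 1]))


class TestORScale:
    def test_null_theta_gives_unit_or(self):
        o, lo, hi = or_ci(0.0, 0.1)
        assert o == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric on log scale

    def test_exp_identity(self):
        o, _, _ = or_ci(np.log(1.58), 0.2)
        assert o == pytest.approx(1.58)

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            or_ci(0.1, 0.1, level=1.5)

    def test_round_trip_with_wald_p(self):
        theta, se = 0.25, 0.08
        o, lo, hi = or_ci(theta, se)
        p = wald_p_from_or_ci(o, lo, hi)
        assert p == pytest.approx(2 * sps.norm.sf(abs(theta / se)), rel=1e-9)

    def test_unit_or_gives_p_one(self):
        assert wald_p_from_or_ci(1.0, 0.8, 1.25) == pytest.approx(1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            wald_p_from_or_ci(-1.0, 0.5, 2.0)


class TestPlotData:
    def test_tables_have_one_row_per_instrument(self, hset10):
        est, _ = ivw(hset10, model="random")
        data = funnel_scatter_data(hset10, [est], egger_result=egger(hset10))
        assert len(data["funnel"]) == len(hset10)
        assert len(data["scatter"]) == len(hset10)
        ivw_line = data["lines"].set_index("method").loc["IVW-random"]
        assert ivw_line["intercept"] == 0.0
        egger_line = data["lines"].set_index("method").loc["Egger"]
        assert egger_line["intercept"] != 0.0

    def test_funnel_precision_is_reciprocal_se(self, hset10):
        data = funnel_scatter_data(hset10)
        se_j = hset10.rows["se_y"] / hset10.rows["beta_x"].abs()
        np.testing.assert_allclose(data["funnel"]["precision"], 1 / se_j)
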