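import numpy as np
import pytest

from leukomr.estimators import ivw
from leukomr.gwas_io import LDMatrix
from leukomr.harmonize import harmonized_set_from_arrays
from leukomr.instruments import SelectionConfig
from leukomr.mvmr import MVMRSet, build_mvmr_set, conditional_f, mvmr_ivw
from leukomr.simulate import SimConfig, simulate_multi

from conftest import make_stats


def small_mvset(j=8, k=2, seed=0, theta=(0.3, -0.2), noise=0.02):
    rng = np.random.default_rng(seed)
    beta_x = rng.uniform(0.05, 0.4, size=(j, k))
    se_y = rng.uniform(0.02, 0.06, size=j)
    beta_y = beta_x @ np.asarray(theta[:k]) + rng.normal(0, noise, j)
    return MVMRSet(
        exposure_names=[f"exp{i+1}" for i in range(k)],
        snp_ids=[f"rs{i}" for i in range(j)],
        beta_x=beta_x,
        se_x=np.full((j, k), 0.01),
        beta_y=beta_y,
        se_y=se_y,
    )


class TestBuildSet:
    def _exposure(self, name, sig_ids, all_ids, seed=0):
        rng = np.random.default_rng(seed)
        n = len(all_ids)
        return make_stats(
            trait=name,
            snp_id=all_ids,
            chrom=["1"] * n,
            pos=[100 + 200_000 * i for i in range(n)],
            effect_allele=["A"] * n, other_allele=["G"] * n,
            eaf=[0.3] * n,
            beta=rng.normal(0.2, 0.02, n).tolist(),
            se=[0.01] * n,
            pval=[1e-9 if s in sig_ids else 0.5 for s in all_ids],
            n=[1000] * n,
        )

    def test_union_of_significant_sets(self):
        ids = [f"rs{i}" for i in range(8)]
        e1 = self._exposure("e1", ids[:3], ids, seed=1)
        e2 = self._exposure("e2", ids[3:6], ids, seed=2)
        outcome = self._exposure("ra", [], ids, seed=3)
        mvset = build_mvmr_set([e1, e2], outcome, SelectionConfig())
        assert sorted(mvset.snp_ids) == ids[:6]
        assert mvset.shape == (6, 2)

    def test_snp_missing_in_outcome_dropped_and_counted(self):
        ids = [f"rs{i}" for i in range(8)]
        e1 = self._exposure("e1", ids[:3], ids, seed=1)
        e2 = self._exposure("e2", ids[3:6], ids, seed=2)
        outcome = self._exposure("ra", [], ids, seed=3).subset(ids[1:])
        mvset = build_mvmr_set([e1, e2], outcome, SelectionConfig())
        assert "rs0" not in mvset.snp_ids
        assert mvset.n_dropped_missing == 1

    def test_joint_clump_keeps_min_p_across_exposures(self):
        # two linked SNPs: rs0 best in e1 (1e-9), rs1 better in e2 (1e-12)
        ids = ["rs0", "rs1"]
        e1 = self._exposure("e1", [], ids, seed=1)
        e1.records.loc[0, "pval"] = 1e-9
        e1.records.loc[1, "pval"] = 1e-8
        e2 = self._exposure("e2", [], ids, seed=2)
        e2.records.loc[1, "pval"] = 1e-12
        extra = [f"rx{i}" for i in range(3)]
        all_ids = ids + extra
        e1b = self._exposure("e1", [], all_ids, seed=1)
        e1b.records.loc[:1, "pval"] = [1e-9, 1e-8]
        e1b.records.loc[2:, "pval"] = 1e-10
        e2b = self._exposure("e2", [], all_ids, seed=2)
        e2b.records.loc[1, "pval"] = 1e-12
        e2b.records.loc[2:, "pval"] = 1e-10
        outcome = self._exposure("ra", [], all_ids, seed=3)
        ld = LDMatrix(ids, np.array([[1.0, 0.9], [0.9, 1.0]]))
        # put the two linked SNPs within one window
        for e in (e1b, e2b, outcome):
            e.records.loc[1, "pos"] = 200
        mvset = build_mvmr_set([e1b, e2b], outcome, SelectionConfig(), ld)
        assert "rs1" in mvset.snp_ids  # min-p winner across exposures
        assert "rs0" not in mvset.snp_ids


class TestEstimator:
    def test_k1_reduces_to_univariable_ivw(self):
        rng = np.random.default_rng(3)
        j = 10
        bx = rng.uniform(0.05, 0.4, j)
        sy = rng.uniform(0.02, 0.06, j)
        by = 0.3 * bx + rng.normal(0, 0.03, j)
        mvset = MVMRSet(["e1"], [f"rs{i}" for i in range(j)],
                        bx[:, None], np.full((j, 1), 0.01), by, sy)
        mv = mvmr_ivw(mvset)
        h = harmonized_set_from_arrays(
            [f"rs{i}" for i in range(j)], bx, np.full(j, 0.01), by, sy
        )
        uni, _ = ivw(h, model="random" if mv.dispersion > 1 else "fixed")
        assert mv.theta[0] == pytest.approx(uni.theta, rel=1e-10)
        assert mv.se[0] == pytest.approx(uni.se, rel=1e-10)

    def test_exact_linear_outcome_recovered(self):
        beta_x = np.array([[0.1, 0.0], [0.2, 0.0], [0.0, 0.1],
                           [0.0, 0.2], [0.15, 0.15]])
        beta_y = beta_x @ np.array([0.5, -0.3])
        mvset = MVMRSet(["e1", "e2"], [f"s{i}" for i in range(5)],
                        beta_x, np.full((5, 2), 0.01),
                        beta_y, np.full(5, 0.05))
        mv = mvmr_ivw(mvset)
        np.testing.assert_allclose(mv.theta, [0.5, -0.3], atol=1e-12)
        assert mv.q_a == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_gls_oracle(self):
        import statsmodels.api as sm

        mvset = small_mvset(j=6, seed=5)
        mv = mvmr_ivw(mvset)
        fit = sm.WLS(mvset.beta_y, mvset.beta_x, weights=1 / mvset.se_y**2).fit()
        np.testing.assert_allclose(mv.theta, fit.params, rtol=1e-9)
        if mv.dispersion > 1:
            np.testing.assert_allclose(mv.se, fit.bse, rtol=1e-9)

    def test_rank_deficiency_names_collinear_exposures(self):
        mvset = small_mvset(j=8, seed=6)
        mvset.beta_x[:, 1] = 2 * mvset.beta_x[:, 0]
        with pytest.raises(ValueError, match="exp1.*exp2|exp2.*exp1"):
            mvmr_ivw(mvset)

    def test_zero_column_errors_rather_than_silently_dropping(self):
        mvset = small_mvset(j=8, seed=7)
        mvset.beta_x[:, 1] = 0.0
        with pytest.raises(ValueError, match="exp2"):
            mvmr_ivw(mvset)

    def test_invariance_row_order_and_row_sign_flips(self):
        mvset = small_mvset(j=8, seed=8)
        base = mvmr_ivw(mvset).theta
        rng = np.random.default_rng(0)
        perm = rng.permutation(8)
        signs = rng.choice([-1.0, 1.0], 8)
        flipped = MVMRSet(
            mvset.exposure_names,
            [mvset.snp_ids[i] for i in perm],
            mvset.beta_x[perm] * signs[perm, None],
            mvset.se_x[perm],
            mvset.beta_y[perm] * signs[perm],
            mvset.se_y[perm],
        )
        np.testing.assert_allclose(mvmr_ivw(flipped).theta, base, rtol=1e-9)


class TestConditionalF:
    def test_independent_exposure_close_to_univariable_f(self):
        rng = np.random.default_rng(9)
        j = 400
        gamma = rng.normal(0, 0.03, size=(j, 2))  # independent columns
        se_x = np.full((j, 2), 0.003)
        beta_x = gamma + rng.normal(0, se_x)
        mvset = MVMRSet(["e1", "e2"], [f"rs{i}" for i in range(j)],
                        beta_x, se_x,
                        beta_x[:, 0] * 0.3, np.full(j, 0.05))
        cf = conditional_f(mvset)
        univ_f = np.mean((beta_x[:, 0] / se_x[:, 0]) ** 2)
        assert cf["e1"] == pytest.approx(univ_f, rel=0.1)

    def test_duplicated_column_collapses_to_zero(self):
        rng = np.random.default_rng(10)
        j = 50
        col = rng.normal(0, 0.05, j)
        beta_x = np.column_stack([col, col])
        mvset = MVMRSet(["e1", "e2"], [f"rs{i}" for i in range(j)],
                        beta_x, np.full((j, 2), 0.01),
                        col * 0.3, np.full(j, 0.05))
        cf = conditional_f(mvset)
        assert cf["e1"] == pytest.approx(0.0, abs=1e-12)
        assert cf["e2"] == pytest.approx(0.0, abs=1e-12)

    def test_outputs_nonnegative_one_per_exposure(self):
        mvset = small_mvset(j=10, k=2, seed=11)
        cf = conditional_f(mvset)
        assert set(cf) == {"exp1", "exp2"}
        assert all(v >= 0 for v in cf.values())


class TestSimulatedRecovery:
    def test_duplicate_exposure_in_simulation_errors_on_rank(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])  # perfectly correlated pair
        with pytest.raises(ValueError):
            exposures, outcome, _, _ = simulate_multi(
                SimConfig(n_snp=30, seed=1), 2, corr, np.array([0.3, 0.0])
            )

    def test_direct_effect_recovery_with_correlated_exposures(self):
        # five correlated exposures, only the first with a direct effect:
        # MVMR centers exposure 1 on the truth and the rest on zero
        from leukomr.studies import mvmr_recovery_study

        res = mvmr_recovery_study(n_reps=500, seed=0)
        assert abs(res["mean_theta_causal"] - 0.3) <= 3 * res["mc_se_causal"]
        assert res["mean_abs_theta_null"] < 0.01
        assert 0.92 <= res["coverage_causal"] <= 0.97
        assert 0.92 <= res["coverage_null"] <= 0.97

    def test_truth_vector_length_k(self):
        corr = np.eye(3)
        _, _, _, truth = simulate_multi(
            SimConfig(n_snp=30, seed=2), 3, corr, np.array([0.3, 0.0, 0.0])
        )
        assert np.asarray(truth.theta_true).shape == (3,)
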