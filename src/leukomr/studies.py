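"""Monte-Carlo operating-characteristic studies for the MR pipeline.

Each study fixes a generating scenario, replicates it under a seed, and
summarises how the estimators behave: type-I error under the null,
bias/coverage under a true effect, robustness of the weighted median to
directional pleiotropy, MR-PRESSO detection and false-flag rates, and the
end-to-end six-exposure design. The tests and the acceptance script both
call these functions, so the numbers they report are always recomputed.

Problem sizes (replicate counts, instrument counts, GWAS sizes) are the
package's study design; see docs/methods.md for the rationale behind each.
"""

from __future__ import annotations

import numpy as np

from .estimators import _weighted_median_point, egger, ivw
from .harmonize import harmonize, harmonized_set_from_arrays
from .instruments import SelectionConfig, select_instruments
from .mvmr import MVMRSet, mvmr_ivw
from .presso import presso_outliers
from .report import bonferroni_threshold
from .simulate import SimConfig, simulate_multi, simulate_pair


def _draw_instrument_arrays(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Draw one replicate of post-selection instrument summary data.

    Same closed forms as the file-level generator (maf ~ U, γ ~ N(0, σ²),
    se = 1/√(2·maf(1−maf)·n), estimates Gaussian around truth), without the
    allele/file bookkeeping — the studies operate on harmonized arrays.
    """
    j = cfg.n_snp
    maf = rng.uniform(*cfg.maf_range, size=j)
    gamma = rng.normal(0.0, cfg.sigma_gamma, size=j)
    if cfg.orient_gamma:
        gamma = np.abs(gamma)
    alpha = np.zeros(j)
    invalid = rng.random(j) < cfg.pi_invalid
    k = int(invalid.sum())
    if k:
        alpha[invalid] = rng.normal(cfg.mu_alpha, cfg.tau_alpha, size=k)
    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exposure_samples)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_outcome_samples)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.theta_true * gamma + alpha, se_y)
    return {
        "snp_id": [f"rs{i}" for i in range(j)],
        "beta_x": beta_x, "se_x": se_x,
        "beta_y": beta_y, "se_y": se_y,
        "gamma": gamma, "alpha": alpha, "invalid": invalid,
    }


def _hset(d: dict):
    return harmonized_set_from_arrays(
        d["snp_id"], d["beta_x"], d["se_x"], d["beta_y"], d["se_y"]
    )


def null_calibration(
    n_reps: int = 1000, n_snp: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Rejection rates of the IVW (random-effects) test and the MR-Egger
    intercept test under the sharp null: θ = 0, no pleiotropy.

    Both should reject at ≈ the nominal level.
    """
    cfg = SimConfig(n_snp=n_snp, theta_true=0.0)
    rng = np.random.default_rng(seed)
    rej_ivw = rej_egger = 0
    for _ in range(n_reps):
        hset = _hset(_draw_instrument_arrays(cfg, rng))
        est, _ = ivw(hset, model="random")
        if est.pval < alpha:
            rej_ivw += 1
        if egger(hset).intercept_pval < alpha:
            rej_egger += 1
    return {
        "ivw_rejection_rate": rej_ivw / n_reps,
        "egger_intercept_rejection_rate": rej_egger / n_reps,
        "n_reps": n_reps,
        "n_snp": n_snp,
    }


def recovery_study(
    n_reps: int = 500,
    n_snp: int = 100,
    theta_true: float = 0.3,
    target_mean_f: float = 60.0,
    n_outcome: int = 10_000,
    seed: int = 0,
) -> dict:
    """Bias and 95% CI coverage of random-effects IVW under a true effect.

    σ_γ is set from the closed-form mean-F relation so the instruments have
    the requested strength; the outcome GWAS is sized so sampling error
    dominates the O(θ/F̄) weak-instrument attenuation of summary-data IVW
    (see methods note).
    """
    base = SimConfig()
    lo, hi = base.maf_range
    h2 = 2 * ((lo + hi) / 2 - (lo**2 + lo * hi + hi**2) / 3)
    sigma = float(np.sqrt((target_mean_f - 1) / (h2 * base.n_exposure_samples)))
    cfg = SimConfig(
        n_snp=n_snp,
        theta_true=theta_true,
        sigma_gamma=sigma,
        n_outcome_samples=n_outcome,
    )
    rng = np.random.default_rng(seed)
    thetas = np.empty(n_reps)
    covered = 0
    for b in range(n_reps):
        hset = _hset(_draw_instrument_arrays(cfg, rng))
        est, _ = ivw(hset, model="random")
        thetas[b] = est.theta
        lo_ci = np.log(est.ci_low)
        hi_ci = np.log(est.ci_high)
        if lo_ci <= theta_true <= hi_ci:
            covered += 1
    mean = float(thetas.mean())
    mc_se = float(thetas.std(ddof=1) / np.sqrt(n_reps))
    return {
        "theta_true": theta_true,
        "mean_theta": mean,
        "mc_se": mc_se,
        "abs_error_in_mc_ses": abs(mean - theta_true) / mc_se,
        "coverage": covered / n_reps,
        "n_reps": n_reps,
        "n_snp": n_snp,
    }


def robustness_study(
    n_reps: int = 200,
    n_snp: int = 100,
    theta_true: float = 0.3,
    pi_invalid: float = 0.4,
    mu_alpha: float = 0.03,
    tau_alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Bias of IVW vs the weighted median with directional pleiotropy.

    Instruments are oriented to the exposure-increasing allele (γ ≥ 0), the
    orientation in which same-sign pleiotropic effects push every affected
    Wald ratio the same way. The invalid fraction carries large positive
    direct effects on the outcome; the valid majority holds >50% of the
    weight, so the weighted median should stay near the truth while IVW is
    dragged upward. Matched seeds: both estimators see the same replicates.
    """
    cfg = SimConfig(
        n_snp=n_snp,
        theta_true=theta_true,
        pi_invalid=pi_invalid,
        mu_alpha=mu_alpha,
        tau_alpha=tau_alpha,
        orient_gamma=True,
    )
    rng = np.random.default_rng(seed)
    t_ivw = np.empty(n_reps)
    t_wm = np.empty(n_reps)
    for b in range(n_reps):
        d = _draw_instrument_arrays(cfg, rng)
        hset = _hset(d)
        t_ivw[b] = ivw(hset, model="random")[0].theta
        ratio = d["beta_y"] / d["beta_x"]
        w = (d["beta_x"] / d["se_y"]) ** 2
        t_wm[b] = _weighted_median_point(ratio, w)
    return {
        "theta_true": theta_true,
        "bias_ivw": float(t_ivw.mean() - theta_true),
        "bias_weighted_median": float(t_wm.mean() - theta_true),
        "n_reps": n_reps,
    }


def presso_power_study(
    n_runs: int = 200,
    n_clean_runs: int = 100,
    n_snp: int = 20,
    n_sim: int = 1000,
    outlier_scale: float = 10.0,
    seed: int = 0,
) -> dict:
    """MR-PRESSO outlier detection and false-flag rates.

    Each contaminated run injects one SNP whose outcome effect is shifted by
    ``outlier_scale`` × its standard error; detection means that SNP is
    Bonferroni-flagged. The false-flag rate is the per-SNP rate at which
    clean SNPs are flagged (pooled over the clean runs and the non-injected
    SNPs of contaminated runs); ``clean_empty_rate`` is the fraction of
    clean runs with an empty flag set.
    """
    cfg = SimConfig(n_snp=n_snp, theta_true=0.3)
    rng = np.random.default_rng(seed)
    detected = 0
    clean_flagged = 0
    clean_total = 0
    for _ in range(n_runs):
        d = _draw_instrument_arrays(cfg, rng)
        k = int(rng.integers(n_snp))
        d["beta_y"][k] += outlier_scale * d["se_y"][k]
        _, flagged = presso_outliers(
            _hset(d), n_sim=n_sim, seed=int(rng.integers(2**31))
        )
        if d["snp_id"][k] in flagged:
            detected += 1
        clean_flagged += len(flagged - {d["snp_id"][k]})
        clean_total += n_snp - 1
    empty_runs = 0
    for _ in range(n_clean_runs):
        d = _draw_instrument_arrays(cfg, rng)
        _, flagged = presso_outliers(
            _hset(d), n_sim=n_sim, seed=int(rng.integers(2**31))
        )
        clean_flagged += len(flagged)
        clean_total += n_snp
        if not flagged:
            empty_runs += 1
    return {
        "detection_rate": detected / n_runs,
        "false_flag_rate": clean_flagged / clean_total,
        "clean_empty_rate": empty_runs / n_clean_runs,
        "n_runs": n_runs,
        "n_clean_runs": n_clean_runs,
        "n_sim": n_sim,
    }


def end_to_end_study(
    n_reps: int = 100,
    n_exposures: int = 6,
    causal_index: int = 0,
    theta_causal: float = 0.3,
    n_snp: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """The full six-exposure design with one causal exposure.

    Each replicate simulates paired GWAS files per exposure, runs instrument
    selection (significance filter, clumping against the simulated LD
    sidecar, palindrome removal), harmonizes against the outcome, estimates
    with random-effects IVW and applies the Bonferroni threshold α/m.
    Success means exactly the causal exposure is flagged.
    """
    threshold = bonferroni_threshold(alpha, n_exposures)
    selection = SelectionConfig()
    root = np.random.SeedSequence(seed)
    exact = 0
    causal_flagged = 0
    for rep_ss in root.spawn(n_reps):
        child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in rep_ss.spawn(n_exposures)]
        flagged = set()
        for e in range(n_exposures):
            cfg = SimConfig(
                n_snp=n_snp,
                theta_true=theta_causal if e == causal_index else 0.0,
                seed=child_seeds[e],
            )
            exposure, outcome, ld, _ = simulate_pair(cfg)
            selected, _ = select_instruments(exposure, ld, selection)
            hset = harmonize(selected, outcome, drop_palindromes=True)
            est, _ = ivw(hset, model="random")
            if est.pval < threshold:
                flagged.add(e)
        if flagged == {causal_index}:
            exact += 1
        if causal_index in flagged:
            causal_flagged += 1
    return {
        "exact_recovery_rate": exact / n_reps,
        "causal_power": causal_flagged / n_reps,
        "n_reps": n_reps,
        "n_exposures": n_exposures,
    }


def mvmr_recovery_study(
    n_reps: int = 500,
    n_snp: int = 100,
    k_exposures: int = 5,
    rho: float = 0.5,
    theta_direct: float = 0.3,
    seed: int = 0,
) -> dict:
    """Direct-effect recovery for MVMR with correlated exposures.

    Only exposure 1 has a direct effect; exposures 2..K act on the outcome
    only through their correlation with exposure 1. MVMR should center
    exposure 1 on the truth and the rest on zero, with ≈95% CI coverage —
    the total-vs-direct contrast that separates univariable from
    multivariable MR.
    """
    corr = np.full((k_exposures, k_exposures), rho)
    np.fill_diagonal(corr, 1.0)
    direct = np.zeros(k_exposures)
    direct[0] = theta_direct
    root = np.random.SeedSequence(seed)
    est1 = np.empty(n_reps)
    est_others = np.empty((n_reps, k_exposures - 1))
    cover1 = cover_others = 0
    for b, ss in enumerate(root.spawn(n_reps)):
        cfg = SimConfig(
            n_snp=n_snp,
            frac_allele_swap=0.0,
            frac_strand_flip=0.0,
            frac_palindromic=0.0,
            seed=int(ss.generate_state(1)[0] % 2**31),
        )
        exposures, outcome, _, _ = simulate_multi(cfg, k_exposures, corr, direct)
        mvset = MVMRSet(
            exposure_names=[e.trait_name for e in exposures],
            snp_ids=exposures[0].snp_ids,
            beta_x=np.column_stack([e.records["beta"] for e in exposures]),
            se_x=np.column_stack([e.records["se"] for e in exposures]),
            beta_y=outcome.records["beta"].to_numpy(),
            se_y=outcome.records["se"].to_numpy(),
        )
        mv = mvmr_ivw(mvset)
        est1[b] = mv.theta[0]
        est_others[b] = mv.theta[1:]
        lo = np.log(mv.ci_low)
        hi = np.log(mv.ci_high)
        if lo[0] <= theta_direct <= hi[0]:
            cover1 += 1
        cover_others += int(np.sum((lo[1:] <= 0) & (0 <= hi[1:])))
    mc_se1 = float(est1.std(ddof=1) / np.sqrt(n_reps))
    return {
        "theta_direct": theta_direct,
        "mean_theta_causal": float(est1.mean()),
        "mc_se_causal": mc_se1,
        "mean_abs_theta_null": float(np.abs(est_others.mean(axis=0)).max()),
        "coverage_causal": cover1 / n_reps,
        "coverage_null": cover_others / (n_reps * (k_exposures - 1)),
        "n_reps": n_reps,
    }
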