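"""Synthetic GWAS summary-statistics generator with known truth.

The generator emulates the statistical structure the two-sample MR analysis
assumes, on the summary-data (Gaussian) approximation — no individual-level
genotypes:

* per-SNP effect-allele frequency maf ~ Uniform(maf_range);
* true SNP–exposure effects γ_j ~ Normal(0, σ_γ²) (optionally folded
  positive, the orientation in which directional pleiotropy is directional
  on the ratio scale);
* exposure estimate β̂_Xj ~ Normal(γ_j, se_Xj²) with the standard-error
  closed form se = 1/√(2·maf(1−maf)·n) of a standardized-trait GWAS;
* a fraction ``pi_invalid`` of SNPs violate the exclusion restriction with
  pleiotropic effects α_j ~ Normal(μ_α, τ_α²) (correlated with γ_j when
  ``inside_violated``, breaking InSIDE);
* outcome estimate β̂_Yj ~ Normal(θ·γ_j + α_j, se_Yj²) on the log-odds
  scale;
* alleles drawn with a configurable palindromic fraction; the outcome file
  is perturbed by allele-swap and strand-flip rates so harmonization has
  real work to do;
* an LD sidecar with constant within-block r² drives clumping. The summary
  statistics themselves are drawn independently across SNPs — the LD
  structure lives only in the sidecar (a documented simplification).

One master seed expands into named per-component streams, so varying one
component leaves the others bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .gwas_io import LDMatrix, SummaryStats, summary_stats_from_arrays

_P_FLOOR = 1e-300  # keep Wald p-values inside (0, 1] for very strong hits

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Generating parameters for one exposure/outcome pair.

    Defaults are sized to echo a large blood-trait GWAS feeding a disease
    outcome: a few hundred candidate instruments with mean F in the
    100–200 range, an exposure GWAS of half a million and an outcome GWAS
    of ~58k samples.
    """

    n_snp: int = 400
    n_exposure_samples: int = 500_000
    n_outcome_samples: int = 58_284
    theta_true: float = 0.3
    pi_invalid: float = 0.0
    mu_alpha: float = 0.0
    tau_alpha: float = 0.0
    sigma_gamma: float = 0.0275
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.2
    frac_strand_flip: float = 0.05
    frac_allele_swap: float = 0.2
    ld_block_size: int = 4
    ld_r2: float = 0.4
    inside_violated: bool = False
    orient_gamma: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_invalid", "frac_palindromic", "frac_strand_flip", "frac_allele_swap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.sigma_gamma <= 0:
            raise ValueError("sigma_gamma must be positive")
        if self.n_snp < 4:
            raise ValueError("n_snp must be at least 4")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.ld_r2 <= 1:
            raise ValueError("ld_r2 must lie in [0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class SimTruth:
    """The generating parameters retained for recovery tests."""

    theta_true: float | np.ndarray
    gamma_j: np.ndarray
    alpha_j: np.ndarray
    invalid_ids: set[str]
    expected_mean_f: float
    maf: np.ndarray = field(default=None, repr=False)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _positions(j: int, block: int) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome and bp position per SNP; LD blocks are runs of consecutive
    SNPs placed ~10 kb apart, distinct blocks 2 Mb apart on a rotating set
    of 22 chromosomes (so blocks never straddle a chromosome)."""
    idx = np.arange(j)
    b = idx // block
    chrom = (1 + b % 22).astype(str)
    pos = 1 + (b // 22) * 2_000_000 + (idx % block) * 10_000
    return chrom, pos


def _draw_alleles(j: int, frac_palindromic: float, rng) -> tuple[np.ndarray, np.ndarray]:
    pal = rng.random(j) < frac_palindromic
    ea = np.empty(j, dtype=object)
    oa = np.empty(j, dtype=object)
    pick_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    pick_n = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=j)
    for i in range(j):
        ea[i], oa[i] = (
            _PALINDROMIC_PAIRS[pick_p[i]] if pal[i] else _NONPALINDROMIC_PAIRS[pick_n[i]]
        )
    return ea, oa


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2 * sps.norm.sf(np.abs(beta / se)), _P_FLOOR)


def _ld_matrix(ids: list[str], chrom, pos, block: int, r2: float) -> LDMatrix:
    j = len(ids)
    mat = np.eye(j)
    if block > 1 and r2 > 0:
        b = np.arange(j) // block
        same = b[:, None] == b[None, :]
        mat = np.where(same, r2, 0.0)
        np.fill_diagonal(mat, 1.0)
    positions = {s: (c, int(p)) for s, c, p in zip(ids, chrom, pos)}
    return LDMatrix(ids, mat, positions)


def _perturb_outcome(ea, oa, beta, eaf, swap_mask, flip_mask):
    """Allele swaps negate beta and reflect eaf; strand flips complement the
    allele labels only (the effect is unchanged on the flipped strand)."""
    ea = ea.copy()
    oa = oa.copy()
    beta = beta.copy()
    eaf = eaf.copy()
    for i in np.nonzero(swap_mask)[0]:
        ea[i], oa[i] = oa[i], ea[i]
        beta[i] = -beta[i]
        eaf[i] = 1.0 - eaf[i]
    for i in np.nonzero(flip_mask)[0]:
        ea[i] = _COMPLEMENT[ea[i]]
        oa[i] = _COMPLEMENT[oa[i]]
    return ea, oa, beta, eaf


def _draw_alpha(cfg: SimConfig, gamma: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    j = len(gamma)
    invalid = rng.random(j) < cfg.pi_invalid
    alpha = np.zeros(j)
    k = int(invalid.sum())
    if k:
        alpha[invalid] = rng.normal(cfg.mu_alpha, cfg.tau_alpha, size=k)
        if cfg.inside_violated:
            # tie pleiotropy to instrument strength: break InSIDE
            alpha[invalid] += 0.5 * gamma[invalid]
    return alpha, invalid


def simulate_pair(
    config: SimConfig,
) -> tuple[SummaryStats, SummaryStats, LDMatrix, SimTruth]:
    """Generate one exposure GWAS, one outcome GWAS, the LD sidecar and the
    truth record. Fixing ``config.seed`` fixes the output bit-for-bit."""
    cfg = config
    j = cfg.n_snp
    rng_maf, rng_gamma, rng_alpha, rng_x, rng_y, rng_alleles, rng_perturb = _streams(
        cfg.seed, 7
    )

    maf = rng_maf.uniform(*cfg.maf_range, size=j)
    gamma = rng_gamma.normal(0.0, cfg.sigma_gamma, size=j)
    if cfg.orient_gamma:
        gamma = np.abs(gamma)
    alpha, invalid = _draw_alpha(cfg, gamma, rng_alpha)

    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exposure_samples)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_outcome_samples)
    beta_x = rng_x.normal(gamma, se_x)
    beta_y = rng_y.normal(cfg.theta_true * gamma + alpha, se_y)

    ids = [f"rs{100000 + i}" for i in range(j)]
    chrom, pos = _positions(j, cfg.ld_block_size)
    ea, oa = _draw_alleles(j, cfg.frac_palindromic, rng_alleles)

    exposure = summary_stats_from_arrays(
        "exposure",
        snp_id=ids, chrom=chrom, pos=pos,
        effect_allele=ea, other_allele=oa, eaf=maf,
        beta=beta_x, se=se_x, pval=_wald_p(beta_x, se_x),
        n=np.full(j, cfg.n_exposure_samples),
    )
    swap = rng_perturb.random(j) < cfg.frac_allele_swap
    flip = rng_perturb.random(j) < cfg.frac_strand_flip
    ea_y, oa_y, beta_y_file, eaf_y = _perturb_outcome(ea, oa, beta_y, maf.copy(), swap, flip)
    outcome = summary_stats_from_arrays(
        "outcome",
        snp_id=ids, chrom=chrom, pos=pos,
        effect_allele=ea_y, other_allele=oa_y, eaf=eaf_y,
        beta=beta_y_file, se=se_y, pval=_wald_p(beta_y_file, se_y),
        n=np.full(j, cfg.n_outcome_samples),
    )
    ld = _ld_matrix(ids, chrom, pos, cfg.ld_block_size, cfg.ld_r2)
    truth = SimTruth(
        theta_true=cfg.theta_true,
        gamma_j=gamma,
        alpha_j=alpha,
        invalid_ids={ids[i] for i in np.nonzero(invalid)[0]},
        expected_mean_f=expected_mean_f(cfg, maf),
        maf=maf,
    )
    return exposure, outcome, ld, truth


def expected_mean_f(config: SimConfig, maf: np.ndarray | None = None) -> float:
    """Closed-form expected per-SNP F under the config:
    E[F_j] = 1 + n_X · 2 maf_j (1 − maf_j) · σ_γ², averaged over maf.

    With ``maf=None`` the average is over the maf distribution
    (Uniform(maf_range)) rather than a realized draw.
    """
    if maf is None:
        lo, hi = config.maf_range
        # E[2m(1-m)] for m ~ U(lo, hi)
        em = (lo + hi) / 2
        em2 = (lo**2 + lo * hi + hi**2) / 3
        h2 = 2 * (em - em2)
    else:
        h2 = np.mean(2 * maf * (1 - maf))
    return float(1.0 + config.n_exposure_samples * h2 * config.sigma_gamma**2)


def simulate_multi(
    config: SimConfig,
    k_exposures: int,
    exposure_correlation: np.ndarray,
    direct_effects: np.ndarray,
) -> tuple[list[SummaryStats], SummaryStats, LDMatrix, SimTruth]:
    """Generate K correlated exposures and one outcome driven only by the
    ``direct_effects`` vector.

    The true effect matrix has correlated columns (γ = Z L' σ_γ with L the
    Cholesky factor of ``exposure_correlation``); each exposure file gets its
    own estimation noise, and all exposures share alleles and frequencies.
    The outcome mean is Σ_k θ_k γ_jk (+ pleiotropy as configured), so an
    exposure with θ_k = 0 shows only a *total* (correlation-borne) effect in
    univariable MR and none in MVMR.
    """
    cfg = config
    if k_exposures < 2:
        raise ValueError("simulate_multi needs K >= 2")
    corr = np.asarray(exposure_correlation, dtype=float)
    if corr.shape != (k_exposures, k_exposures):
        raise ValueError("correlation matrix shape mismatch")
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("exposure correlation matrix is not positive definite") from err
    theta = np.asarray(direct_effects, dtype=float)
    if theta.shape != (k_exposures,):
        raise ValueError("direct_effects must have length K")

    j = cfg.n_snp
    rng_maf, rng_gamma, rng_alpha, rng_x, rng_y, rng_alleles, rng_perturb = _streams(
        cfg.seed, 7
    )
    maf = rng_maf.uniform(*cfg.maf_range, size=j)
    z = rng_gamma.normal(size=(j, k_exposures))
    gamma = (z @ chol.T) * cfg.sigma_gamma
    if cfg.orient_gamma:
        sign = np.where(gamma[:, 0] < 0, -1.0, 1.0)
        gamma = gamma * sign[:, None]
    alpha, invalid = _draw_alpha(cfg, gamma[:, 0], rng_alpha)

    se_x = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_exposure_samples)
    se_y = 1.0 / np.sqrt(2 * maf * (1 - maf) * cfg.n_outcome_samples)
    ids = [f"rs{100000 + i}" for i in range(j)]
    chrom, pos = _positions(j, cfg.ld_block_size)
    ea, oa = _draw_alleles(j, cfg.frac_palindromic, rng_alleles)

    exposures = []
    for k in range(k_exposures):
        bx = rng_x.normal(gamma[:, k], se_x)
        exposures.append(
            summary_stats_from_arrays(
                f"exposure_{k + 1}",
                snp_id=ids, chrom=chrom, pos=pos,
                effect_allele=ea, other_allele=oa, eaf=maf,
                beta=bx, se=se_x, pval=_wald_p(bx, se_x),
                n=np.full(j, cfg.n_exposure_samples),
            )
        )
    by = rng_y.normal(gamma @ theta + alpha, se_y)
    swap = rng_perturb.random(j) < cfg.frac_allele_swap
    flip = rng_perturb.random(j) < cfg.frac_strand_flip
    ea_y, oa_y, by_file, eaf_y = _perturb_outcome(ea, oa, by, maf.copy(), swap, flip)
    outcome = summary_stats_from_arrays(
        "outcome",
        snp_id=ids, chrom=chrom, pos=pos,
        effect_allele=ea_y, other_allele=oa_y, eaf=eaf_y,
        beta=by_file, se=se_y, pval=_wald_p(by_file, se_y),
        n=np.full(j, cfg.n_outcome_samples),
    )
    ld = _ld_matrix(ids, chrom, pos, cfg.ld_block_size, cfg.ld_r2)
    truth = SimTruth(
        theta_true=theta,
        gamma_j=gamma,
        alpha_j=alpha,
        invalid_ids={ids[i] for i in np.nonzero(invalid)[0]},
        expected_mean_f=expected_mean_f(cfg, maf),
        maf=maf,
    )
    return exposures, outcome, ld, truth
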