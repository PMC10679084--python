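"""Multivariable MR: direct effects of several exposures on one outcome.

The MVMR model regresses the SNP–outcome effects β̂_Yj on the J×K matrix of
SNP–exposure effects with weights 1/se_Yj² and no intercept; the coefficient
for exposure k is its *direct* effect, holding the other exposures fixed.
Heterogeneity is the weighted residual sum Q_A on J−K df, and inference
carries multiplicative overdispersion φ = max(1, √(Q_A/(J−K))).

Instrument assembly takes the union of per-exposure genome-wide-significant
SNPs, clumps them jointly (the index SNP in a correlated block is the one
with the smallest p across exposures) and harmonizes every file to the
first exposure's effect alleles. Covariances between a SNP's effect
estimates across exposures are set to zero: the source GWAS overlap is
unknown from summary data alone (a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .estimators import _estimate
from .gwas_io import LDMatrix, SummaryStats
from .harmonize import HarmonizedSet, harmonize
from .instruments import SelectionConfig, clump, drop_palindromic, exclude_confounder_snps, filter_significant


@dataclass
class MVMRSet:
    """J instruments × K exposures of aligned effects plus the outcome."""

    exposure_names: list[str]
    snp_ids: list[str]
    beta_x: np.ndarray  # (J, K)
    se_x: np.ndarray  # (J, K)
    beta_y: np.ndarray  # (J,)
    se_y: np.ndarray  # (J,)
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        j, k = self.beta_x.shape
        if len(self.exposure_names) != k:
            raise ValueError("exposure_names length mismatch")
        if self.se_x.shape != (j, k) or self.beta_y.shape != (j,) or self.se_y.shape != (j,):
            raise ValueError("inconsistent MVMR array dimensions")
        if len(self.snp_ids) != j:
            raise ValueError("snp_ids length mismatch")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("all SEs must be positive")
        if j <= k:
            raise ValueError(f"need more instruments than exposures (J={j}, K={k})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.beta_x.shape


@dataclass
class MVMREstimate:
    """Per-exposure direct effects with heterogeneity and strength diagnostics."""

    exposure_names: list[str]
    theta: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pval: np.ndarray
    q_a: float
    q_df: int
    q_pval: float
    dispersion: float
    conditional_f: dict[str, float] = field(default_factory=dict)


def build_mvmr_set(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    selection: SelectionConfig | None = None,
    ld: LDMatrix | None = None,
) -> MVMRSet:
    """Assemble the joint instrument set for MVMR.

    Union of SNPs genome-wide significant for *any* exposure, jointly clumped
    with each SNP scored by its minimum p across exposures, confounder ids
    excluded, palindromes dropped, then harmonized pairwise (every exposure
    and the outcome aligned to exposure 1's effect alleles). SNPs missing a
    record in any file are dropped and counted.
    """
    if len(exposures) < 2:
        raise ValueError("MVMR needs at least two exposures")
    selection = selection or SelectionConfig()
    ld = ld or LDMatrix.empty()

    sig_ids: set[str] = set()
    for ex in exposures:
        sig_ids |= set(filter_significant(ex, selection.p_threshold).snp_ids)

    # joint clumping frame: min p across exposures, coordinates from the
    # first exposure that carries the SNP
    frames = [ex.records.set_index("snp_id") for ex in exposures]
    rows = []
    for sid in sorted(sig_ids):
        pmin, chrom, pos = np.inf, None, None
        for fr in frames:
            if sid in fr.index:
                r = fr.loc[sid]
                if chrom is None:
                    chrom, pos = r["chrom"], r["pos"]
                pmin = min(pmin, r["pval"])
        rows.append((sid, chrom, pos, pmin))
    import pandas as pd

    union = SummaryStats(
        "mvmr_union",
        pd.DataFrame(
            rows, columns=["snp_id", "chrom", "pos", "pval"]
        ).assign(
            effect_allele="A", other_allele="C", eaf=np.nan, beta=0.0, se=1.0, n=1
        )[
            ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "eaf", "beta", "se", "pval", "n"]
        ],
    )
    union = clump(union, ld, selection.r2_threshold, selection.window_kb)
    union = exclude_confounder_snps(union, selection.exclusion_ids)
    keep_ids = union.snp_ids

    ref = exposures[0].subset(keep_ids)
    ref = drop_palindromic(ref)
    n_missing = len(keep_ids) - len(ref)

    aligned: list[HarmonizedSet] = []
    for other in exposures[1:] + [outcome]:
        aligned.append(harmonize(ref, other, drop_palindromes=True))
    common = set(ref.snp_ids)
    for h in aligned:
        common &= set(h.rows["snp_id"])
    n_missing += len(ref) - len(common)
    ordered = [s for s in ref.snp_ids if s in common]

    refrec = ref.records.set_index("snp_id")
    k = len(exposures)
    j = len(ordered)
    beta_x = np.empty((j, k))
    se_x = np.empty((j, k))
    beta_x[:, 0] = refrec.loc[ordered, "beta"].to_numpy()
    se_x[:, 0] = refrec.loc[ordered, "se"].to_numpy()
    for kk, h in enumerate(aligned[:-1], start=1):
        hr = h.rows.set_index("snp_id").loc[ordered]
        beta_x[:, kk] = hr["beta_y"].to_numpy()
        se_x[:, kk] = hr["se_y"].to_numpy()
    hy = aligned[-1].rows.set_index("snp_id").loc[ordered]
    return MVMRSet(
        exposure_names=[e.trait_name for e in exposures],
        snp_ids=ordered,
        beta_x=beta_x,
        se_x=se_x,
        beta_y=hy["beta_y"].to_numpy(),
        se_y=hy["se_y"].to_numpy(),
        n_dropped_missing=n_missing,
    )


def _collinear_names(x: np.ndarray, names: list[str]) -> list[str]:
    """Name exposures involved in a rank deficiency via column correlations."""
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(x, rowvar=False)
    bad = set()
    k = x.shape[1]
    for a in range(k):
        if np.allclose(x[:, a], 0):
            bad.add(names[a])
        for b in range(a + 1, k):
            if abs(c[a, b]) > 0.9999:
                bad.update((names[a], names[b]))
    return sorted(bad) or list(names)


def mvmr_ivw(mvset: MVMRSet) -> MVMREstimate:
    """Weighted least squares of β̂_Y on the exposure-effect columns.

    No intercept; weights 1/se_Y²; per-exposure Wald inference is normal
    with SEs inflated by φ = max(1, √(Q_A/(J−K))). A rank-deficient design
    is a hard error naming the collinear exposures.
    """
    x = mvset.beta_x
    y = mvset.beta_y
    j, k = x.shape
    w = 1.0 / mvset.se_y**2
    xtwx = x.T @ (w[:, None] * x)
    if np.linalg.matrix_rank(xtwx) < k:
        names = _collinear_names(x, mvset.exposure_names)
        raise ValueError(f"rank-deficient MVMR design; collinear exposures: {names}")
    cond = np.linalg.cond(xtwx)
    if cond > 1e12:
        names = _collinear_names(x, mvset.exposure_names)
        raise ValueError(
            f"near-singular MVMR design (cond={cond:.2e}); "
            f"collinear exposures: {names}"
        )
    theta = np.linalg.solve(xtwx, x.T @ (w * y))
    resid = y - x @ theta
    q_a = float(np.sum(w * resid**2))
    df = j - k
    phi = max(1.0, float(np.sqrt(q_a / df)))
    se = np.sqrt(np.diag(np.linalg.inv(xtwx))) * phi
    z = theta / se
    pval = 2 * sps.norm.sf(np.abs(z))
    z975 = float(sps.norm.ppf(0.975))
    return MVMREstimate(
        exposure_names=list(mvset.exposure_names),
        theta=theta,
        se=se,
        or_=np.exp(theta),
        ci_low=np.exp(theta - z975 * se),
        ci_high=np.exp(theta + z975 * se),
        pval=pval,
        q_a=q_a,
        q_df=df,
        q_pval=float(sps.chi2.sf(q_a, df)),
        dispersion=phi,
        conditional_f=conditional_f(mvset) if k >= 2 else {},
    )


def conditional_f(mvset: MVMRSet) -> dict[str, float]:
    """Per-exposure conditional instrument strength.

    For exposure k, regress its effect column on the other K−1 columns
    (weights 1/se_xk²); the conditional F is the mean of r_j²/se_xjk² over
    instruments, where r_j is the residual — the signal in exposure k's
    instruments that the other exposures do not explain, relative to its
    estimation noise. Assumes zero covariance between exposure-effect
    estimates. Reduces to the univariable mean F when exposure k's column is
    orthogonal to the rest, and collapses to ≈0 under perfect collinearity.
    """
    x = mvset.beta_x
    j, k = x.shape
    if k < 2:
        raise ValueError("conditional F needs at least two exposures")
    out = {}
    for kk in range(k):
        others = np.delete(x, kk, axis=1)
        target = x[:, kk]
        w = 1.0 / mvset.se_x[:, kk] ** 2
        g = others.T @ (w[:, None] * others)
        try:
            coef = np.linalg.solve(g, others.T @ (w * target))
            resid = target - others @ coef
        except np.linalg.LinAlgError:
            resid = target - others @ np.linalg.lstsq(others, target, rcond=None)[0]
        out[mvset.exposure_names[kk]] = float(np.mean(resid**2 * w))
    return out
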