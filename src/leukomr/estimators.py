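"""Univariable two-sample MR estimators and diagnostics.

All estimators consume a :class:`~leukomr.harmonize.HarmonizedSet` of J
aligned instruments (β̂_Xj, se_Xj, β̂_Yj, se_Yj) and return causal estimates
on the log-odds scale with ORs by exponentiation.

Per-SNP Wald ratio: θ̂_j = β̂_Yj/β̂_Xj with first-order SE se_Yj/|β̂_Xj|
(the delta-method term in se_Xj is negligible for strong instruments;
a second-order option is exposed behind ``second_order``).

IVW: θ̂ = Σ w_j θ̂_j / Σ w_j with w_j = 1/se_j²; fixed-effect
SE = (Σ w_j)^(-1/2); Cochran's Q = Σ w_j (θ̂_j − θ̂)² on J−1 df. The
"random-effects" model is multiplicative overdispersion — SE inflated by
φ = max(1, √(Q/(J−1))) — the convention of the summary-data MR software
family, not an additive τ² model. Inference is normal for IVW and t on
J−2 df for MR-Egger.

MR-Egger: weighted regression of β̂_Yj on β̂_Xj *with* intercept, weights
1/se_Yj², rows oriented so every β̂_Xj ≥ 0 (Egger is not invariant to
allele orientation). The intercept estimates average directional
pleiotropy; the slope is the causal estimate under InSIDE.

Weighted median: the ratio value at cumulative standardized weight 1/2,
consistent when instruments carrying ≥50% of the weight are valid; its SE
comes from a seeded parametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import HarmonizedSet

Z975 = float(sps.norm.ppf(0.975))


@dataclass
class RatioEstimate:
    """Per-SNP Wald ratio with first-order SE and IVW weight 1/se²."""

    snp_id: str
    theta_j: float
    se_j: float

    @property
    def weight(self) -> float:
        return 1.0 / self.se_j**2


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale.

    ``ci_low``/``ci_high`` are 95% bounds on the OR scale;
    ``dispersion`` is the multiplicative overdispersion factor applied
    (1 when none).
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    dispersion: float = 1.0

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.theta))


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _ratio_arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bx = hset.rows["beta_x"].to_numpy(dtype=float)
    by = hset.rows["beta_y"].to_numpy(dtype=float)
    sy = hset.rows["se_y"].to_numpy(dtype=float)
    if np.any(bx == 0):
        raise ValueError("Wald ratio undefined: some beta_x are exactly 0")
    theta = by / bx
    se = sy / np.abs(bx)
    return theta, se, 1.0 / se**2


def wald_ratio(row, second_order: bool = False) -> RatioEstimate:
    """Wald ratio for one harmonized row (namedtuple/Series with beta_x,
    se_x, beta_y, se_y)."""
    if row.beta_x == 0:
        raise ValueError("Wald ratio undefined for beta_x = 0")
    theta = row.beta_y / row.beta_x
    se = abs(row.se_y / row.beta_x)
    if second_order:
        se = float(
            np.sqrt(row.se_y**2 / row.beta_x**2
                    + row.beta_y**2 * row.se_x**2 / row.beta_x**4)
        )
    return RatioEstimate(str(row.snp_id), float(theta), float(se))


def or_ci(theta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Exponentiate a log-scale estimate into (OR, low, high) at ``level``."""
    if not 0 < level < 1:
        raise ValueError("confidence level must lie in (0, 1)")
    if se <= 0:
        raise ValueError("se must be positive")
    z = float(sps.norm.ppf(0.5 + level / 2))
    return float(np.exp(theta)), float(np.exp(theta - z * se)), float(np.exp(theta + z * se))


def wald_p_from_or_ci(or_value: float, ci_low: float, ci_high: float) -> float:
    """Two-sided Wald p implied by a printed OR and 95% CI.

    se = (ln hi − ln lo)/(2 z₀.₉₇₅); p = 2Φ(−|ln OR|/se). Computed from CI
    width regardless of whether the OR sits inside the printed CI, so
    published rows can be checked for internal consistency.
    """
    if min(or_value, ci_low, ci_high) <= 0:
        raise ValueError("OR and CI bounds must be positive")
    se = (np.log(ci_high) - np.log(ci_low)) / (2 * Z975)
    if se == 0:
        return 0.0 if or_value != 1 else 1.0
    z = np.log(or_value) / se
    return float(2 * sps.norm.sf(abs(z)))


def _estimate(method, theta, se, j, dispersion=1.0, df_t=None) -> MREstimate:
    if df_t is None:
        p = float(2 * sps.norm.sf(abs(theta / se)))
        crit = Z975
    else:
        p = float(2 * sps.t.sf(abs(theta / se), df_t))
        crit = float(sps.t.ppf(0.975, df_t))
    return MREstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(np.exp(theta - crit * se)),
        ci_high=float(np.exp(theta + crit * se)),
        pval=p,
        n_snp=int(j),
        dispersion=float(dispersion),
    )


def ivw(
    hset: HarmonizedSet, model: str = "random"
) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with Cochran's Q.

    ``model='fixed'`` uses SE = (Σw)^(-1/2); ``model='random'`` multiplies it
    by φ = max(1, √(Q/(J−1))). A single instrument reduces to the Wald ratio
    (fixed model only; Q is then undefined and reported as 0 on 0 df, p = 1).
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = len(hset)
    if j == 0:
        raise ValueError("IVW needs at least one instrument")
    theta_j, _, w = _ratio_arrays(hset)
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    if j == 1:
        if model == "random":
            raise ValueError("random-effects IVW needs J >= 2")
        est = _estimate("IVW-fixed", theta, se_fixed, 1)
        return est, HeterogeneityResult(0.0, 0, 1.0)
    q = float(np.sum(w * (theta_j - theta) ** 2))
    df = j - 1
    q_p = float(sps.chi2.sf(q, df))
    if model == "fixed":
        est = _estimate("IVW-fixed", theta, se_fixed, j)
    else:
        phi = max(1.0, float(np.sqrt(q / df)))
        est = _estimate("IVW-random", theta, se_fixed * phi, j, dispersion=phi)
    return est, HeterogeneityResult(q, df, q_p)


def cochran_q(ratios: list[RatioEstimate], theta_ref: float) -> HeterogeneityResult:
    """Q = Σ w_j (θ̂_j − θ_ref)² against χ² on J−1 df."""
    j = len(ratios)
    if j < 2:
        raise ValueError("Cochran's Q needs at least two instruments")
    w = np.array([r.weight for r in ratios])
    t = np.array([r.theta_j for r in ratios])
    q = float(np.sum(w * (t - theta_ref) ** 2))
    return HeterogeneityResult(q, j - 1, float(sps.chi2.sf(q, j - 1)))


def egger(hset: HarmonizedSet) -> EggerResult:
    """MR-Egger weighted regression with intercept.

    SEs carry multiplicative overdispersion φ = max(1, √(RSS_w/(J−2)));
    p-values are two-sided t on J−2 df.
    """
    j = len(hset)
    if j < 3:
        raise ValueError("MR-Egger needs at least three instruments")
    bx = hset.rows["beta_x"].to_numpy(dtype=float).copy()
    by = hset.rows["beta_y"].to_numpy(dtype=float).copy()
    sy = hset.rows["se_y"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = 1.0 / sy**2
    # weighted normal equations for [intercept, slope]
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, float(np.sqrt(rss / (j - 2))))
    cov = np.linalg.inv(xtwx) * phi**2
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    slope = _estimate("Egger", coef[1], se_slope, j, dispersion=phi, df_t=j - 2)
    p_int = float(2 * sps.t.sf(abs(coef[0] / se_int), j - 2))
    return EggerResult(slope, float(coef[0]), se_int, p_int)


def _weighted_median_point(theta_j: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta_j, kind="mergesort")
    t = theta_j[order]
    ws = w[order]
    s = (np.cumsum(ws) - 0.5 * ws) / np.sum(ws)
    return float(np.interp(0.5, s, t))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    The estimate interpolates the order statistics of the Wald ratios at
    cumulative standardized weight s = 1/2; the SE is the standard deviation
    of the estimate over ``n_boot`` resamples θ̂_j* ~ N(θ̂_j, se_j²) drawn
    from a generator seeded with ``seed``.
    """
    j = len(hset)
    if j < 3:
        raise ValueError("weighted median needs at least three instruments")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} is small; bootstrap SE will be noisy", stacklevel=2
        )
    theta_j, se_j, w = _ratio_arrays(hset)
    point = _weighted_median_point(theta_j, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta_j, se_j, size=(n_boot, j))
    order = np.argsort(draws, axis=1, kind="mergesort")
    t_sorted = np.take_along_axis(draws, order, axis=1)
    w_sorted = w[order]
    s = (np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted) / np.sum(w)
    boot = np.array(
        [np.interp(0.5, s[b], t_sorted[b]) for b in range(n_boot)]
    )
    se = float(boot.std(ddof=1))
    return _estimate("WeightedMedian", point, se, j)


def leave_one_out(hset: HarmonizedSet, model: str = "random") -> pd.DataFrame:
    """Recompute IVW excluding each SNP in turn.

    Returns a table with one row per excluded SNP: the re-estimated theta,
    se, OR-scale CI and p, plus ``sign_robust`` — False when dropping that
    SNP moves the CI across zero relative to the full-set estimate's sign
    status (the flag behind leave-one-out forest plots).
    """
    j = len(hset)
    if j < 3:
        raise ValueError("leave-one-out needs at least three instruments")
    full, _ = ivw(hset, model=model)
    full_excludes_null = full.ci_low > 1.0 or full.ci_high < 1.0
    ids = hset.rows["snp_id"].tolist()
    rows = []
    for sid in ids:
        sub = hset.subset([s for s in ids if s != sid])
        est, _ = ivw(sub, model=model)
        excl_null = est.ci_low > 1.0 or est.ci_high < 1.0
        rows.append(
            {
                "excluded_snp": sid,
                "theta": est.theta,
                "se": est.se,
                "or": est.odds_ratio,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "sign_robust": excl_null == full_excludes_null,
            }
        )
    return pd.DataFrame(rows)


def funnel_scatter_data(
    hset: HarmonizedSet,
    estimates: list[MREstimate] | None = None,
    egger_result: EggerResult | None = None,
) -> dict[str, pd.DataFrame]:
    """Plot-ready tables (pure data, no rendering decisions).

    ``funnel``: per-SNP ratio θ̂_j against precision 1/se_j.
    ``scatter``: β̂_Xj vs β̂_Yj with per-SNP SEs.
    ``lines``: one (intercept, slope) per supplied method estimate — IVW and
    weighted-median lines pass through the origin; the Egger line carries
    its pleiotropy intercept α̂.
    """
    if len(hset) == 0:
        raise ValueError("empty harmonized set")
    theta_j, se_j, _ = _ratio_arrays(hset)
    funnel = pd.DataFrame(
        {
            "snp_id": hset.rows["snp_id"],
            "ratio": theta_j,
            "precision": 1.0 / se_j,
        }
    )
    scatter = hset.rows[["snp_id", "beta_x", "se_x", "beta_y", "se_y"]].copy()
    line_rows = [
        {"method": e.method, "intercept": 0.0, "slope": e.theta}
        for e in (estimates or [])
    ]
    if egger_result is not None:
        line_rows.append(
            {
                "method": "Egger",
                "intercept": egger_result.intercept,
                "slope": egger_result.slope.theta,
            }
        )
    lines = pd.DataFrame(line_rows, columns=["method", "intercept", "slope"])
    return {"funnel": funnel, "scatter": scatter, "lines": lines}
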