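"""MR-PRESSO: pleiotropy residual sum and outlier detection.

Three stages on a harmonized instrument set:

* **global test** — the observed leave-one-out residual sum of squares
  RSS_obs = Σ_j w_j (β̂_Yj − θ̂₍₋j₎ β̂_Xj)², w_j = 1/se_Yj², where θ̂₍₋j₎ is
  the IVW slope excluding SNP j, compared against its simulated null
  distribution (β*_Xj ~ N(β̂_Xj, se_Xj²), β*_Yj ~ N(θ̂₍₋j₎ β̂_Xj, se_Yj²));
* **outlier test** — each SNP's observed weighted squared residual against
  its own simulated distribution, Bonferroni-flagged at 0.05/J;
* **distortion test** — the relative change in the IVW estimate after
  removing flagged outliers, compared with the same statistic under random
  removal of equally many instruments.

All empirical p-values use the plus-one estimator (r+1)/(n+1), so a fixed
seed fixes every p bit-for-bit and no p is ever exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import ivw
from .harmonize import HarmonizedSet


@dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float] = field(default_factory=dict)
    outliers: set[str] = field(default_factory=set)
    distortion_pval: float | None = None
    theta_raw: float | None = None
    theta_corrected: float | None = None
    n_sim: int = 0
    seed: int | None = None


def _arrays(hset: HarmonizedSet):
    bx = hset.rows["beta_x"].to_numpy(dtype=float)
    by = hset.rows["beta_y"].to_numpy(dtype=float)
    sx = hset.rows["se_x"].to_numpy(dtype=float)
    sy = hset.rows["se_y"].to_numpy(dtype=float)
    return bx, by, sx, sy


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope through the origin excluding each j, vectorised.

    The weighted regression of by on bx with weights w has slope
    Σ w bx by / Σ w bx²; leave-one-out subtracts each term.
    """
    num = np.sum(w * bx * by)
    den = np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def _loo_slopes_matrix(bxm: np.ndarray, bym: np.ndarray, w: np.ndarray) -> np.ndarray:
    num = np.sum(w * bxm * bym, axis=1, keepdims=True)
    den = np.sum(w * bxm**2, axis=1, keepdims=True)
    return (num - w * bxm * bym) / (den - w * bxm**2)


def _observed_residuals(hset: HarmonizedSet):
    bx, by, sx, sy = _arrays(hset)
    w = 1.0 / sy**2
    slopes = _loo_slopes(bx, by, w)
    resid2 = w * (by - slopes * bx) ** 2
    return bx, by, sx, sy, w, slopes, resid2


def _simulated_residuals(
    bx, sx, sy, w, slopes, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_sim, J) weighted squared leave-one-out residuals under the null."""
    j = len(bx)
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(slopes * bx, sy, size=(n_sim, j))
    slopes_star = _loo_slopes_matrix(bx_star, by_star, w)
    return w * (by_star - slopes_star * bx_star) ** 2


def presso_global(
    hset: HarmonizedSet, n_sim: int = 1000, seed: int | None = None
) -> tuple[float, float]:
    """Observed RSS and its empirical global p-value."""
    if len(hset) < 4:
        raise ValueError("too few instruments for PRESSO (need J >= 4)")
    bx, by, sx, sy, w, slopes, resid2 = _observed_residuals(hset)
    rss_obs = float(np.sum(resid2))
    rng = np.random.default_rng(seed)
    sim = _simulated_residuals(bx, sx, sy, w, slopes, n_sim, rng)
    rss_star = sim.sum(axis=1)
    p = (1 + int(np.sum(rss_star >= rss_obs))) / (n_sim + 1)
    return rss_obs, float(p)


def presso_outliers(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[dict[str, float], set[str]]:
    """Per-SNP empirical outlier p-values; flag when p < alpha/J (Bonferroni)."""
    if len(hset) < 4:
        raise ValueError("too few instruments for PRESSO (need J >= 4)")
    bx, by, sx, sy, w, slopes, resid2 = _observed_residuals(hset)
    rng = np.random.default_rng(seed)
    sim = _simulated_residuals(bx, sx, sy, w, slopes, n_sim, rng)
    counts = np.sum(sim >= resid2[None, :], axis=0)
    pvals = (1 + counts) / (n_sim + 1)
    ids = hset.rows["snp_id"].tolist()
    j = len(ids)
    pmap = {sid: float(p) for sid, p in zip(ids, pvals)}
    flagged = {sid for sid, p in pmap.items() if p < alpha / j}
    return pmap, flagged


def presso_distortion(
    hset: HarmonizedSet,
    outliers: set[str],
    n_sim: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Raw vs outlier-corrected IVW and the distortion-test p-value.

    The statistic is (θ_raw − θ_corrected)/|θ_corrected|, referred to its
    distribution under removal of |outliers| instruments drawn at random.
    """
    ids = hset.rows["snp_id"].tolist()
    outliers = set(outliers)
    if not outliers:
        raise ValueError("distortion test needs a non-empty outlier set")
    if outliers >= set(ids):
        raise ValueError("cannot remove every instrument")
    theta_raw = ivw(hset, model="fixed")[0].theta
    keep = [s for s in ids if s not in outliers]
    theta_corr = ivw(hset.subset(keep), model="fixed")[0].theta
    d_obs = (theta_raw - theta_corr) / abs(theta_corr)

    rng = np.random.default_rng(seed)
    k = len(outliers)
    d_null = np.empty(n_sim)
    idx = np.arange(len(ids))
    for b in range(n_sim):
        drop = set(rng.choice(idx, size=k, replace=False))
        sub = hset.subset([ids[i] for i in idx if i not in drop])
        t = ivw(sub, model="fixed")[0].theta
        d_null[b] = (theta_raw - t) / abs(t) if t != 0 else np.inf
    p = (1 + int(np.sum(np.abs(d_null) >= abs(d_obs)))) / (n_sim + 1)
    return float(theta_raw), float(theta_corr), float(p)


def run_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PressoResult:
    """Global, outlier and (when outliers are found) distortion tests.

    Sub-streams of ``seed`` drive each stage, so a fixed seed fixes every
    reported p-value bit-for-bit.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    s_global, s_out, s_dist = (int(s.generate_state(1)[0] % 2**31) for s in ss)
    rss_obs, global_p = presso_global(hset, n_sim=n_sim, seed=s_global)
    pvals, flagged = presso_outliers(hset, n_sim=n_sim, seed=s_out, alpha=alpha)
    result = PressoResult(
        rss_obs=rss_obs,
        global_pval=global_p,
        outlier_pvals=pvals,
        outliers=flagged,
        n_sim=n_sim,
        seed=seed,
    )
    if flagged and len(flagged) < len(hset):
        raw, corr, dp = presso_distortion(hset, flagged, n_sim=n_sim, seed=s_dist)
        result.theta_raw = raw
        result.theta_corrected = corr
        result.distortion_pval = dp
    return result
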