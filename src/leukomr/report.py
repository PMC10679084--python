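"""Multiple-testing correction and study-level result assembly.

The univariable analyses over m exposures are Bonferroni-corrected at
family-wise level alpha (per-test threshold alpha/m, the study default being
0.05/6 ≈ 8.33e-3); an exposure is flagged significant when its primary (IVW)
p-value falls below the threshold. The assembled table mirrors the usual
"one row per exposure × method" layout: instrument count, OR with 95% CI,
p, Cochran's Q with its p, and the Egger intercept with its p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .estimators import EggerResult, HeterogeneityResult, MREstimate

TABLE_COLUMNS = [
    "exposure",
    "method",
    "n_snp",
    "or",
    "ci_low",
    "ci_high",
    "pval",
    "q",
    "q_pval",
    "egger_intercept",
    "egger_intercept_pval",
    "significant",
]


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m for m tests at family-wise level alpha."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


@dataclass
class ExposureBundle:
    """All univariable results for one exposure."""

    exposure: str
    estimates: dict[str, MREstimate]  # keyed by method label
    heterogeneity: HeterogeneityResult | None = None
    egger: EggerResult | None = None
    primary_method: str = "IVW-random"


@dataclass
class StudyReport:
    table: pd.DataFrame
    bonferroni_threshold: float
    significant_exposures: set[str] = field(default_factory=set)
    mvmr_block: dict | None = None
    audit: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        for col in ("or", "ci_low", "ci_high", "egger_intercept", "q"):
            df[col] = df[col].map(_fmt3)
        for col in ("pval", "q_pval", "egger_intercept_pval"):
            df[col] = df[col].map(_fmt_p)
        df.to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            "bonferroni_threshold": self.bonferroni_threshold,
            "significant_exposures": sorted(self.significant_exposures),
            "table": self.table.to_dict(orient="records"),
            "mvmr": self.mvmr_block,
            "audit": self.audit,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "StudyReport":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            table=pd.DataFrame(payload["table"], columns=TABLE_COLUMNS),
            bonferroni_threshold=payload["bonferroni_threshold"],
            significant_exposures=set(payload["significant_exposures"]),
            mvmr_block=payload.get("mvmr"),
            audit=payload.get("audit", {}),
        )


def _fmt3(x) -> str:
    return "" if pd.isna(x) else f"{x:.3f}"


def _fmt_p(x) -> str:
    if pd.isna(x):
        return ""
    return f"{x:.2e}" if x < 1e-3 else f"{x:.3f}"


def assemble_table(
    bundles: list[ExposureBundle],
    threshold: float,
    mvmr_block: dict | None = None,
    audit: dict | None = None,
) -> StudyReport:
    """One row per (exposure × method); significance from the primary method.

    The report is a pure function of its inputs: regenerating from the same
    estimates yields an identical table.
    """
    if not bundles:
        raise ValueError("no exposure bundles supplied")
    rows = []
    significant = set()
    for b in bundles:
        primary = b.estimates.get(b.primary_method)
        is_sig = primary is not None and primary.pval < threshold
        if is_sig:
            significant.add(b.exposure)
        for method, est in b.estimates.items():
            het = b.heterogeneity if method.startswith("IVW") else None
            egg = b.egger if method == "Egger" else None
            rows.append(
                {
                    "exposure": b.exposure,
                    "method": method,
                    "n_snp": est.n_snp,
                    "or": est.odds_ratio,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "pval": est.pval,
                    "q": het.q if het else None,
                    "q_pval": het.pval if het else None,
                    "egger_intercept": egg.intercept if egg else None,
                    "egger_intercept_pval": egg.intercept_pval if egg else None,
                    "significant": method == b.primary_method and is_sig,
                }
            )
    return StudyReport(
        table=pd.DataFrame(rows, columns=TABLE_COLUMNS),
        bonferroni_threshold=threshold,
        significant_exposures=significant,
        mvmr_block=mvmr_block,
        audit=audit or {},
    )
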