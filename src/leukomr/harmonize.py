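"""Harmonize exposure and outcome summary statistics to a common effect allele.

For each SNP shared between the two studies (matched on snp_id — both source
GWAS are rsID-keyed, and positions can disagree across genome builds):

* identical alleles — copy the outcome effect as-is;
* swapped alleles (outcome EA = exposure OA and vice versa) — negate the
  outcome beta and reflect its allele frequency;
* strand-complement match (after complementing the outcome alleles, one of
  the above applies) — apply the complement, then the same rule;
* anything else — irreconcilable, dropped as an allele mismatch.

Palindromic (A/T, C/G) SNPs are ambiguous under strand flips and are dropped
when ``drop_palindromes`` (allele frequency is never used to rescue them).
An EAF discordance > 0.2 between studies on a retained SNP is a data-quality
warning, not a drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas_io import SummaryStats
from .instruments import is_palindromic

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

AUDIT_KEYS = (
    "aligned",
    "sign_flipped",
    "strand_flipped",
    "palindromic_dropped",
    "allele_mismatch_dropped",
    "missing_in_outcome",
)

ROW_COLUMNS = ["snp_id", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"]


class HarmonizationError(ValueError):
    pass


@dataclass
class HarmonizedSet:
    """Aligned instrument rows (β̂_Xj, se_Xj, β̂_Yj, se_Yj) ready for MR.

    ``rows`` has columns :data:`ROW_COLUMNS`; ``audit`` counts each matching
    outcome per :data:`AUDIT_KEYS` and sums to |shared ids| + |exposure ids
    missing in outcome|.
    """

    exposure_name: str
    outcome_name: str
    rows: pd.DataFrame
    audit: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rows["snp_id"].duplicated().any():
            raise HarmonizationError("duplicate snp_id in harmonized rows")
        if len(self.rows) and not (
            (self.rows["se_x"] > 0).all() and (self.rows["se_y"] > 0).all()
        ):
            raise HarmonizationError("harmonized SEs must be positive")

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, ids) -> "HarmonizedSet":
        keep = set(ids)
        rows = self.rows[self.rows["snp_id"].isin(keep)].reset_index(drop=True)
        return HarmonizedSet(self.exposure_name, self.outcome_name, rows, dict(self.audit))


def harmonized_set_from_arrays(
    snp_id, beta_x, se_x, beta_y, se_y, eaf_x=None, eaf_y=None,
    exposure_name: str = "exposure", outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from parallel arrays (simulation and
    test convenience; no allele bookkeeping implied)."""
    n = len(snp_id)
    rows = pd.DataFrame(
        {
            "snp_id": list(snp_id),
            "beta_x": np.asarray(beta_x, dtype=float),
            "se_x": np.asarray(se_x, dtype=float),
            "beta_y": np.asarray(beta_y, dtype=float),
            "se_y": np.asarray(se_y, dtype=float),
            "eaf_x": np.full(n, np.nan) if eaf_x is None else np.asarray(eaf_x, float),
            "eaf_y": np.full(n, np.nan) if eaf_y is None else np.asarray(eaf_y, float),
        }
    )
    return HarmonizedSet(exposure_name, outcome_name, rows)


def _classify(ea_x: str, oa_x: str, ea_y: str, oa_y: str) -> tuple[str, bool]:
    """Return (category, flip_sign); category in
    {aligned, sign_flipped, strand_flipped, mismatch}."""
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "aligned", False
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "sign_flipped", True
    cea, coa = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if (cea, coa) == (ea_x, oa_x):
        return "strand_flipped", False
    if (cea, coa) == (oa_x, ea_x):
        return "strand_flipped", True
    return "mismatch", False


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    drop_palindromes: bool = True,
) -> HarmonizedSet:
    """Align ``outcome`` effects onto the exposure's effect alleles.

    Raises
    ------
    HarmonizationError
        If no instrument is shared between the two studies.
    """
    exp = exposure.records.set_index("snp_id", drop=False)
    out = outcome.records.set_index("snp_id", drop=False)
    audit = {k: 0 for k in AUDIT_KEYS}

    rows = []
    discordant_eaf = []
    for sid in exposure.records["snp_id"]:
        if sid not in out.index:
            audit["missing_in_outcome"] += 1
            continue
        ex = exp.loc[sid]
        oy = out.loc[sid]
        if drop_palindromes and is_palindromic(ex.effect_allele, ex.other_allele):
            audit["palindromic_dropped"] += 1
            continue
        cat, flip = _classify(
            ex.effect_allele, ex.other_allele, oy.effect_allele, oy.other_allele
        )
        if cat == "mismatch":
            audit["allele_mismatch_dropped"] += 1
            continue
        audit[cat] += 1
        beta_y = -oy.beta if flip else oy.beta
        eaf_y = oy.eaf
        if flip and pd.notna(eaf_y):
            eaf_y = 1.0 - eaf_y
        if pd.notna(ex.eaf) and pd.notna(eaf_y) and abs(ex.eaf - eaf_y) > 0.2:
            discordant_eaf.append(sid)
        rows.append(
            (sid, ex.beta, ex.se, beta_y, oy.se, ex.eaf, eaf_y)
        )

    if audit["missing_in_outcome"] == len(exposure):
        raise HarmonizationError(
            f"no shared instruments between {exposure.trait_name!r} "
            f"and {outcome.trait_name!r}"
        )
    if discordant_eaf:
        warnings.warn(
            f"{len(discordant_eaf)} harmonized SNP(s) with allele-frequency "
            f"discordance > 0.2 between studies (e.g. {discordant_eaf[:3]})",
            stacklevel=2,
        )
    df = pd.DataFrame(rows, columns=ROW_COLUMNS)
    return HarmonizedSet(exposure.trait_name, outcome.trait_name, df, audit)
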