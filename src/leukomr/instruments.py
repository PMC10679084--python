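"""Instrument selection for two-sample MR.

The selection pipeline mirrors the usual summary-data workflow: keep
genome-wide-significant SNPs (p < 5e-8), greedily clump to approximate
linkage-equilibrium (r² < 0.01 within a 10,000 kb window), drop SNPs on a
confounder exclusion list, drop palindromic (A/T, C/G) SNPs whose strand
cannot be resolved from alleles alone, and summarise instrument strength
with the per-SNP F statistic (β/se)², flagging weak sets (mean F < 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gwas_io import LDMatrix, SummaryStats, VALID_BASES


@dataclass
class SelectionConfig:
    """Tunable thresholds of the instrument-selection pipeline."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.01
    window_kb: float = 10_000.0
    exclusion_ids: frozenset = frozenset()
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        self.exclusion_ids = frozenset(self.exclusion_ids)


@dataclass
class SelectionReport:
    """Record counts after each selection stage, plus instrument strength."""

    n_input: int = 0
    n_after_p: int = 0
    n_after_clump: int = 0
    n_after_exclusion: int = 0
    n_after_palindrome: int = 0
    mean_f: float = float("nan")
    weak_instruments: bool = False
    per_snp_f: dict[str, float] = field(default_factory=dict)


def filter_significant(stats: SummaryStats, p_threshold: float = 5e-8) -> SummaryStats:
    """Keep exactly the records with pval strictly below ``p_threshold``,
    preserving input order."""
    return stats.subset((stats.records["pval"] < p_threshold).to_numpy())


def clump(
    stats: SummaryStats,
    ld: LDMatrix,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000.0,
) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly take the lowest-p unassigned SNP as an index and discard every
    unassigned SNP on the same chromosome within ``window_kb`` whose r² with
    the index is ≥ ``r2_threshold``. The returned set is the index SNPs, in
    original record order. Ties on p break by (chrom, pos), then snp_id, so
    the selected id set is invariant to input row order. SNPs absent from
    ``ld`` are treated as unlinked.
    """
    if window_kb < 0:
        raise ValueError("window_kb must be non-negative")
    if r2_threshold > 1:
        raise ValueError("r2_threshold must be <= 1")
    df = stats.records
    if len(df) == 0:
        return stats.subset([])
    order = df.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="mergesort"
    ).index.to_numpy()
    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy(dtype=float)
    ids = df["snp_id"].to_numpy()
    window_bp = window_kb * 1000.0

    assigned = np.zeros(len(df), dtype=bool)
    kept: list[str] = []
    loc = {i: k for k, i in enumerate(df.index)}
    for idx in order:
        k = loc[idx]
        if assigned[k]:
            continue
        assigned[k] = True
        kept.append(ids[k])
        near = (
            ~assigned
            & (chrom == chrom[k])
            & (np.abs(pos - pos[k]) <= window_bp)
        )
        for j in np.nonzero(near)[0]:
            if ld.r2_between(ids[k], ids[j]) >= r2_threshold:
                assigned[j] = True
    return stats.subset(set(kept))


def exclude_confounder_snps(stats: SummaryStats, exclusion_ids) -> SummaryStats:
    """Remove SNPs on a confounder-associated exclusion list (file input;
    no annotation service is queried)."""
    excl = set(exclusion_ids)
    mask = ~stats.records["snp_id"].isin(excl).to_numpy()
    return stats.subset(mask)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is {A,T} or {C,G}."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea not in VALID_BASES or oa not in VALID_BASES:
        raise ValueError(f"non-ACGT allele: {effect_allele!r}/{other_allele!r}")
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def drop_palindromic(stats: SummaryStats) -> SummaryStats:
    """Remove palindromic SNPs unconditionally (no EAF-based strand rescue)."""
    ea = stats.records["effect_allele"]
    oa = stats.records["other_allele"]
    pal = (((ea == "A") & (oa == "T")) | ((ea == "T") & (oa == "A"))
           | ((ea == "C") & (oa == "G")) | ((ea == "G") & (oa == "C")))
    return stats.subset((~pal).to_numpy())


def per_snp_f(beta: float, se: float) -> float:
    """Instrument-strength F statistic (β/se)² for one SNP."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def mean_f(stats: SummaryStats, f_min: float = 10.0) -> tuple[float, bool]:
    """Arithmetic mean of per-SNP F over all records and the strength flag
    (mean ≥ ``f_min``)."""
    if len(stats) == 0:
        raise ValueError("mean_f undefined for empty stats")
    f = (stats.records["beta"] / stats.records["se"]) ** 2
    m = float(f.mean())
    return m, m >= f_min


def select_instruments(
    stats: SummaryStats, ld: LDMatrix, config: SelectionConfig | None = None
) -> tuple[SummaryStats, SelectionReport]:
    """Full selection pipeline: significance filter → clumping → confounder
    exclusion → palindrome removal, with stage counts and mean F."""
    config = config or SelectionConfig()
    report = SelectionReport(n_input=len(stats))
    out = filter_significant(stats, config.p_threshold)
    report.n_after_p = len(out)
    out = clump(out, ld, config.r2_threshold, config.window_kb)
    report.n_after_clump = len(out)
    out = exclude_confounder_snps(out, config.exclusion_ids)
    report.n_after_exclusion = len(out)
    out = drop_palindromic(out)
    report.n_after_palindrome = len(out)
    if len(out):
        report.per_snp_f = {
            s: per_snp_f(b, e)
            for s, b, e in zip(
                out.records["snp_id"], out.records["beta"], out.records["se"]
            )
        }
        report.mean_f, strong = mean_f(out, config.f_min)
        report.weak_instruments = not strong
    return out, report
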