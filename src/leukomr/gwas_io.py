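"""Reading, validating and writing GWAS summary statistics and LD matrices.

Summary statistics travel as tab-delimited text with one header row, UTF-8,
'.' decimal separator and ``NA`` as the missing token — the dialect of common
GWAS summary-stat exports. Positions are 1-based (GWAS-catalogue convention).
A ``column_map`` adapts files whose headers differ from the canonical names;
no per-consortium readers are needed.

Linkage disequilibrium is always an *input* (square or sparse-triplet TSV
against a reference panel), never estimated here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order for summary-statistics files.
COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

VALID_BASES = frozenset("ACGT")

NA_TOKEN = "NA"


class SummaryStatsError(ValueError):
    """Raised for malformed summary-statistics inputs."""


@dataclass
class LoadReport:
    """Accounting of rows dropped while reading a summary-statistics file."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


@dataclass
class SummaryStats:
    """Per-SNP association records for one trait.

    ``records`` is a DataFrame with :data:`COLUMNS`; snp_id values are unique
    and input order is preserved. ``load_report`` is attached by
    :func:`read_summary_stats`.
    """

    trait_name: str
    records: pd.DataFrame
    load_report: LoadReport | None = None

    def __post_init__(self) -> None:
        if not self.trait_name:
            raise SummaryStatsError("trait_name must be non-empty")
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise SummaryStatsError(f"records missing columns: {missing}")
        if self.records["snp_id"].duplicated().any():
            dups = self.records.loc[self.records["snp_id"].duplicated(), "snp_id"]
            raise SummaryStatsError(f"duplicate snp_id: {sorted(set(dups))[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return self.records["snp_id"].tolist()

    def subset(self, mask_or_ids) -> "SummaryStats":
        """New SummaryStats restricted to a boolean mask or an id collection,
        preserving order."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray, list)) and len(
            mask_or_ids
        ) == len(self.records) and pd.api.types.is_bool_dtype(
            np.asarray(mask_or_ids)
        ):
            rec = self.records.loc[np.asarray(mask_or_ids)]
        else:
            keep = set(mask_or_ids)
            rec = self.records[self.records["snp_id"].isin(keep)]
        return SummaryStats(self.trait_name, rec.reset_index(drop=True))


def _row_failures(df: pd.DataFrame) -> pd.DataFrame:
    """Boolean failure indicators per invariant class (vectorised)."""
    ea = df["effect_allele"]
    oa = df["other_allele"]
    bad_allele = ~(ea.isin(VALID_BASES) & oa.isin(VALID_BASES)) | (ea == oa)
    return pd.DataFrame(
        {
            "invalid_allele": bad_allele,
            "nonpositive_se": ~(df["se"] > 0),
            "bad_pval": ~((df["pval"] > 0) & (df["pval"] <= 1)),
            "bad_eaf": df["eaf"].notna() & ~((df["eaf"] >= 0) & (df["eaf"] <= 1)),
            "bad_pos": ~(df["pos"] >= 1),
            "bad_n": ~(df["n"] > 0),
            "missing_core": df[["snp_id", "chrom", "pos", "beta", "se", "pval", "n"]]
            .isna()
            .any(axis=1),
        }
    )


def read_summary_stats(
    path, column_map: dict[str, str] | None = None, trait_name: str | None = None
) -> SummaryStats:
    """Read a tab-delimited summary-statistics file.

    Parameters
    ----------
    path
        File path (or readable buffer) of a TSV with a header row.
    column_map
        Optional mapping ``canonical name -> file column name`` for files
        whose headers differ from :data:`COLUMNS`.
    trait_name
        Trait label; defaults to the file stem.

    Rows violating the per-record invariants (non-ACGT or identical alleles,
    se ≤ 0, p ∉ (0,1], eaf outside [0,1], pos < 1, n ≤ 0, duplicated snp_id)
    are dropped and counted in the attached :class:`LoadReport`. Alleles are
    upper-cased before validation. A missing mandatory column or an empty
    file is a hard error.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={0: str},
            keep_default_na=False,
            na_values=[NA_TOKEN, ""],
        )
    except pd.errors.EmptyDataError as err:
        raise SummaryStatsError(f"empty summary-statistics file: {path}") from err
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        missing_src = [s for s in rename if s not in df.columns]
        if missing_src:
            raise SummaryStatsError(f"mapped columns absent from file: {missing_src}")
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsError(f"missing mandatory column(s): {missing}")
    df = df[COLUMNS].copy()

    for col in ("snp_id", "chrom", "effect_allele", "other_allele"):
        df[col] = df[col].astype(str)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    report = LoadReport(n_read=len(df))
    fails = _row_failures(df)
    for cls in fails.columns:
        report.dropped[cls] = int(fails[cls].sum())
    keep = ~fails.any(axis=1)
    df = df.loc[keep]
    dup = df["snp_id"].duplicated()
    report.dropped["duplicate_id"] = int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    report.n_kept = len(df)

    if trait_name is None:
        trait_name = getattr(path, "name", None) or str(path)
        trait_name = trait_name.rsplit("/", 1)[-1].removesuffix(".tsv")
    stats = SummaryStats(trait_name, df)
    stats.load_report = report
    return stats


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write ``stats`` as canonical TSV; missing eaf serialises as ``NA``.

    ``read_summary_stats(write_summary_stats(x))`` reproduces ``x``
    field-for-field (floats are written at full round-tripping precision).
    """
    stats.records.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def validate_summary_stats(stats: SummaryStats) -> dict[str, int]:
    """Counts per failure class on an already-built SummaryStats.

    Purely reporting: the input is not modified. Classes mirror the reader's
    drop accounting plus duplicate ids (always 0 post-construction, but
    counted for frames inspected before construction).
    """
    df = stats.records
    fails = _row_failures(df)
    out = {cls: int(fails[cls].sum()) for cls in fails.columns}
    out["duplicate_id"] = int(df["snp_id"].duplicated().sum())
    return out


class LDMatrixError(ValueError):
    """Raised for malformed LD inputs."""


@dataclass
class LDMatrix:
    """Squared-correlation (r²) matrix over a set of SNPs.

    Symmetric, unit diagonal, entries in [0,1]. SNPs absent from the matrix
    are treated as unlinked (r² = 0) by :meth:`r2_between` — sparse LD files
    only list nonzero pairs.
    """

    snp_ids: list[str]
    r2: np.ndarray
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise LDMatrixError(f"r2 shape {self.r2.shape} != ({k}, {k})")
        if k:
            if not np.allclose(self.r2, self.r2.T, atol=1e-12):
                raise LDMatrixError("r2 matrix is not symmetric")
            if not np.allclose(np.diag(self.r2), 1.0):
                raise LDMatrixError("r2 diagonal must be exactly 1")
            if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
                raise LDMatrixError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def r2_between(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        ia = self._index.get(snp_a)
        ib = self._index.get(snp_b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def empty(cls) -> "LDMatrix":
        return cls([], np.zeros((0, 0)))

    @classmethod
    def from_sparse_tsv(cls, path) -> "LDMatrix":
        """Load a sparse triplet file with columns ``snp_a snp_b r2``.

        Unlisted pairs are r² = 0; the diagonal is implied.
        """
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        for col in ("snp_a", "snp_b", "r2"):
            if col not in df.columns:
                raise LDMatrixError(f"sparse LD file missing column {col!r}")
        ids = sorted(set(df["snp_a"]) | set(df["snp_b"]))
        idx = {s: i for i, s in enumerate(ids)}
        mat = np.eye(len(ids))
        for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
            i, j = idx[a], idx[b]
            mat[i, j] = r2
            mat[j, i] = r2
        np.fill_diagonal(mat, 1.0)
        return cls(ids, mat)

    def to_sparse_tsv(self, path) -> None:
        """Write the strictly-nonzero off-diagonal upper triangle as triplets."""
        rows = []
        k = len(self.snp_ids)
        for i in range(k):
            for j in range(i + 1, k):
                if self.r2[i, j] > 0:
                    rows.append((self.snp_ids[i], self.snp_ids[j], self.r2[i, j]))
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


def summary_stats_from_arrays(trait_name: str, **arrays) -> SummaryStats:
    """Convenience constructor from parallel arrays (used by the simulator)."""
    df = pd.DataFrame({c: arrays[c] for c in COLUMNS})
    return SummaryStats(trait_name, df)
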