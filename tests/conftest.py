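import numpy as np
import pandas as pd
import pytest

from leukomr.gwas_io import COLUMNS, SummaryStats
from leukomr.harmonize import harmonized_set_from_arrays


def make_stats(trait="trait", **overrides) -> SummaryStats:
    """A small, fully valid SummaryStats; any column overridable."""
    base = {
        "snp_id": ["rs1", "rs2", "rs3", "rs4"],
        "chrom": ["1", "1", "2", "2"],
        "pos": [1000, 2000, 1000, 900000],
        "effect_allele": ["A", "C", "G", "T"],
        "other_allele": ["G", "T", "A", "C"],
        "eaf": [0.1, 0.2, 0.3, 0.4],
        "beta": [0.10, -0.05, 0.20, 0.08],
        "se": [0.01, 0.01, 0.02, 0.01],
        "pval": [1e-9, 1e-7, 4e-8, 2e-10],
        "n": [10000, 10000, 10000, 10000],
    }
    base.update(overrides)
    n = len(base["snp_id"])
    for c in COLUMNS:
        if len(base[c]) != n:
            raise ValueError(f"column {c} length mismatch in fixture")
    return SummaryStats(trait, pd.DataFrame({c: base[c] for c in COLUMNS}))


def make_hset(theta=0.3, j=10, seed=0, se_y=0.05, sigma=0.2):
    """Harmonized instruments with ratios scattered around ``theta``."""
    rng = np.random.default_rng(seed)
    beta_x = rng.uniform(0.1, 0.5, size=j)
    beta_y = theta * beta_x + rng.normal(0, se_y * sigma, size=j)
    return harmonized_set_from_arrays(
        [f"rs{i}" for i in range(j)],
        beta_x,
        np.full(j, 0.01),
        beta_y,
        np.full(j, se_y),
    )


@pytest.fixture
def stats4():
    return make_stats()


@pytest.fixture
def hset10():
    return make_hset()
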