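"""Simulate the six-trait leukocyte → rheumatoid-arthritis study.

Generates GWAS summary statistics for six correlated leukocyte-count
exposures (eosinophil, lymphocyte, neutrophil, monocyte, basophil, white
blood cells) and one outcome, where only the eosinophil trait carries a
direct causal effect (θ = 0.3 log-odds per SD) — the data-generating
pattern the downstream analyses should recover. Also writes the LD sidecar,
a mock confounder-SNP exclusion list, and the generating truth.

Outputs: results/data/{trait}.tsv, outcome.tsv, ld.tsv, truth.json,
exclusion_ids.txt
"""

import json
from pathlib import Path

import numpy as np

from leukomr.gwas_io import write_summary_stats
from leukomr.simulate import SimConfig, simulate_multi

TRAITS = ["eosinophil", "lymphocyte", "neutrophil", "monocyte", "basophil", "wbc"]
CAUSAL = "eosinophil"
THETA = 0.3
RHO = 0.25  # phenotypic correlation between leukocyte subtypes
SEED = 20240901

OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    k = len(TRAITS)
    corr = np.full((k, k), RHO)
    np.fill_diagonal(corr, 1.0)
    direct = np.array([THETA if t == CAUSAL else 0.0 for t in TRAITS])

    cfg = SimConfig(seed=SEED)
    exposures, outcome, ld, truth = simulate_multi(cfg, k, corr, direct)
    for trait, stats in zip(TRAITS, exposures):
        stats.trait_name = trait
        write_summary_stats(stats, OUT / f"{trait}.tsv")
    write_summary_stats(outcome, OUT / "outcome.tsv")
    ld.to_sparse_tsv(OUT / "ld.tsv")

    # a mock confounder screen: a handful of SNPs flagged for exclusion
    rng = np.random.default_rng(SEED + 1)
    excluded = sorted(map(str, rng.choice(exposures[0].snp_ids, size=5, replace=False)))
    (OUT / "exclusion_ids.txt").write_text("\n".join(excluded) + "\n")

    with open(OUT / "truth.json", "w") as fh:
        json.dump(
            {
                "traits": TRAITS,
                "causal_trait": CAUSAL,
                "direct_effects": direct.tolist(),
                "exposure_correlation": RHO,
                "n_snp": cfg.n_snp,
                "expected_mean_f": truth.expected_mean_f,
                "seed": SEED,
            },
            fh,
            indent=2,
        )
    print(f"simulated {cfg.n_snp} SNPs for {k} exposures + outcome -> {OUT}")
    print(f"causal trait: {CAUSAL} (theta = {THETA}); "
          f"expected mean F = {truth.expected_mean_f:.1f}")
    print(f"confounder exclusion list: {excluded}")


if __name__ == "__main__":
    main()
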