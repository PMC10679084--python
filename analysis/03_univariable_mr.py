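"""Univariable two-sample MR of each leukocyte trait on the outcome.

Harmonizes each trait's instruments with the outcome GWAS, then estimates
the causal effect with random-effects IVW (primary), MR-Egger and the
weighted median; computes Cochran's Q, the Egger pleiotropy intercept,
leave-one-out estimates and the funnel/scatter plot data. One scatter/funnel
figure is rendered for the causal trait as a visual check.

Inputs:  results/data/, results/instruments/
Outputs: results/univariable/
"""

import dataclasses
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from leukomr.estimators import (
    egger,
    funnel_scatter_data,
    ivw,
    leave_one_out,
    weighted_median,
)
from leukomr.gwas_io import read_summary_stats
from leukomr.harmonize import harmonize

DATA = Path("results/data")
INSTR = Path("results/instruments")
OUT = Path("results/univariable")
SEED = 17
TRUTH = json.loads((DATA / "truth.json").read_text())


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    outcome = read_summary_stats(DATA / "outcome.tsv", trait_name="outcome")
    all_results = {}
    for trait in TRUTH["traits"]:
        selected = read_summary_stats(INSTR / f"{trait}.tsv", trait_name=trait)
        hset = harmonize(selected, outcome, drop_palindromes=True)
        hset.rows.to_csv(OUT / f"{trait}_harmonized.tsv", sep="\t", index=False)

        est_random, het = ivw(hset, model="random")
        est_fixed, _ = ivw(hset, model="fixed")
        egger_res = egger(hset)
        wm = weighted_median(hset, n_boot=1000, seed=SEED)
        loo = leave_one_out(hset)
        loo.to_csv(OUT / f"{trait}_leave_one_out.tsv", sep="\t", index=False)
        plot_data = funnel_scatter_data(hset, [est_random], egger_result=egger_res)
        plot_data["funnel"].to_csv(OUT / f"{trait}_funnel.tsv", sep="\t", index=False)
        plot_data["scatter"].to_csv(OUT / f"{trait}_scatter.tsv", sep="\t", index=False)

        all_results[trait] = {
            "estimates": {
                "IVW-random": dataclasses.asdict(est_random),
                "IVW-fixed": dataclasses.asdict(est_fixed),
                "Egger": dataclasses.asdict(egger_res.slope),
                "WeightedMedian": dataclasses.asdict(wm),
            },
            "heterogeneity": dataclasses.asdict(het),
            "egger_intercept": {
                "intercept": egger_res.intercept,
                "se": egger_res.intercept_se,
                "pval": egger_res.intercept_pval,
            },
            "harmonization_audit": hset.audit,
            "loo_sign_robust": bool(loo["sign_robust"].all()),
        }
        e = est_random
        print(
            f"{trait:>11}: OR {e.odds_ratio:.3f} "
            f"({e.ci_low:.3f}-{e.ci_high:.3f}), p = {e.pval:.3g}, "
            f"J = {e.n_snp}, Q p = {het.pval:.3g}, "
            f"Egger intercept p = {egger_res.intercept_pval:.3f}"
        )

        if trait == TRUTH["causal_trait"]:
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
            sc = plot_data["scatter"]
            axes[0].errorbar(sc["beta_x"], sc["beta_y"], yerr=sc["se_y"],
                             fmt="o", ms=3, alpha=0.6)
            for _, line in plot_data["lines"].iterrows():
                xs = [0, sc["beta_x"].max()]
                axes[0].plot(xs, [line["intercept"] + line["slope"] * x for x in xs],
                             label=line["method"])
            axes[0].set_xlabel("SNP effect on exposure")
            axes[0].set_ylabel("SNP effect on outcome")
            axes[0].legend()
            fu = plot_data["funnel"]
            axes[1].plot(fu["ratio"], fu["precision"], "o", ms=3, alpha=0.6)
            axes[1].axvline(e.theta, color="k", lw=1)
            axes[1].set_xlabel("Wald ratio")
            axes[1].set_ylabel("precision (1/se)")
            fig.tight_layout()
            fig.savefig(OUT / f"{trait}_plots.png", dpi=100)
            plt.close(fig)

    with open(OUT / "univariable_estimates.json", "w") as fh:
        json.dump(all_results, fh, indent=2)
    print(f"\nwrote per-trait harmonized sets, estimates and plot data to {OUT}")


if __name__ == "__main__":
    main()
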