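"""Config-driven orchestration of the full study design.

One YAML config describes the inputs (exposure files, outcome file, LD
sidecar), the selection thresholds, the methods to run, and the seeds; the
pipeline then runs, per exposure: instrument selection → harmonization →
IVW / MR-Egger / weighted median → Cochran's Q → MR-PRESSO → leave-one-out,
followed by one MVMR over all exposures and a Bonferroni-corrected report
(m = number of exposures). The pipeline is glue only — every computation
lives in the library modules — and a run manifest records inputs, seeds and
stage counts so a rerun with the same config is identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .estimators import egger, funnel_scatter_data, ivw, leave_one_out, weighted_median
from .gwas_io import LDMatrix, read_summary_stats
from .harmonize import harmonize
from .instruments import SelectionConfig, select_instruments
from .mvmr import build_mvmr_set, mvmr_ivw
from .presso import run_presso
from .report import ExposureBundle, StudyReport, assemble_table, bonferroni_threshold


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and exposure it hit."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> StudyReport:
    """Run the whole study described by ``config`` and write artifacts.

    ``config`` may be a dict or a path to a YAML file with sections
    ``inputs`` (exposures: list of {name, path}, outcome: path, ld: path,
    optional exclusion_ids: path), ``selection``, ``methods``, ``presso``,
    ``report`` and ``seeds``. Any stage error aborts with the stage name and
    the offending exposure.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    inputs = config["inputs"]
    sel_cfg = dict(config.get("selection", {}))
    exclusion_path = inputs.get("exclusion_ids")
    if exclusion_path:
        with open(exclusion_path) as fh:
            sel_cfg["exclusion_ids"] = frozenset(
                line.strip() for line in fh if line.strip()
            )
    selection = SelectionConfig(**sel_cfg)
    methods = config.get("methods", {})
    n_boot = int(methods.get("n_boot", 1000))
    presso_cfg = config.get("presso", {"enabled": True, "n_sim": 1000})
    run_loo = bool(methods.get("leave_one_out", True))
    seeds = config.get("seeds", {})
    master_seed = int(seeds.get("master", 0))

    outcome = read_summary_stats(inputs["outcome"], trait_name="outcome")
    ld = (
        LDMatrix.from_sparse_tsv(inputs["ld"])
        if inputs.get("ld")
        else LDMatrix.empty()
    )

    manifest: dict = {
        "version": __version__,
        "seeds": {"master": master_seed},
        "inputs": {},
        "stages": {},
    }
    for key in ("outcome", "ld", "exclusion_ids"):
        if inputs.get(key):
            manifest["inputs"][key] = {
                "path": str(inputs[key]),
                "sha256": _sha256(Path(inputs[key])),
            }

    bundles: list[ExposureBundle] = []
    audit: dict = {}
    exposures_kept = []
    for i, exp_spec in enumerate(inputs["exposures"]):
        name = exp_spec.get("name") or Path(exp_spec["path"]).stem
        seed_i = (master_seed * 1_000_003 + i) % 2**31
        try:
            exposure = read_summary_stats(exp_spec["path"], trait_name=name)
            manifest["inputs"].setdefault("exposures", []).append(
                {"name": name, "path": str(exp_spec["path"]),
                 "sha256": _sha256(Path(exp_spec["path"]))}
            )
            selected, sel_report = select_instruments(exposure, ld, selection)
            exposures_kept.append(exposure)
        except Exception as err:
            raise PipelineError(f"stage=selection exposure={name}: {err}") from err
        try:
            hset = harmonize(selected, outcome, drop_palindromes=True)
        except Exception as err:
            raise PipelineError(f"stage=harmonize exposure={name}: {err}") from err
        try:
            est_random, het = ivw(hset, model="random")
            est_fixed, _ = ivw(hset, model="fixed")
            egger_res = egger(hset)
            wm = weighted_median(hset, n_boot=n_boot, seed=seed_i)
        except Exception as err:
            raise PipelineError(f"stage=estimation exposure={name}: {err}") from err
        presso_block = None
        if presso_cfg.get("enabled", True):
            try:
                presso_res = run_presso(
                    hset, n_sim=int(presso_cfg.get("n_sim", 1000)), seed=seed_i
                )
                presso_block = {
                    "rss_obs": presso_res.rss_obs,
                    "global_pval": presso_res.global_pval,
                    "outliers": sorted(presso_res.outliers),
                    "distortion_pval": presso_res.distortion_pval,
                }
            except Exception as err:
                raise PipelineError(f"stage=presso exposure={name}: {err}") from err
        loo_table = None
        if run_loo:
            try:
                loo_table = leave_one_out(hset)
            except Exception as err:
                raise PipelineError(
                    f"stage=leave_one_out exposure={name}: {err}"
                ) from err

        plot_data = funnel_scatter_data(hset, [est_random], egger_result=egger_res)
        ex_dir = out_dir / name
        ex_dir.mkdir(exist_ok=True)
        plot_data["funnel"].to_csv(ex_dir / "funnel.tsv", sep="\t", index=False)
        plot_data["scatter"].to_csv(ex_dir / "scatter.tsv", sep="\t", index=False)
        if loo_table is not None:
            loo_table.to_csv(ex_dir / "leave_one_out.tsv", sep="\t", index=False)

        bundles.append(
            ExposureBundle(
                exposure=name,
                estimates={
                    "IVW-random": est_random,
                    "IVW-fixed": est_fixed,
                    "Egger": egger_res.slope,
                    "WeightedMedian": wm,
                },
                heterogeneity=het,
                egger=egger_res,
            )
        )
        audit[name] = {
            "selection": {
                "n_input": sel_report.n_input,
                "n_after_p": sel_report.n_after_p,
                "n_after_clump": sel_report.n_after_clump,
                "n_after_exclusion": sel_report.n_after_exclusion,
                "n_after_palindrome": sel_report.n_after_palindrome,
                "mean_f": sel_report.mean_f,
                "weak_instruments": sel_report.weak_instruments,
            },
            "harmonization": hset.audit,
            "presso": presso_block,
            "seed": seed_i,
        }
        manifest["stages"][name] = audit[name]["selection"]

    mvmr_block = None
    if len(exposures_kept) >= 2 and config.get("mvmr", {}).get("enabled", True):
        try:
            mvset = build_mvmr_set(exposures_kept, outcome, selection, ld)
            mv = mvmr_ivw(mvset)
            mvmr_block = {
                "exposures": mv.exposure_names,
                "theta": mv.theta.tolist(),
                "se": mv.se.tolist(),
                "or": mv.or_.tolist(),
                "ci_low": mv.ci_low.tolist(),
                "ci_high": mv.ci_high.tolist(),
                "pval": mv.pval.tolist(),
                "q_a": mv.q_a,
                "q_df": mv.q_df,
                "q_pval": mv.q_pval,
                "conditional_f": mv.conditional_f,
                "n_snp": len(mvset.snp_ids),
            }
        except Exception as err:
            raise PipelineError(f"stage=mvmr exposure=<all>: {err}") from err

    alpha = float(config.get("report", {}).get("alpha", 0.05))
    threshold = bonferroni_threshold(alpha, len(inputs["exposures"]))
    report = assemble_table(bundles, threshold, mvmr_block=mvmr_block, audit=audit)
    report.to_tsv(out_dir / "report.tsv")
    report.to_json(out_dir / "report.json")
    manifest["selection_config"] = {
        k: (sorted(v) if isinstance(v, frozenset) else v)
        for k, v in asdict(selection).items()
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
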