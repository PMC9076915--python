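"""End-to-end pipeline: simulate -> associate -> stratify -> survive ->
paired genomics, with a machine-readable report.

A run is driven by a :class:`RunConfig` holding either a simulation block
(parameters for :mod:`neostrat.synthetic_cohort`) or paths to real-format
inputs — never both. All stage outputs land in one directory; ``report.json``
echoes every parameter, the seed and per-stage summaries, and is
byte-identical across runs of the same configuration.

Per-stage seeds are derived from the single run seed by fixed offsets so
stages can be re-run standalone and reproduce the pipeline's outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_io, metagene_strat, paired_genomics, response_assoc
from . import survival_stats
from .synthetic_cohort import (PROCESSES, SimConfig, simulate_cohort,
                               simulate_paired_genomics, simulate_survival)

logger = logging.getLogger("neostrat")

#: fixed per-stage seed offsets from the run seed
SEED_OFFSETS = {"simulate": 0, "associate": 1, "survive": 2, "genomics": 3}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a :class:`SimConfig` or parameter dict)
    and ``inputs`` (paths: expression, annotation, optionally cn_pre,
    cn_post, vcf, markers) must be provided.
    """

    seed: int = 0
    out_dir: str = "neostrat_run"
    simulation: object = None
    inputs: dict | None = None
    n_perm: int = 1000
    fdr: float = 0.05
    assoc_cohort: str = "TN"
    min_probes: int = 10
    t_threshold: float = 4.0
    n_markers: int = 10
    quiet: bool = False

    def validate(self) -> "RunConfig":
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulation' and 'inputs' must be set")
        if self.simulation is not None and not isinstance(self.simulation, SimConfig):
            sim = dict(self.simulation)
            if "purity_range" in sim:
                sim["purity_range"] = tuple(sim["purity_range"])
            if "response_coefs" in sim:
                sim["response_coefs"] = {
                    k: tuple(v) for k, v in sim["response_coefs"].items()}
            sim.setdefault("seed", self.seed + SEED_OFFSETS["simulate"])
            self.simulation = SimConfig(**sim)
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw).validate()


def _setup_logging(quiet: bool) -> None:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("[neostrat] %(message)s"))
        logger.addHandler(h)
    logger.setLevel(logging.ERROR if quiet else logging.INFO)


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage and write the report bundle.

    Writes expression.tsv, annotation.tsv, sam.tsv, assignment.tsv,
    profiles.tsv, survival.json, delta.seg, variants.tsv and report.json
    (plus truth.json and somatic.vcf in simulation mode) under
    ``config.out_dir``. On a stage error all partial outputs are removed
    and :class:`PipelineError` is raised. Returns the report dict.
    """
    config.validate()
    _setup_logging(config.quiet)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    report: dict = {"seed": config.seed, "stages": {}}
    stage = "setup"
    t0 = time.perf_counter()
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        if config.simulation is not None:
            sim: SimConfig = config.simulation
            expr, ann, true_assignment, latents = simulate_cohort(sim)
            genomics = simulate_paired_genomics(sim)
            markers = {
                p: list(true_assignment.index[true_assignment == p][:config.n_markers])
                for p in PROCESSES}
            cohort_io.write_expression(expr, save("expression.tsv"))
            cohort_io.write_annotation(ann, save("annotation.tsv"))
            truth = dict(genomics.truth)
            truth["latents"] = latents.table.to_dict(orient="list")
            with open(save("truth.json"), "w") as fh:
                json.dump(truth, fh, sort_keys=True)
            cohort_io.write_paired_vcf(genomics.variants, save("somatic.vcf"))
            paired_genomics.write_cn_profile(genomics.pre, save("pre.cn.tsv"))
            paired_genomics.write_cn_profile(genomics.post, save("post.cn.tsv"))
            report["stages"]["simulate"] = {
                "config": sim.to_dict(),
                "n_samples": int(expr.shape[1]),
                "n_genes": int(expr.shape[0]),
            }
            pre_cn, post_cn, variants = genomics.pre, genomics.post, genomics.variants
        else:
            paths = config.inputs
            expr = cohort_io.read_expression(paths["expression"])
            ann = cohort_io.read_annotation(paths["annotation"])
            markers = None
            if paths.get("markers"):
                mk = pd.read_csv(paths["markers"], sep="\t")
                markers = {p: g["gene"].tolist() for p, g in mk.groupby("process")}
            pre_cn = post_cn = variants = None
            if paths.get("cn_pre") and paths.get("cn_post"):
                pre_cn = paired_genomics.read_cn_profile(
                    paths["cn_pre"], purity=paths.get("purity_pre", 1.0))
                post_cn = paired_genomics.read_cn_profile(
                    paths["cn_post"], purity=paths.get("purity_post", 1.0))
            if paths.get("vcf"):
                variants = cohort_io.read_paired_vcf(paths["vcf"])
            report["stages"]["simulate"] = {"skipped": "inputs supplied"}
        logger.info("stage simulate done (%.1fs)", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "associate"
        t0 = time.perf_counter()
        cohort_ids = ann.loc[(ann["subtype"] == config.assoc_cohort)
                             & (ann["timepoint"] == "pre"), "sample_id"]
        sub = expr[cohort_ids]
        y = ann.set_index("sample_id").loc[cohort_ids, "nri"]
        sam = response_assoc.sam_quantitative(
            sub, y, n_perm=config.n_perm,
            seed=config.seed + SEED_OFFSETS["associate"])
        core = response_assoc.select_core_set(sam, fdr=config.fdr)
        sam.table.to_csv(save("sam.tsv"), sep="\t")
        report["stages"]["associate"] = {
            "cohort": config.assoc_cohort,
            "n_samples": int(len(cohort_ids)),
            "n_genes_tested": int(len(sam.table)),
            "n_perm": int(sam.n_perm),
            "s0": float(sam.s0),
            "fdr": config.fdr,
            "n_core": int(len(core)),
            "n_core_positive": int((core["direction"] == "positive").sum()),
            "n_core_negative": int((core["direction"] == "negative").sum()),
        }
        logger.info("stage associate done (%.1fs)", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "stratify"
        t0 = time.perf_counter()
        if len(core) >= 3:
            assignment = response_assoc.assign_processes(
                sub, core.index, markers=markers)
        else:
            assignment = pd.Series(dtype=object, name="process")
        if set(PROCESSES) <= set(assignment.unique()):
            assignment.rename_axis("gene").to_frame().to_csv(
                save("assignment.tsv"), sep="\t")
            scores = metagene_strat.metagene_scores(expr, assignment)
            # thresholds recomputed within each stratified cohort
            frames = []
            ann_idx = ann.set_index("sample_id")
            for st, ids in ann_idx.groupby("subtype").groups.items():
                strat = metagene_strat.stratify(scores.loc[list(ids)])
                strat["subtype"] = st
                frames.append(strat)
            profiles = pd.concat(frames).loc[scores.index]
            profiles.to_csv(save("profiles.tsv"), sep="\t", na_rep="NA")
            coh_prof = profiles.loc[cohort_ids]
            tests = metagene_strat.profile_response_tests(
                coh_prof, ann[ann["sample_id"].isin(cohort_ids)])
            counts = coh_prof["profile"].value_counts().to_dict()
            report["stages"]["stratify"] = {
                "profile_counts": {k: int(v) for k, v in counts.items()},
                "response_tests": tests,
                "thresholds": "per-cohort medians",
            }
        else:
            profiles = None
            report["stages"]["stratify"] = {
                "skipped": "core set does not cover all three processes"}
        logger.info("stage stratify done (%.1fs)", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "survive"
        t0 = time.perf_counter()
        if profiles is None:
            report["stages"]["survive"] = {"skipped": "profiles missing"}
        else:
            coh_ann = ann[ann["sample_id"].isin(cohort_ids)].copy()
            if config.simulation is not None:
                sim = config.simulation
                coh_ann = simulate_survival(
                    coh_ann, profiles["profile"], sim.planted_log_hr,
                    sim.censor_rate, seed=config.seed + SEED_OFFSETS["survive"])
            surv = coh_ann.dropna(subset=["rfs_time", "rfs_event"])
            surv = surv.merge(profiles[["profile"]], left_on="sample_id",
                              right_index=True)
            surv = surv[surv["profile"].isin(["HHL", "LLH"])]
            data = pd.DataFrame({"time": surv["rfs_time"],
                                 "event": surv["rfs_event"].astype(int),
                                 "group": surv["profile"]})
            if data.empty or data["event"].sum() == 0:
                report["stages"]["survive"] = {"skipped": "no events"}
            else:
                curves = survival_stats.km_fit(data)
                chi2_stat, lr_p = survival_stats.logrank_test(data)
                fit = survival_stats.cox_two_group(data)
                summary = {
                    "n": {k: int((data["group"] == k).sum()) for k in curves},
                    "logrank_chi2": chi2_stat, "logrank_p": lr_p,
                    "cox": {
                        "log_hr": fit.log_hr, "hr": fit.hr, "se": fit.se,
                        "ci95": list(fit.ci95), "p": fit.p,
                        "reference": fit.reference, "comparison": fit.comparison,
                        "converged": fit.converged,
                        "diverged_sign": fit.diverged_sign,
                    },
                }
                with open(save("survival.json"), "w") as fh:
                    json.dump(summary, fh, sort_keys=True, indent=1)
                report["stages"]["survive"] = summary
        logger.info("stage survive done (%.1fs)", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "cndelta"
        t0 = time.perf_counter()
        if pre_cn is None or post_cn is None:
            report["stages"]["cndelta"] = {"skipped": "no paired profiles"}
        else:
            delta = paired_genomics.paired_delta(pre_cn, post_cn)
            segments = paired_genomics.segment_delta(
                delta, min_probes=config.min_probes,
                t_threshold=config.t_threshold)
            cohort_io.write_seg(segments, save("delta.seg"))
            report["stages"]["cndelta"] = {
                "n_probes": int(len(delta)),
                "n_segments": int(len(segments)),
                "purity_pre": pre_cn.purity,
                "purity_post": post_cn.purity,
                "min_probes": config.min_probes,
                "t_threshold": config.t_threshold,
            }
        logger.info("stage cndelta done (%.1fs)", time.perf_counter() - t0)

        # ------------------------------------------------------------------
        stage = "variants"
        t0 = time.perf_counter()
        if variants is None:
            report["stages"]["variants"] = {"skipped": "no variant calls"}
        else:
            retained = paired_genomics.filter_somatic_variants(variants)
            classified = paired_genomics.classify_variant_sharing(retained)
            classified.to_csv(save("variants.tsv"), sep="\t", index=False,
                              na_rep="NA")
            sharing = classified["sharing"].value_counts().to_dict()
            report["stages"]["variants"] = {
                "n_input": int(len(variants)),
                "n_retained": int(len(retained)),
                "sharing_counts": {k: int(v) for k, v in sharing.items()},
            }
        logger.info("stage variants done (%.1fs)", time.perf_counter() - t0)

        make_report(report, save("report.json"))
        return report
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc


def make_report(report: dict, path) -> dict:
    """Serialize the run report deterministically (sorted keys)."""
    if not report.get("stages"):
        raise ValueError("no stage outputs to report")
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1, default=_jsonable)
        fh.write("\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
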