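"""End-to-end pipeline orchestration.

Runs the whole analysis from one declarative config: simulate paired
cohorts -> genotype QC / polygenic scores -> medication-adjusted progression
labels -> baseline feature assembly -> subpart x horizon submodels -> stacked
meta-prediction -> evaluation on the holdout and the external cohort ->
feature-class ablation -> trial-enrichment power calculation.  Every stage's
outputs land in the run directory and a manifest records the config hash,
the seed fan-out, and a checksum for every artifact; rerunning the same
config and seed reproduces identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, evaluation, genetics, labels as labels_mod
from .features import build_baseline_features
from .modeling import ModelConfig, ablate, run_experiment
from .synthetic import (LongitudinalCohort, SimConfig, generate_cohort,
                        write_cohort, write_genotype_data)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative pipeline configuration (round-trips through YAML)."""

    n_subjects: int = 500
    prevalence_a: float = 0.64
    prevalence_b: float = 0.48
    p_treated_a: float = 0.20
    p_treated_b: float = 0.75
    p_female_a: float = 0.35
    p_female_b: float = 0.65
    n_trials: int = 25
    n_estimators: int = 60
    oof_folds: int = 10
    top_k: int = 25
    meta_horizon: int = 12
    ablation_classes: tuple[str, ...] = ("genetic", "physician-exam",
                                         "survey", "imaging")
    run_ablation: bool = True
    power_p_control: float = 0.5
    power_rrr: float = 0.10
    power_alpha: float = 0.05
    power_power: float = 0.80
    power_enriched: float = 0.75
    seed: int = 0
    outdir: str = "pdprog_run"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ablation_classes"] = list(d["ablation_classes"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "ablation_classes" in d:
            d["ablation_classes"] = tuple(d["ablation_classes"])
        return cls(**d)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["ablation_classes"] = list(d["ablation_classes"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def stage_seeds(seed: int, n: int = 12) -> list[int]:
    """Deterministic per-stage seed fan-out: stage i receives word i of the
    SeedSequence state stream (kept below 2**31)."""
    return [int(s) % (2 ** 31)
            for s in np.random.SeedSequence(seed).generate_state(n)]


def _genetics_stage(geno, seed: int) -> tuple[pd.DataFrame, dict]:
    """QC, pruning report, ancestry filter, and both polygenic scores."""
    qc_mask = genetics.variant_qc(geno)
    qc_geno = geno.subset_variants(qc_mask.index[qc_mask].tolist())
    pruned = genetics.ld_prune(qc_geno)
    keep = genetics.ancestry_filter(geno.pcs,
                                    geno.pc_ref["mean"].values,
                                    geno.pc_ref["sd"].values)
    kept_ids = keep.index[keep]
    prs = pd.DataFrame(index=kept_ids)
    skipped = {}
    for name in ("pd", "ea"):
        res = genetics.compute_prs(geno, geno.weights[name], name=name)
        prs[f"{name}_prs"] = res.scores.reindex(kept_ids)
        skipped[name] = res.variants_skipped
    report = {"n_variants": geno.n_variants,
              "n_pass_qc": int(qc_mask.sum()),
              "n_after_prune": len(pruned),
              "n_subjects": geno.n_subjects,
              "n_ancestry_kept": int(keep.sum()),
              "prs_variants_skipped": {k: len(v) for k, v in skipped.items()}}
    return prs, report


def synthesize_features(seed: int, n_subjects: int = 600,
                        prevalence: float = 0.64, imaging: bool = True,
                        p_treated: float = 0.20,
                        sim_overrides: dict | None = None):
    """Convenience: one synthetic cohort through genetics + adjustment +
    labelling + feature assembly.  Returns (X, labels, schema, cohort, geno).

    Medication offsets are estimated within this cohort; for the paired
    train/external design use ``run_pipeline``, which freezes the training
    cohort's offsets.
    """
    cfg = SimConfig(n_subjects=n_subjects, seed=seed,
                    prevalence_target=prevalence, imaging_available=imaging,
                    **(sim_overrides or {}))
    cfg.treatment_model.p_treated = p_treated
    cohort, geno = generate_cohort(cfg)
    prs = pd.DataFrame(
        {"pd_prs": genetics.compute_prs(geno, geno.weights["pd"], "pd").scores,
         "ea_prs": genetics.compute_prs(geno, geno.weights["ea"], "ea").scores})
    offsets = labels_mod.estimate_offsets(cohort)
    adjusted = labels_mod.apply_adjustment(cohort, offsets)
    lab = labels_mod.label_progression(adjusted)
    X, schema = build_baseline_features(cohort, prs)
    return X, lab, schema, cohort, geno


def _restrict(cohort: LongitudinalCohort, ids) -> LongitudinalCohort:
    ids = set(ids)
    out = cohort.copy()
    out.subjects = out.subjects[out.subjects["participant_id"].isin(ids)]
    out.visits = out.visits[out.visits["participant_id"].isin(ids)]
    if out.truth is not None:
        out.truth = out.truth[out.truth["participant_id"].isin(ids)]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    stage = "init"
    try:
        stage = "simulate"
        cfg_a = SimConfig(n_subjects=config.n_subjects, seed=seeds[0],
                          prevalence_target=config.prevalence_a,
                          imaging_available=True, p_female=config.p_female_a)
        cfg_a.treatment_model.p_treated = config.p_treated_a
        cfg_b = SimConfig(n_subjects=config.n_subjects, seed=seeds[1],
                          prevalence_target=config.prevalence_b,
                          imaging_available=False, p_female=config.p_female_b)
        cfg_b.treatment_model.p_treated = config.p_treated_b
        cohort_a, geno_a = generate_cohort(cfg_a)
        cohort_b, geno_b = generate_cohort(cfg_b)
        write_cohort(cohort_a, outdir / "cohort_a")
        write_cohort(cohort_b, outdir / "cohort_b")
        write_genotype_data(geno_a, outdir / "cohort_a")
        write_genotype_data(geno_b, outdir / "cohort_b")

        stage = "genetics"
        prs_a, qc_report_a = _genetics_stage(geno_a, seeds[2])
        prs_b, qc_report_b = _genetics_stage(geno_b, seeds[3])
        cohort_a = _restrict(cohort_a, prs_a.index)
        cohort_b = _restrict(cohort_b, prs_b.index)
        prs_a.to_csv(outdir / "prs_a.tsv", sep="\t")
        prs_b.to_csv(outdir / "prs_b.tsv", sep="\t")
        (outdir / "qc_report.json").write_text(json.dumps(
            {"cohort_a": qc_report_a, "cohort_b": qc_report_b}, indent=2))

        stage = "labels"
        offsets = labels_mod.estimate_offsets(cohort_a)
        adj_a = labels_mod.apply_adjustment(cohort_a, offsets)
        adj_b = labels_mod.apply_adjustment(cohort_b, offsets)
        lab_a = labels_mod.label_progression(adj_a)
        lab_b = labels_mod.label_progression(adj_b)
        lab_a.to_csv(outdir / "labels_a.tsv", sep="\t", index=False)
        lab_b.to_csv(outdir / "labels_b.tsv", sep="\t", index=False)
        jac = labels_mod.jaccard_overlap(lab_a, horizon=config.meta_horizon)
        jac.to_csv(outdir / "jaccard_a.tsv", sep="\t")

        stage = "features"
        X_a, schema = build_baseline_features(cohort_a, prs_a)
        X_b, _ = build_baseline_features(cohort_b, prs_b)
        schema.to_tsv(outdir / "schema.tsv")

        stage = "model"
        mcfg = ModelConfig(n_trials=config.n_trials,
                           n_estimators=config.n_estimators,
                           oof_folds=config.oof_folds, top_k=config.top_k,
                           meta_horizon=config.meta_horizon)
        result = run_experiment(X_a, lab_a, schema, mcfg, seeds[4],
                                X_b=X_b, labels_b=lab_b,
                                with_comparators=True)
        metrics = {
            "holdout_meta_by_horizon": {f"{h}m": m for h, m in
                                        sorted(result.metas_holdout.items())},
            "holdout_meta": result.holdout,
            "holdout_direct": result.holdout_direct,
            "external_meta": result.external,
            "external_direct": result.external_direct,
            "submodel_val_f1": {f"{p}_{h}m": rec.val_f1
                                for (p, h), rec in sorted(
                                    result.submodels.items())},
            "direct_val_f1": {f"total_{h}m": rec.val_f1 for h, rec in
                              sorted(result.submodels.direct.items())},
            "comparators": result.comparators,
        }
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        result.meta.ranking.head(30).to_csv(
            outdir / "meta_feature_ranking.tsv", sep="\t", index=False)

        stage = "evaluate"
        y12 = lab_a[(lab_a["part"] == "total")
                    & (lab_a["horizon"] == config.meta_horizon)].set_index(
                        "participant_id")["progressor"]
        comp_cols = [c for c in ("age_at_baseline", "sex",
                                 "mds_updrs_i_summary_score",
                                 "mds_updrs_ii_summary_score",
                                 "mds_updrs_iii_summary_score",
                                 "mds_updrs_total_score", "hoehn_yahr",
                                 "se_adl", "moca_total", "pd_prs", "ea_prs")
                     if c in X_a.columns]
        evaluation.group_compare(X_a[comp_cols], y12).to_csv(
            outdir / "baseline_comparison_a.tsv", sep="\t", index=False)
        evaluation.prs_distribution_report(
            prs_a, lab_a[lab_a["part"] != "total"]).to_csv(
                outdir / "prs_report_a.tsv", sep="\t", index=False)

        ablation_summary = {}
        if config.run_ablation:
            stage = "ablate"
            abl = ablate(X_a, lab_a, schema, mcfg, seeds[5],
                         classes=config.ablation_classes)
            for cls, entry in abl["ablations"].items():
                ablation_summary[cls] = {
                    "holdout_roc_auc": entry["result"].holdout.get("roc_auc"),
                    "delta_roc_auc": entry["delta_roc_auc"],
                    "noop": entry["result"].noop}
            ablation_summary["full_holdout_roc_auc"] = \
                abl["full"].holdout.get("roc_auc")
            (outdir / "ablation.json").write_text(
                json.dumps(ablation_summary, indent=2))

        stage = "powercalc"
        pcfg = enrichment.PowerCalcConfig(
            p_control=config.power_p_control, rrr=config.power_rrr,
            alpha=config.power_alpha, power=config.power_power)
        n0, n1, ratio = enrichment.enrichment_gain(pcfg,
                                                   config.power_enriched)
        (outdir / "power.json").write_text(json.dumps(
            {"total_n": n0, "total_n_enriched": n1, "ratio": ratio},
            indent=2))

        stage = "manifest"
        config.to_yaml(outdir / "config.yaml")
        files = sorted(p for p in outdir.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": seeds,
            "artifacts": {str(p.relative_to(outdir)):
                          hashlib.sha256(p.read_bytes()).hexdigest()[:16]
                          for p in files},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:  # partial artifacts retained for debugging
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
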