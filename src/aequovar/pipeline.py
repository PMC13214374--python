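"""End-to-end orchestration: traces → metrics → categories → scores →
OddsPath calibration → ACMG/AMP classification → predictor concordance.

Every stage is a pure function of its inputs plus the run configuration;
randomness enters only through the seed, so a rerun with the same config
is byte-identical apart from nothing (no timestamps are written). Stage
outputs are written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import acmg, assay, calibration, classify, concordance, simulate
from .errors import AequovarError, ValidationError

logger = logging.getLogger("aequovar")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

#: predictor banding defaults: AlphaMissense per its published thresholds,
#: REVEL per the calibrated pathogenicity bands, CADD_Phred per the
#: matching published score bounds, PrimateAI per its recommended cutoffs
DEFAULT_BANDINGS = [
    concordance.VepBanding("revel", lb_max=0.29, lp_min=0.644),
    concordance.VepBanding("alphamissense", lb_max=0.34, lp_min=0.564),
    concordance.VepBanding("cadd_phred", lb_max=17.3, lp_min=25.3, score_range=(0.0, 99.0)),
    concordance.VepBanding("primateai", lb_max=0.484, lp_min=0.79),
]


@dataclass
class RunConfig:
    """Single configuration object driving all stages.

    All of the study's numeric operating points live here (window 14 s +
    279 s, non-functional AUC floor 0.02, z = 2.56, BA1 5%, BS1 0.00297,
    BS2 > 2 homozygotes, PM3 < 2.2e-5, PP3 SpliceAI >= 0.2, BP4 SpliceAI
    <= 0.1 & REVEL <= 0.29, AlphaMissense 0.34/0.564, OddsPath strong >=
    18.7), never in code.
    """

    seed: int = 0
    outdir: str = "aequovar_out"
    # input paths; None means "simulate them"
    traces_csv: str | None = None
    control_manifest_tsv: str | None = None
    annotation_tsv: str | None = None
    injection_time_s: float | None = None
    simulate_spec: simulate.CohortSpec = field(default_factory=simulate.CohortSpec)
    assay_config: assay.AssayConfig = field(default_factory=assay.AssayConfig)
    z_multiplier: float = 2.56
    include_controls_in_score_context: bool = False
    disease_model: calibration.DiseaseModel = field(default_factory=lambda:
        calibration.DiseaseModel(prevalence=1 / 4000, genetic_heterogeneity=0.08,
                                 allelic_heterogeneity=0.63, penetrance=0.9))
    strength_bands: calibration.StrengthBands = field(
        default_factory=calibration.StrengthBands)
    rule_config: acmg.RuleConfig = field(default_factory=acmg.RuleConfig)
    #: fallback OddsPath contingency when the run has no pathogenic controls
    #: to derive one from (counts of the assay validation design)
    oddspath_fallback: dict = field(default_factory=lambda: {
        "n_pathogenic_controls": 30, "n_benign_controls": 20,
        "abnormal_pathogenic": 28, "abnormal_benign": 0,
        "normal_pathogenic": 2, "normal_benign": 19,
    })


def _atomic_write(df: pd.DataFrame, path: Path, **kwargs: Any) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, sep="\t", index=False, **kwargs)
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _atomic_write_json(obj: Any, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        with open(tmp, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def _coerce(value, target):
    if dataclasses.is_dataclass(target) and isinstance(value, Mapping):
        return dataclasses.replace(target, **value)
    return value


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML or JSON mapping; nested blocks update
    the corresponding dataclass defaults field by field."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise ValidationError(f"unknown config key {key!r}")
        setattr(cfg, key, _coerce(value, getattr(cfg, key)))
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the result bundle to ``config.outdir``.

    Returns the run summary (also written as ``summary.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- stage: inputs ----------------------------------------------------
    if config.traces_csv is None:
        logger.info("simulating cohort (seed=%d)", config.seed)
        spec = dataclasses.replace(config.simulate_spec, seed=config.seed)
        traces, manifest, truth = simulate.simulate_cohort(spec)
        annotation = simulate.generate_variant_table(truth, seed=config.seed + 1)
        _atomic_write(traces, outdir / "traces.csv")
        _atomic_write(manifest, outdir / "control_manifest.tsv")
        _atomic_write(truth, outdir / "truth.tsv")
        _atomic_write(annotation, outdir / "annotation.tsv")
    else:
        traces = assay.read_trace_csv(config.traces_csv, config.injection_time_s)
        manifest = (pd.read_csv(config.control_manifest_tsv, sep="\t")
                    if config.control_manifest_tsv else pd.DataFrame(
                        columns=["sample_id", "control_type"]))
        annotation = (pd.read_csv(config.annotation_tsv, sep="\t")
                      if config.annotation_tsv else None)

    # -- stage: assay metrics ---------------------------------------------
    logger.info("assay: window %.0f s + %.0f s, non-functional floor %.3g",
                config.assay_config.auc_window_offset,
                config.assay_config.auc_window_length,
                config.assay_config.nonfunctional_auc_floor)
    results = assay.process_plate_table(traces, config.assay_config)
    results_df = assay.results_to_frame(results)
    results_df["low_replicate_warning"] = (
        results_df["n_biological"] < config.assay_config.min_biological_replicates)
    _atomic_write(results_df, outdir / "variant_results.tsv")
    by_sample = {r.sample_id: r for r in results}

    # -- stage: thresholds and tri-category classification ----------------
    control_ids = set(manifest.loc[
        manifest["control_type"].isin(["gnomad_benign", "homology_control"]),
        "sample_id"])
    controls = [by_sample[s] for s in sorted(control_ids) if s in by_sample]
    thresholds = classify.derive_thresholds(controls, config.z_multiplier)
    logger.info("thresholds: AUC (%.4f, %.4f), latency (%.4f, %.4f), z=%.2f",
                thresholds.auc_lo, thresholds.auc_hi,
                thresholds.latency_lo, thresholds.latency_hi, config.z_multiplier)
    variant_ids = set(traces.loc[traces["role"] == assay.Role.VARIANT.value,
                                 "sample_id"].astype(str))
    assayable = [r for r in results if r.sample_id in variant_ids]
    variant_results = [r for r in assayable if r.sample_id not in control_ids]
    rows = []
    categories: dict[str, classify.FunctionalCategory] = {}
    for r in assayable:
        cat, auc_state, lat_state = classify.categorize(r, thresholds)
        categories[r.sample_id] = cat
        rows.append({"sample_id": r.sample_id, "category": cat.value,
                     "auc_state": auc_state.value, "latency_state": lat_state.value})
    class_df = pd.DataFrame(rows)

    score_cohort = assayable if config.include_controls_in_score_context else variant_results
    _, scores_df = classify.compute_functional_scores(score_cohort)
    class_df = class_df.merge(scores_df, on="sample_id", how="left")
    _atomic_write(class_df, outdir / "classification.tsv")

    # -- stage: OddsPath calibration --------------------------------------
    path_ids = set(manifest.loc[manifest.get("control_type", pd.Series(dtype=str))
                                == "pathogenic_control", "sample_id"])
    if path_ids and control_ids:
        n_path, n_ben = len(path_ids & set(categories)), len(control_ids & set(categories))
        def _count(ids, cat):
            return sum(1 for s in ids if categories.get(s) == cat)
        abn = classify.FunctionalCategory.ABNORMAL
        nrm = classify.FunctionalCategory.NORMAL
        op_counts = {
            "n_pathogenic_controls": n_path, "n_benign_controls": n_ben,
            "abnormal_pathogenic": _count(path_ids, abn),
            "abnormal_benign": _count(control_ids, abn),
            "normal_pathogenic": _count(path_ids, nrm),
            "normal_benign": _count(control_ids, nrm),
        }
    else:
        op_counts = dict(config.oddspath_fallback)
    op_path = calibration.compute_oddspath(calibration.OddsPathInput(
        op_counts["n_pathogenic_controls"], op_counts["n_benign_controls"],
        op_counts["abnormal_pathogenic"], op_counts["abnormal_benign"]))
    op_benign = calibration.compute_oddspath(calibration.OddsPathInput(
        op_counts["n_pathogenic_controls"], op_counts["n_benign_controls"],
        op_counts["normal_pathogenic"], op_counts["normal_benign"]))
    ps3_strength = calibration.map_oddspath_to_strength(
        op_path.oddspath, "pathogenic", config.strength_bands)
    bs3_strength = calibration.map_oddspath_to_strength(
        op_benign.oddspath, "benign", config.strength_bands)
    logger.info("OddsPath: pathogenic %.3f -> PS3_%s; benign %.3f -> BS3_%s",
                op_path.oddspath, ps3_strength.value,
                op_benign.oddspath, bs3_strength.value)

    # -- stage: ACMG/AMP classification -----------------------------------
    summary: dict[str, Any] = {
        "seed": config.seed,
        "n_samples": len(results),
        "thresholds": {
            "auc": [thresholds.auc_lo, thresholds.auc_hi],
            "latency": [thresholds.latency_lo, thresholds.latency_hi],
            "z_multiplier": config.z_multiplier,
        },
        "oddspath": {
            "counts": op_counts,
            "pathogenic": op_path.oddspath, "benign": op_benign.oddspath,
            "ps3_strength": ps3_strength.value, "bs3_strength": bs3_strength.value,
        },
        "category_counts": {c.value: sum(1 for v in categories.values() if v == c)
                            for c in classify.FunctionalCategory},
        "control_category_counts": {
            c.value: sum(1 for s in control_ids if categories.get(s) == c)
            for c in classify.FunctionalCategory},
    }

    if annotation is not None:
        evidence_rows = []
        initial: dict[str, acmg.AcmgClass] = {}
        final: dict[str, acmg.AcmgClass] = {}
        for rec in annotation.to_dict("records"):
            ann = acmg.VariantAnnotation(**{
                k: (None if pd.isna(v) else v) for k, v in rec.items()
                if k in acmg.VariantAnnotation.__dataclass_fields__})
            base = (acmg.evaluate_population_criteria(ann, config.rule_config)
                    + acmg.evaluate_insilico_criteria(ann, config.rule_config))
            cat = categories.get(ann.variant_id)
            functional = (acmg.apply_functional_evidence(
                ann, cat, ps3_strength, bs3_strength, config.rule_config)
                if cat is not None else [])
            initial[ann.variant_id] = acmg.combine_criteria(base)
            final[ann.variant_id] = acmg.combine_criteria(base + functional)
            for item in base + functional:
                evidence_rows.append({
                    "variant_id": ann.variant_id, "criterion": item.criterion,
                    "strength": item.strength.value, "rationale": item.rationale,
                    "stage": "functional" if item in functional else "baseline"})
        _atomic_write(pd.DataFrame(evidence_rows), outdir / "evidence.tsv")
        report = acmg.reclassification_report(initial, final)
        _atomic_write(report.per_variant, outdir / "acmg_classification.tsv")
        summary["acmg"] = {
            "initial_counts": report.per_variant["initial_class"].value_counts().to_dict(),
            "final_counts": report.per_variant["final_class"].value_counts().to_dict(),
            "pct_reclassified": report.pct_reclassified,
            "transition_matrix": report.transition_matrix.to_dict(),
        }

        # -- stage: predictor concordance ---------------------------------
        merged = class_df.merge(annotation, left_on="sample_id",
                                right_on="variant_id", how="inner")
        definitive = merged["category"].isin(["normal", "abnormal"])
        if definitive.any() and merged.loc[definitive, "category"].nunique() == 2:
            bandings = list(DEFAULT_BANDINGS)
            cpt_scores = merged.loc[definitive & ~merged["in_clz"].astype(bool), "cpt1"]
            cpt_labels = merged.loc[definitive & ~merged["in_clz"].astype(bool),
                                    "category"] == "abnormal"
            if cpt_labels.nunique() == 2:
                thr, auc_roc = concordance.roc_threshold(
                    cpt_scores.to_numpy(), cpt_labels.to_numpy())
                bandings.append(concordance.VepBanding("cpt1", lb_max=thr, lp_min=thr))
                summary["cpt1_roc"] = {"threshold": thr, "auc_roc": auc_roc}
            conc = concordance.concordance_table(merged, bandings)
            _atomic_write(conc, outdir / "concordance.tsv")
            summary["concordance"] = conc.set_index("predictor")[
                ["spearman_rho", "fraction_correct"]].to_dict("index")

    _atomic_write_json(summary, outdir / "summary.json")
    return summary
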