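"""End-to-end orchestration: simulate -> preprocess -> cluster -> classify
-> stability -> biomarkers -> report, with a YAML config and fixed seeds.

Every run writes a manifest recording the config hash and seed; re-running
the same config reproduces all numeric outputs bit-identically (one master
seed, per-stage streams derived deterministically).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phenoclust import biomarkers, classify, cohort, fuzzy_pam, preprocess, stability, stats_report

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    seed: int = 0
    out_dir: str = "phenoclust_run"
    cohort_csv: str | None = None          # None -> simulate the default cohort
    spec_yaml: str | None = None
    clustering_variables: str = "clinical9"
    k_min: int = 2
    k_max: int = 5
    fuzzifier: float = 1.1
    restarts: int = 50
    variants: tuple[str, ...] = ("A", "B")
    squamous_max: float = 30.0
    alpha_grid: tuple[float, ...] = classify.DEFAULT_ALPHA_GRID
    lambda_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(x) for x in classify.DEFAULT_LAMBDA_GRID)
    )
    cv: str | int = "loo"
    variant_variables: dict = field(default_factory=dict)  # optional per-variant override

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("variants", "alpha_grid", "lambda_grid"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def canonical(self) -> str:
        doc = asdict(self)
        doc["variants"] = list(doc["variants"])
        doc["alpha_grid"] = list(doc["alpha_grid"])
        doc["lambda_grid"] = list(doc["lambda_grid"])
        return yaml.safe_dump(doc, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Schema/compatibility diagnostics; raises on fatal problems."""
    notes: list[str] = []
    if config.fuzzifier <= 1:
        raise ValueError("fuzzifier must exceed 1")
    if config.k_min > config.k_max or config.k_min < 2:
        raise ValueError("need 2 <= k_min <= k_max")
    if config.clustering_variables not in preprocess.VARIABLE_SETS:
        raise ValueError(f"unknown variable set {config.clustering_variables!r}")
    for variant in config.variants:
        if variant not in classify.VARIANT_VARIABLES:
            raise ValueError(f"unknown classifier variant {variant!r}")
    for variant in config.variants:
        override = config.variant_variables.get(variant)
        used = tuple(override) if override else classify.VARIANT_VARIABLES[variant]
        if variant in ("A", "B") and "pc20" in used:
            raise ValueError(f"Model {variant} must exclude PC20")
        if variant == "B" and "blood_eos" in used:
            raise ValueError("Model B must exclude blood eosinophils (and PC20)")
    if config.squamous_max <= 0 or config.squamous_max > 100:
        raise ValueError("squamous threshold must be a percentage in (0, 100]")
    if not config.alpha_grid or not config.lambda_grid:
        raise ValueError("empty tuning grid")
    if config.cohort_csv is not None and not Path(config.cohort_csv).exists():
        raise ValueError(f"cohort file {config.cohort_csv} does not exist")
    if config.k_min == config.k_max:
        notes.append(f"k fixed at {config.k_min}; selection skipped")
    return notes


def run_full(config: RunConfig) -> Path:
    """Execute the whole pipeline; returns the run directory."""
    notes = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage_log: list[dict] = []

    def record(stage: str, **info) -> None:
        stage_log.append({"stage": stage, "elapsed_s": round(time.time() - t0, 3),
                          **info})
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

    # --- cohort -----------------------------------------------------------
    if config.cohort_csv is not None:
        records = cohort.read_cohort_csv(config.cohort_csv)
    else:
        spec = (cohort.spec_from_yaml(config.spec_yaml)
                if config.spec_yaml else cohort.default_cohort_spec(seed=config.seed))
        records = cohort.generate_cohort(spec)
        cohort.write_cohort_csv(records, out / "cohort.csv")
    record("cohort", n_rows=int(len(records)))

    baseline = records[records["visit"] == records["visit"].iloc[0]].reset_index(drop=True)
    baseline = preprocess.sputum_qc(baseline, squamous_max=config.squamous_max)

    # --- cluster ----------------------------------------------------------
    fm_raw = preprocess.transform_variables(baseline, config.clustering_variables)
    fm = preprocess.mad_scale(fm_raw)
    D = fuzzy_pam.pairwise_distance(fm)
    selection = fuzzy_pam.select_k(
        D, range(config.k_min, config.k_max + 1), m=config.fuzzifier,
        restarts=config.restarts, seed=config.seed, subject_ids=fm.subject_ids,
    )
    partition = selection.partitions[selection.best_k]
    with open(out / "partition.json", "w") as fh:
        json.dump(fuzzy_pam.partition_to_dict(partition), fh)
    selection.table.to_csv(out / "k_selection.csv", index=False)
    record("cluster", best_k=selection.best_k)

    labels = np.array([f"C{v + 1}" for v in partition.hard_labels])

    # --- classify ---------------------------------------------------------
    models: dict[str, classify.ClassifierModel] = {}
    for variant in config.variants:
        override = config.variant_variables.get(variant)
        model = classify.train_classifier(
            fm, labels, variant=variant, alpha_grid=config.alpha_grid,
            lambda_grid=config.lambda_grid, cv=config.cv, seed=config.seed,
            variables=tuple(override) if override else None,
        )
        classify.model_to_json(model, out / f"model_{variant}.json")
        classify.export_calculator(model, out / f"calculator_{variant}.csv")
        models[variant] = model
    record("classify", concordance={v: m.training_concordance for v, m in models.items()})

    # --- stability --------------------------------------------------------
    stability_summary = None
    if "B" in models and records["visit"].nunique() > 1:
        calls = stability.longitudinal_classify(models["B"], records)
        baseline_assignments = pd.Series(labels, index=list(fm.subject_ids))
        report = stability.stability_report(calls, baseline_assignments)
        report.to_json(out / "stability.json")
        (out / "stability.md").write_text(report.to_markdown())
        stability_summary = report.to_dict()["per_visit_discordance"]
    record("stability")

    # --- biomarkers + report ---------------------------------------------
    called = biomarkers.call_biomarkers(baseline)
    called.to_csv(out / "biomarker_calls.csv", index=False)
    assignments = pd.Series(labels, index=baseline.index)
    table = stats_report.cluster_table(called, assignments)
    table.to_csv(out / "cluster_table.csv", index=False)
    (out / "cluster_table.md").write_text(table.to_markdown(index=False))
    record("report")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "notes": notes,
        "best_k": selection.best_k,
        "k_table": selection.table.to_dict(orient="records"),
        "training_concordance": {v: m.training_concordance for v, m in models.items()},
        "per_visit_discordance": stability_summary,
        "stages": stage_log,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
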