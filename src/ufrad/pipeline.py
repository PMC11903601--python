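"""End-to-end experiment orchestration.

Stages: generate a phantom cohort -> extract feature tables per modality
and mask source -> select/fit/score each classification task -> evaluate
(ROC summaries, paired DeLong ultrafast vs standard, segmentation
overlap, correlation map).  Each stage writes its artifacts so later
stages can re-run from disk, and the whole experiment is deterministic
given the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import ufrad
from ufrad.evaluation import (
    delong_test,
    dice_jaccard,
    feature_label_correlation,
    performance_summary,
)
from ufrad.features import build_feature_table, predictor_columns
from ufrad.kinetics import KineticsConfig
from ufrad.modeling import StabilityConfig, TASKS, run_task, task_labels
from ufrad.synthetic import (
    CohortSpec,
    KineticEffect,
    TissueKinetics,
    generate_cohort,
    load_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Serializable description of one full experiment."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    tasks: tuple[str, ...] = TASKS
    modalities: tuple[str, ...] = ("ultrafast", "standard")
    mask_sources: tuple[str, ...] = ("truth", "reader2")
    feature_set: str = "all"
    n_bins: int = 32
    wavelet: str = "coif1"
    eval_threshold: float = 0.5
    n_eval_repeats: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["effects"] = {
            k: asdict(v) for k, v in self.cohort.effects.items()
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=list))

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        return _strict_load(cls, data)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _strict_load(cls, data):
    """Build a dataclass from a dict, rejecting unknown keys recursively."""
    if not dataclasses.is_dataclass(cls):
        return data
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name == "effects":
            kwargs[name] = {
                k: _strict_load(KineticEffect, v) for k, v in value.items()
            }
        elif isinstance(value, dict):
            target = {
                "cohort": CohortSpec,
                "stability": StabilityConfig,
                "kinetics": KineticsConfig,
                "base_tumor": TissueKinetics,
                "tumor_kinetics": TissueKinetics,
                "aorta_kinetics": TissueKinetics,
                "background_kinetics": TissueKinetics,
                "tumor_kinetics_standard": TissueKinetics,
            }.get(name)
            kwargs[name] = _strict_load(target, value) if target else value
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


# --------------------------------------------------------------------------
# stages

def stage_generate(config: ExperimentConfig, outdir: Path) -> list:
    cohort_dir = outdir / "cohort"
    records = generate_cohort(dataclasses.replace(config.cohort, seed=config.seed))
    write_cohort(records, cohort_dir, config.cohort)
    logger.info("generated %d lesions -> %s", len(records), cohort_dir)
    return records


def stage_extract(
    config: ExperimentConfig, outdir: Path, records: list | None = None
) -> dict[tuple[str, str], pd.DataFrame]:
    if records is None:
        records = load_cohort(outdir / "cohort")
    tables = {}
    for modality in config.modalities:
        for mask_source in config.mask_sources:
            table = build_feature_table(
                records,
                modality,
                mask_source,
                config.feature_set,
                config.kinetics,
                config.n_bins,
                config.wavelet,
            )
            path = outdir / f"features_{modality}_{mask_source}.csv"
            table.to_csv(path, index=False)
            tables[(modality, mask_source)] = table
            logger.info("extracted %s -> %s", table.shape, path)
    if config.feature_set in ("all", "radiomic"):
        from ufrad.radiomics import build_manifest

        manifest = build_manifest()
        (outdir / "feature_manifest.json").write_text(
            json.dumps(
                {"version": manifest.version, "entries": list(manifest.entries)},
                indent=2,
            )
        )
    return tables


def stage_model(
    config: ExperimentConfig,
    outdir: Path,
    tables: dict[tuple[str, str], pd.DataFrame] | None = None,
) -> dict:
    if tables is None:
        tables = {
            (m, s): pd.read_csv(outdir / f"features_{m}_{s}.csv")
            for m in config.modalities
            for s in config.mask_sources
        }
    results: dict = {}
    for (modality, mask_source), table in tables.items():
        for task in config.tasks:
            key = f"{task}|{modality}|{mask_source}"
            try:
                tr = run_task(
                    table,
                    task,
                    dataclasses.replace(config.stability, seed=config.seed),
                    seed=config.seed,
                    n_eval_repeats=config.n_eval_repeats,
                )
            except ValueError as exc:
                logger.warning("task %s skipped: %s", key, exc)
                results[key] = {"error": str(exc)}
                continue
            perf = performance_summary(
                tr.scores,
                tr.labels,
                threshold=config.eval_threshold,
                replicate_scores=tr.repeat_scores,
            )
            results[key] = {
                "selected_features": tr.selection.selected,
                "selection_counts": {
                    n: int(c)
                    for n, c in zip(tr.selection.predictor_names, tr.selection.counts)
                    if c > 0
                },
                "coefficients": dict(
                    zip(tr.fit.predictor_names, tr.fit.coef.tolist())
                ),
                "intercept": tr.fit.intercept,
                "scores": tr.scores.tolist(),
                "labels": tr.labels.tolist(),
                "performance": perf.as_dict(),
            }
            (outdir / f"task_{task}_{modality}_{mask_source}.json").write_text(
                json.dumps(results[key], indent=2)
            )
    return results


def stage_evaluate(
    config: ExperimentConfig,
    outdir: Path,
    task_results: dict,
    records: list | None = None,
    tables: dict | None = None,
) -> dict:
    report: dict = {"tasks": task_results, "delong": {}, "overlap": {}}
    # paired modality comparison per task and mask source
    if set(config.modalities) >= {"ultrafast", "standard"}:
        for mask_source in config.mask_sources:
            for task in config.tasks:
                a = task_results.get(f"{task}|ultrafast|{mask_source}", {})
                b = task_results.get(f"{task}|standard|{mask_source}", {})
                if "scores" not in a or "scores" not in b:
                    continue
                dl = delong_test(
                    np.asarray(a["scores"]), np.asarray(b["scores"]),
                    np.asarray(a["labels"]),
                )
                report["delong"][f"{task}|{mask_source}"] = dl.as_dict()
    # segmentation agreement truth vs simulated second reader
    if records is None:
        cohort_dir = outdir / "cohort"
        if (cohort_dir / "cohort_manifest.csv").exists():
            records = load_cohort(cohort_dir)
    if records:
        pairs = [dice_jaccard(r.tumor_mask, r.reader2_mask) for r in records]
        report["overlap"] = {
            "dice_mean": float(np.mean([p.dice for p in pairs])),
            "dice_sd": float(np.std([p.dice for p in pairs])),
            "jaccard_mean": float(np.mean([p.jaccard for p in pairs])),
            "jaccard_sd": float(np.std([p.jaccard for p in pairs])),
        }
    # correlation map on the first available table
    if tables:
        (modality, mask_source), table = next(iter(tables.items()))
        label_cols = [c for c in ("HR", "HER2") if c in table.columns]
        if label_cols and len(table) >= 3:
            cm = feature_label_correlation(table, label_cols)
            cm.to_csv(outdir / f"correlation_{modality}_{mask_source}.csv")
    return report


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> dict:
    """Execute all stages and write the experiment report JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    records = stage_generate(config, outdir)
    tables = stage_extract(config, outdir, records)
    task_results = stage_model(config, outdir, tables)
    report = stage_evaluate(config, outdir, task_results, records, tables)
    report["provenance"] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": ufrad.__version__,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
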