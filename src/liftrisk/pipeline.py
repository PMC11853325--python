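"""End-to-end experiment orchestration.

Stages: task risk labeling (lifting equation) -> synthetic cohort
generation -> normalization + windowing + feature extraction ->
stratified split -> model training -> evaluation and report rendering.
A run directory receives every intermediate (cohort manifest, feature
table, split indices, model checkpoints, metric reports), a config
snapshot and a log, so a run can be replayed bit-identically from its
seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, models, preprocessing, rnle, synthetic

log = logging.getLogger("liftrisk")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


def _default_low_task() -> rnle.LiftingTask:
    return rnle.LiftingTask(load_weight=10.0, horizontal_distance=20.0,
                            vertical_origin=25.0, vertical_destination=65.0,
                            frequency=5.0, duration_category="le1h",
                            coupling="poor", unit_system="US")


def _default_high_task() -> rnle.LiftingTask:
    task = _default_low_task()
    task.load_weight = 18.0
    return task


def _default_models() -> list[models.ModelSpec]:
    return [models.ModelSpec(architecture="MLP"),
            models.ModelSpec(architecture="CNN1D"),
            models.ModelSpec(architecture="LSTM")]


@dataclass
class ExperimentConfig:
    """Desk-scale defaults: 6 participants, 400-sample windows, stride 50."""

    low_task: rnle.LiftingTask = field(default_factory=_default_low_task)
    high_task: rnle.LiftingTask = field(default_factory=_default_high_task)
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    window_size: int = 400
    stride: int = 50
    normalization: str = "recording"   # recording | window | none
    model_specs: list[models.ModelSpec] = field(default_factory=_default_models)
    split_ratio: float = 0.8
    seed: int = 0
    save_recordings: bool = False
    plot_roc: bool = False
    log_level: str = "INFO"


def validate_config(config: ExperimentConfig) -> list[str]:
    """Field-level validation; returns an aggregated list of messages."""
    errors: list[str] = []
    if config.window_size < 2:
        errors.append("window_size: must be >= 2")
    if config.stride < 1:
        errors.append("stride: must be >= 1")
    if config.normalization not in ("recording", "window", "none"):
        errors.append(f"normalization: unknown scope {config.normalization!r}")
    if not 0 < config.split_ratio < 1:
        errors.append("split_ratio: must be strictly between 0 and 1")
    if not config.model_specs:
        errors.append("model_specs: need at least one model")
    try:
        config.synthetic.validate()
    except synthetic.SyntheticError as exc:
        errors.append(f"synthetic: {exc}")
    try:
        low = rnle.assess_task(config.low_task)
        high = rnle.assess_task(config.high_task)
        if low.binary_label == high.binary_label:
            errors.append(
                "tasks: low and high task map to the same binary risk label "
                f"({low.binary_label}); the experiment needs both classes "
                f"(LI {low.LI:.2f} vs {high.LI:.2f})")
    except rnle.RnleError as exc:
        errors.append(f"tasks: {exc}")
    return errors


def _configure_logging(out_dir: Path, level: str) -> None:
    log.setLevel(level.upper())
    log.handlers = [h for h in log.handlers
                    if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(stream)
    file_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    file_handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(file_handler)


def _listify(obj):
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def config_to_dict(config: ExperimentConfig) -> dict:
    """YAML-safe plain-dict form (tuples become lists)."""
    return _listify(asdict(config))


def config_from_dict(raw: dict) -> ExperimentConfig:
    kwargs = dict(raw)
    for key, cls in (("low_task", rnle.LiftingTask), ("high_task", rnle.LiftingTask),
                     ("synthetic", synthetic.SyntheticConfig)):
        if key in kwargs and isinstance(kwargs[key], dict):
            value = dict(kwargs[key])
            value.pop("demographics", None)
            if "band" in value:
                value["band"] = tuple(value["band"])
            kwargs[key] = cls(**value)
    if "model_specs" in kwargs:
        specs = []
        for item in kwargs["model_specs"]:
            if isinstance(item, dict):
                item = dict(item)
                for tup in ("mlp_hidden", "cnn_dense", "lstm_dense"):
                    if tup in item:
                        item[tup] = tuple(item[tup])
                item = models.ModelSpec(**item)
            specs.append(item)
        kwargs["model_specs"] = specs
    return ExperimentConfig(**kwargs)


def load_config(path) -> ExperimentConfig:
    """Read an experiment config from YAML (missing keys take defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def build_feature_table(config: ExperimentConfig,
                        recordings: Optional[list] = None) -> pd.DataFrame:
    """Generate (or accept) the cohort and featurize it recording by
    recording, so raw windows never accumulate in memory."""
    if recordings is None:
        recordings = synthetic.generate_cohort(config.synthetic)
    tables = []
    for rec in recordings:
        if config.normalization == "recording":
            rec = preprocessing.normalize_recording(rec)
        batch = preprocessing.sliding_windows(
            rec, config.window_size, config.stride,
            normalize_windows=config.normalization == "window")
        tables.append(features.featurize_batch(batch))
    table = pd.concat(tables, ignore_index=True)
    log.info("feature table: %d windows x %d columns from %d recordings",
             len(table), table.shape[1], len(recordings))
    return table


def run_pipeline(config: ExperimentConfig, out_dir) -> dict:
    """Execute every stage; returns {"metrics": DataFrame, "reports": ...}.

    Raises :class:`PipelineError` with a stage tag on failure; partial
    outputs stay in ``out_dir`` for debugging.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _configure_logging(out_dir, config.log_level)

    errors = validate_config(config)
    if errors:
        raise PipelineError("[validate] invalid config:\n  " + "\n  ".join(errors))
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False))

    stage = "rnle"
    try:
        t0 = time.perf_counter()
        low = rnle.assess_task(config.low_task).rounded()
        high = rnle.assess_task(config.high_task).rounded()
        pd.DataFrame([{"task": "low", **asdict(low)},
                      {"task": "high", **asdict(high)}]).to_csv(
            out_dir / "rnle_assessments.csv", index=False)
        log.info("[rnle] low LI=%.2f (%s), high LI=%.2f (%s)",
                 low.LI, low.risk_category, high.LI, high.risk_category)

        stage = "simulate"
        cohort_config = dataclasses.replace(config.synthetic, seed=config.seed)
        recordings = synthetic.generate_cohort(cohort_config)
        manifest = pd.DataFrame(
            {"participant_id": [r.participant_id for r in recordings],
             "risk": [r.risk_label for r in recordings],
             "n_samples": [r.n_samples for r in recordings],
             "seed": cohort_config.seed})
        if config.save_recordings:
            rec_dir = out_dir / "recordings"
            rec_dir.mkdir(exist_ok=True)
            paths = []
            for rec in recordings:
                path = rec_dir / f"{rec.participant_id}_risk{rec.risk_label}.csv"
                preprocessing.write_emg_csv(rec, path)
                paths.append(str(path))
            manifest["path"] = paths
        manifest.to_csv(out_dir / "cohort_manifest.csv", index=False)
        log.info("[simulate] %d recordings, %d samples each (%.1f s)",
                 len(recordings), recordings[0].n_samples,
                 time.perf_counter() - t0)

        stage = "featurize"
        table = build_feature_table(config, recordings)
        del recordings
        table.to_csv(out_dir / "features.csv", index=False)

        stage = "split"
        split = models.stratified_split(table, config.split_ratio, config.seed)
        (out_dir / "split.json").write_text(json.dumps(
            {"ratio": split.ratio, "seed": config.seed,
             "train": split.train.tolist(), "test": split.test.tolist()}))
        log.info("[split] %d train / %d test windows", len(split.train),
                 len(split.test))

        reports: dict[str, evaluation.MetricReport] = {}
        curves: dict[str, evaluation.RocCurve] = {}
        y_test = table[split.label_column].to_numpy(dtype=int)[split.test]
        test_table = table.iloc[split.test]
        for spec in config.model_specs:
            stage = f"train:{spec.architecture}"
            t0 = time.perf_counter()
            spec = dataclasses.replace(spec, seed=config.seed + spec.seed)
            trained = models.train_model(table, split, spec)
            models.save_checkpoint(trained, out_dir / f"model_{spec.architecture}")
            log.info("[%s] %d params, %d epochs, %.1f s", stage,
                     trained.n_params, len(trained.history["loss"]),
                     time.perf_counter() - t0)

            stage = f"evaluate:{spec.architecture}"
            scores = models.predict_scores(trained, test_table)
            labels = (scores >= trained.threshold).astype(int)
            report = evaluation.compute_metrics(
                evaluation.confusion_matrix(y_test, labels))
            report.auc, curves[spec.architecture] = evaluation.roc_auc(y_test, scores)
            reports[spec.architecture] = report
            log.info("[%s] accuracy %.4f, MCC %.4f, AUC %.4f", stage,
                     report.accuracy, report.mcc, report.auc)

        stage = "report"
        evaluation.render_report(reports, out_dir, curves, plot=config.plot_roc)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[{stage}] {exc}") from exc

    metrics = pd.read_csv(out_dir / "metrics.csv", index_col=0)
    return {"metrics": metrics, "reports": reports, "out_dir": out_dir}
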