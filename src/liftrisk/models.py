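"""Risk classifiers: stratified splitting, the three architectures,
training and prediction.

Architectures (binary output, sigmoid head):

* ``MLP``   — dense 64 -> 32 -> 16 (ReLU) -> 1
* ``CNN1D`` — Conv1D(32 filters, kernel 3, ReLU) -> MaxPool(2) ->
  flatten -> dense 64 -> 16 (ReLU) -> 1
* ``LSTM``  — LSTM(32) -> dense 16 (ReLU) -> 1

The sequence models consume the 96-feature vector reshaped to a
96-step x 1-channel sequence by default (a 12 x 8 feature-by-sensor
layout is available via ``input_layout``).  Features are standardized
with training-split statistics only.  Training is binary cross-entropy
with Adam and early stopping; under a fixed seed it is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _nn
from .features import METADATA_COLUMNS

ARCHITECTURES = ("MLP", "CNN1D", "LSTM")
INPUT_LAYOUTS = ("flat", "seq_per_feature", "seq_per_sensor")


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    architecture: str = "MLP"
    mlp_hidden: tuple = (64, 32, 16)
    cnn_filters: int = 32
    cnn_kernel: int = 3
    cnn_pool: int = 2
    cnn_dense: tuple = (64, 16)
    lstm_units: int = 32
    lstm_dense: tuple = (16,)
    input_layout: str = "seq_per_feature"  # 96 steps x 1 channel
    learning_rate: float = 1e-3
    batch_size: int = 512
    max_epochs: int = 50
    patience: int = 5
    validation_fraction: float = 0.1
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ModelError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {ARCHITECTURES}")
        if self.input_layout not in INPUT_LAYOUTS:
            raise ModelError(f"unknown input layout {self.input_layout!r}")
        if not 0 < self.threshold < 1:
            raise ModelError("threshold must be in (0, 1)")


@dataclass
class SplitIndices:
    train: np.ndarray
    test: np.ndarray
    ratio: float
    label_column: str = "Risk"


def stratified_split(table: pd.DataFrame, ratio: float = 0.8,
                     seed: int = 0, label_column: str = "Risk") -> SplitIndices:
    """Row-wise stratified train/test split on the label column.

    Each class is split ``ratio``/(1-``ratio``) within rounding, so the
    class balance of train and test matches the table's within one row
    per class.  Deterministic under a fixed seed.
    """
    if not 0 < ratio < 1:
        raise ModelError("split ratio must be strictly between 0 and 1")
    labels = table[label_column].to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ModelError("both risk classes must be present to split")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(ratio * len(idx)))
        if n_train in (0, len(idx)):
            raise ModelError(f"class {cls} would have an empty train or test side")
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return SplitIndices(train=np.sort(np.concatenate(train_parts)),
                        test=np.sort(np.concatenate(test_parts)),
                        ratio=ratio, label_column=label_column)


def grouped_split(table: pd.DataFrame, ratio: float = 0.8, seed: int = 0,
                  group_column: str = "Participant",
                  label_column: str = "Risk") -> SplitIndices:
    """Leakage-free alternative: whole participants go to train or test.

    Because every participant contributes one recording per class, the
    split stays stratified by construction.
    """
    if not 0 < ratio < 1:
        raise ModelError("split ratio must be strictly between 0 and 1")
    groups = table[group_column].to_numpy()
    unique = np.unique(groups)
    if len(unique) < 2:
        raise ModelError("need at least 2 groups for a grouped split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    n_train = int(round(ratio * len(unique)))
    n_train = min(max(n_train, 1), len(unique) - 1)
    train_groups = set(perm[:n_train])
    mask = np.fromiter((g in train_groups for g in groups), bool, len(groups))
    return SplitIndices(train=np.flatnonzero(mask), test=np.flatnonzero(~mask),
                        ratio=ratio, label_column=label_column)


def _infer_shape(spec: ModelSpec, n_features: int) -> tuple[int, int]:
    """(time steps, channels) for the sequence architectures."""
    if spec.input_layout == "seq_per_sensor":
        if n_features % 12 != 0:
            raise ModelError("seq_per_sensor layout needs a multiple of 12 features")
        return 12, n_features // 12
    return n_features, 1


def build_model(spec: ModelSpec, n_features: int = 96) -> _nn.Sequential:
    """Instantiate the untrained network for a given feature width."""
    rng = np.random.default_rng(spec.seed)
    layers: list[_nn.Layer] = []
    if spec.architecture == "MLP":
        width = n_features
        for hidden in spec.mlp_hidden:
            layers += [_nn.Dense(width, hidden, rng), _nn.ReLU()]
            width = hidden
        layers += [_nn.Dense(width, 1, rng), _nn.Sigmoid()]
    elif spec.architecture == "CNN1D":
        t, c = _infer_shape(spec, n_features)
        layers += [_nn.Conv1D(c, spec.cnn_filters, spec.cnn_kernel, rng), _nn.ReLU(),
                   _nn.MaxPool1D(spec.cnn_pool), _nn.Flatten()]
        width = ((t - spec.cnn_kernel + 1) // spec.cnn_pool) * spec.cnn_filters
        for hidden in spec.cnn_dense:
            layers += [_nn.Dense(width, hidden, rng), _nn.ReLU()]
            width = hidden
        layers += [_nn.Dense(width, 1, rng), _nn.Sigmoid()]
    else:  # LSTM
        _, c = _infer_shape(spec, n_features)
        layers += [_nn.LSTM(c, spec.lstm_units, rng)]
        width = spec.lstm_units
        for hidden in spec.lstm_dense:
            layers += [_nn.Dense(width, hidden, rng), _nn.ReLU()]
            width = hidden
        layers += [_nn.Dense(width, 1, rng), _nn.Sigmoid()]
    return _nn.Sequential(layers)


@dataclass
class TrainedRiskModel:
    spec: ModelSpec
    model: _nn.Sequential
    feature_names: list[str]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    history: dict
    threshold: float = 0.5

    @property
    def n_params(self) -> int:
        return self.model.n_params()


def _feature_matrix(table: pd.DataFrame,
                    feature_names: Optional[list[str]] = None) -> tuple[np.ndarray, list[str]]:
    if feature_names is None:
        feature_names = [c for c in table.columns if c not in METADATA_COLUMNS]
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise ModelError(f"feature columns missing from table: {missing[:3]} ...")
    return table[feature_names].to_numpy(dtype=float), feature_names


def _shape_input(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    if spec.architecture == "MLP":
        return x
    t, c = _infer_shape(spec, x.shape[1])
    return x.reshape(len(x), t, c)


def train_model(table: pd.DataFrame, split: SplitIndices, spec: ModelSpec,
                model: Optional[_nn.Sequential] = None) -> TrainedRiskModel:
    """Standardize on the training split, fit, return the trained model."""
    x, names = _feature_matrix(table)
    if not np.all(np.isfinite(x)):
        raise ModelError("non-finite feature values; clean the table first")
    y = table[split.label_column].to_numpy(dtype=float)
    x_tr = x[split.train]
    mean = x_tr.mean(axis=0)
    std = x_tr.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    if model is None:
        model = build_model(spec, n_features=x.shape[1])
    rng = np.random.default_rng(spec.seed + 1)
    history = _nn.fit(
        model, _shape_input((x_tr - mean) / std, spec), y[split.train],
        rng=rng, learning_rate=spec.learning_rate, batch_size=spec.batch_size,
        max_epochs=spec.max_epochs, patience=spec.patience,
        validation_fraction=spec.validation_fraction,
    )
    return TrainedRiskModel(spec=spec, model=model, feature_names=names,
                            feature_mean=mean, feature_std=std,
                            history=history, threshold=spec.threshold)


def predict_scores(trained: TrainedRiskModel, table: pd.DataFrame) -> np.ndarray:
    """Sigmoid risk probabilities in [0, 1], one per row."""
    x, _ = _feature_matrix(table, trained.feature_names)
    z = (x - trained.feature_mean) / trained.feature_std
    return trained.model.predict(_shape_input(z, trained.spec)).ravel()


def predict_labels(trained: TrainedRiskModel, table: pd.DataFrame,
                   threshold: Optional[float] = None) -> np.ndarray:
    """Hard labels: score >= threshold (default: the model's threshold)."""
    threshold = trained.threshold if threshold is None else threshold
    return (predict_scores(trained, table) >= threshold).astype(int)


def save_checkpoint(trained: TrainedRiskModel, directory) -> Path:
    """Persist weights (npz) plus a JSON sidecar with spec and history."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = trained.model.get_weights()
    np.savez(directory / "weights.npz",
             *weights, feature_mean=trained.feature_mean,
             feature_std=trained.feature_std)
    meta = {
        "spec": asdict(trained.spec),
        "feature_names": trained.feature_names,
        "history": trained.history,
        "threshold": trained.threshold,
        "n_weight_arrays": len(weights),
        "n_params": trained.n_params,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_checkpoint(directory) -> TrainedRiskModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    spec_dict = meta["spec"]
    for key in ("mlp_hidden", "cnn_dense", "lstm_dense"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = ModelSpec(**spec_dict)
    blob = np.load(directory / "weights.npz")
    model = build_model(spec, n_features=len(meta["feature_names"]))
    model.set_weights([blob[f"arr_{i}"] for i in range(meta["n_weight_arrays"])])
    return TrainedRiskModel(spec=spec, model=model,
                            feature_names=meta["feature_names"],
                            feature_mean=blob["feature_mean"],
                            feature_std=blob["feature_std"],
                            history=meta["history"],
                            threshold=meta["threshold"])
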