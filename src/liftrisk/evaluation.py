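"""Confusion counts, classification metrics and report rendering.

The positive class is high risk (label 1).  Metrics follow the standard
confusion-matrix definitions: recall TP/(TP+FN), precision TP/(TP+FP),
accuracy (TP+TN)/total, F1 the harmonic mean of precision and recall,
and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

ROC-AUC uses the Mann-Whitney formulation (probability that a random
positive outscores a random negative, ties counted 1/2).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be non-negative")
        if self.total == 0:
            raise EvaluationError("confusion counts must total > 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    mcc: float
    confusion: ConfusionCounts
    auc: Optional[float] = None
    degenerate: bool = False  # some denominator was 0 and a metric was zeroed

    def as_percent(self, ndigits: int = 2) -> dict[str, float]:
        """Table-style presentation: percentages at 2 decimals."""
        out = {"Precision": self.precision, "Recall": self.recall,
               "F1 Score": self.f1, "Accuracy": self.accuracy, "MCC": self.mcc}
        if self.auc is not None:
            out["AUC"] = self.auc
        return {k: round(100.0 * v, ndigits) for k, v in out.items()}


def confusion_matrix(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with positive = high risk (1)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise EvaluationError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise EvaluationError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """All confusion-derived metrics; zero denominators give flagged zeros."""
    degenerate = False
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, degenerate = 0.0, True
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    else:
        f1, degenerate = 0.0, True
    accuracy = (c.tp + c.tn) / c.total
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom > 0:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    else:
        mcc, degenerate = 0.0, True
    return MetricReport(precision=precision, recall=recall, f1=f1,
                        accuracy=accuracy, mcc=mcc, confusion=c,
                        degenerate=degenerate)


def roc_auc(y_true, scores) -> tuple[float, RocCurve]:
    """AUC by rank statistics plus the ROC curve points.

    AUC = (R+ - n+(n+ + 1)/2) / (n+ n-) with midranks, i.e. the
    tie-corrected Mann-Whitney probability.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise EvaluationError("y_true and scores must have equal length")
    if not np.isin(y_true, (0, 1)).all():
        raise EvaluationError("y_true must be binary 0/1")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("both classes must be present for ROC analysis")
    ranks = rankdata(scores)
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp_cum = np.cumsum(y_true[order] == 1)
    fp_cum = np.cumsum(y_true[order] == 0)
    # keep one point per distinct threshold
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(sorted_scores) - 1]
    curve = RocCurve(
        fpr=np.r_[0.0, fp_cum[distinct] / n_neg],
        tpr=np.r_[0.0, tp_cum[distinct] / n_pos],
        thresholds=np.r_[np.inf, sorted_scores[distinct]],
    )
    return float(auc), curve


def render_report(reports: dict[str, MetricReport], out_dir,
                  curves: Optional[dict[str, RocCurve]] = None,
                  plot: bool = False) -> Path:
    """Write the experiment report files.

    ``metrics.csv`` — metric rows x model columns, percentages at
    2 decimals; ``metrics_full.json`` — full precision;
    ``confusion_<model>.csv`` — 2x2 count tables;
    ``roc_<model>.csv`` — curve points; optional ``roc.png``.
    """
    if not reports:
        raise EvaluationError("need at least one model report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = pd.DataFrame({name: rep.as_percent() for name, rep in reports.items()})
    table.index.name = "Metric"
    table.to_csv(out_dir / "metrics.csv")

    full = {name: {**asdict(rep), "confusion": asdict(rep.confusion)}
            for name, rep in reports.items()}
    (out_dir / "metrics_full.json").write_text(json.dumps(full, indent=2))

    for name, rep in reports.items():
        c = rep.confusion
        cm = pd.DataFrame(
            [[c.tn, c.fp], [c.fn, c.tp]],
            index=["Actual: Low Risk", "Actual: High Risk"],
            columns=["Predicted: Low Risk", "Predicted: High Risk"],
        )
        cm.to_csv(out_dir / f"confusion_{name}.csv")

    if curves:
        for name, curve in curves.items():
            pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr,
                          "threshold": curve.thresholds}).to_csv(
                out_dir / f"roc_{name}.csv", index=False)
        if plot:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(5, 5))
            for name, curve in curves.items():
                auc = reports[name].auc
                label = f"{name} (AUC = {auc:.2f})" if auc is not None else name
                ax.plot(curve.fpr, curve.tpr, label=label)
            ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="chance")
            ax.set_xlabel("False positive rate")
            ax.set_ylabel("True positive rate")
            ax.legend(loc="lower right")
            fig.savefig(out_dir / "roc.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
    return out_dir


def read_confusion_csv(path) -> ConfusionCounts:
    """Round-trip reader for the 2x2 tables written by render_report."""
    cm = pd.read_csv(path, index_col=0)
    return ConfusionCounts(tn=int(cm.iloc[0, 0]), fp=int(cm.iloc[0, 1]),
                           fn=int(cm.iloc[1, 0]), tp=int(cm.iloc[1, 1]))
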