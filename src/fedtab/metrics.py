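"""Diagnostic classification metrics with malignant (label 1) as positive class.

Confusion counts follow the clinical reading: a true positive is a malignant
case called malignant.  Rates with a zero denominator are reported as NaN — a
distinguished "undefined", never silently zero.  Percent rendering uses two
decimal places with round-half-even.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import FedtabError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise FedtabError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """All reported rates on [0, 1]; NaN marks an undefined ratio."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    tpr: float
    fpr: float
    tnr: float
    fnr: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise FedtabError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if len(arr) and not np.isin(arr, (0, 1)).all():
            raise FedtabError(f"{name} must be binary 0/1")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN when either is undefined."""
    if np.isnan(precision) or np.isnan(recall):
        return float("nan")
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def compute_report(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall/sensitivity, F1 and the four base rates."""
    if c.total == 0:
        raise FedtabError("cannot compute metrics from zero evaluated records")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)  # = sensitivity = TPR
    tnr = _ratio(c.tn, c.tn + c.fp)  # specificity
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        tpr=recall,
        fpr=_ratio(c.fp, c.fp + c.tn),
        tnr=tnr,
        fnr=_ratio(c.fn, c.fn + c.tp),
    )


def report_from_labels(y_true, y_pred) -> MetricsReport:
    return compute_report(confusion(y_true, y_pred))


def format_percent(value: float, decimals: int = 2) -> str:
    """Render a [0,1] rate as a percentage string, round-half-even."""
    if np.isnan(value):
        return "undefined"
    q = Decimal(1).scaleb(-decimals)
    return f"{Decimal(repr(value * 100)).quantize(q, rounding=ROUND_HALF_EVEN)}%"


_ROW_NAMES = {
    "tpr": "True Positive Rate (Sensitivity)",
    "fpr": "False Positive Rate",
    "tnr": "True Negative Rate (Specificity)",
    "fnr": "False Negative Rate",
    "accuracy": "Accuracy",
    "precision": "Precision",
    "f1": "F1-Score",
}


def report_to_frame(report: MetricsReport) -> pd.DataFrame:
    """Two-column table of the seven reported rows, values rendered as percent."""
    return pd.DataFrame(
        {
            "Metric": list(_ROW_NAMES.values()),
            "Value": [format_percent(getattr(report, k)) for k in _ROW_NAMES],
        }
    )


def write_report(report: MetricsReport, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    report_to_frame(report).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.as_dict(), indent=2))
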