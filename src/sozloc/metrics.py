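"""Contact-level classification metrics and cross-validation aggregation.

SOZ is the positive class.  Metrics are reported in percent; undefined
metrics (zero denominator) come back as NaN with a warning, never as 0,
and the cross-patient aggregate is the unweighted mean over patients,
skipping missing values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ConfusionCounts", "confusion", "metrics", "aggregate", "per_patient_metrics"]

METRIC_NAMES = ["SEN", "SPE", "ACC", "PPV", "NPV"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(
    predictions: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Count TP/TN/FP/FN at a probability threshold (SOZ positive)."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (y == 1)).sum()),
        TN=int(((pred == 0) & (y == 0)).sum()),
        FP=int(((pred == 1) & (y == 0)).sum()),
        FN=int(((pred == 0) & (y == 1)).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as missing")
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, PPV, NPV in percent.

    Values are carried at full precision; round for display.
    """
    c = counts
    return {
        "SEN": 100.0 * _safe_div(c.TP, c.TP + c.FN, "SEN"),
        "SPE": 100.0 * _safe_div(c.TN, c.TN + c.FP, "SPE"),
        "ACC": 100.0 * _safe_div(c.TP + c.TN, c.total, "ACC"),
        "PPV": 100.0 * _safe_div(c.TP, c.TP + c.FP, "PPV"),
        "NPV": 100.0 * _safe_div(c.TN, c.TN + c.FN, "NPV"),
    }


def aggregate(per_patient: list[dict[str, float]]) -> dict[str, float]:
    """Unweighted arithmetic mean of each metric over patients; missing
    values are skipped with a logged count."""
    if not per_patient:
        raise ValueError("need at least one patient")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in per_patient if name in m], dtype=float)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            warnings.warn(f"{name}: skipping {n_missing} missing per-patient values")
        out[name] = float(np.nanmean(vals))
    return out


def per_patient_metrics(
    predictions: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-patient confusion + metrics from a prediction table with
    ``patient_id``, ``probability``, ``label`` columns; returns the
    per-patient table and the cross-patient mean."""
    rows = []
    for pid, grp in predictions.groupby("patient_id"):
        c = confusion(grp["probability"].to_numpy(), grp["label"].to_numpy(), threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metrics(c)
        rows.append({"patient_id": pid, "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN, **m})
    table = pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)
    mean = aggregate([r for r in table[METRIC_NAMES].to_dict("records")])
    return table, mean
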