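"""Evaluation measures for angle and accessibility prediction.

Angles live on a circle: the absolute angular error between two rotational
angles x, y in [0, 360) is ``min(|x - y|, 360 - |x - y|)``, in [0, 180].
MAAE is its mean over helices.  rASA regression is scored with MAE, RMSE and
the Pearson correlation; burial classification with the Matthews correlation
coefficient, accuracy, sensitivity, specificity and precision (exposed
residues are the positive class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: Absolute slack used when counting errors against thresholds; printed
#: benchmark angles are rounded to 0.01°, so exact boundary hits occur.
_COUNT_ATOL = 1e-9


def angular_error(x: float, y: float) -> float:
    """Absolute circular difference of two angles, degrees in [0, 180]."""
    d = abs((float(x) % 360.0) - (float(y) % 360.0))
    return d if d <= 180.0 else 360.0 - d


def maae(pairs: Iterable[tuple[float, float]]) -> float:
    """Mean absolute angular error over (observed, predicted) pairs."""
    errs = [angular_error(x, y) for x, y in pairs]
    if not errs:
        raise ValueError("MAAE undefined for an empty pair list")
    return float(np.mean(errs))


def _paired(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("pred and obs must be equal-length non-empty 1-D arrays")
    return p, o


def mae(pred: Sequence[float], obs: Sequence[float]) -> float:
    p, o = _paired(pred, obs)
    return float(np.mean(np.abs(p - o)))


def rmse(pred: Sequence[float], obs: Sequence[float]) -> float:
    p, o = _paired(pred, obs)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def pcc(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation; raises on constant input (undefined)."""
    x, y = _paired(a, b)
    if x.size < 2:
        raise ValueError("PCC requires at least 2 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("PCC undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with exposed (E) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty confusion table")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def from_labels(true_labels: Sequence[str], pred_labels: Sequence[str],
                    positive: str = "E") -> "ConfusionCounts":
        if len(true_labels) != len(pred_labels):
            raise ValueError("label lists differ in length")
        tp = fp = tn = fn = 0
        for t, p in zip(true_labels, pred_labels):
            if p == positive:
                tp, fp = (tp + 1, fp) if t == positive else (tp, fp + 1)
            else:
                fn, tn = (fn + 1, tn) if t == positive else (fn, tn + 1)
        return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """MCC plus rate measures (percentages); undefined rates are None.

    MCC with a zero factor in its denominator is reported as 0 by the usual
    convention (the formula is undefined there).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fn) * float(tn + fp)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom > 0 else 0.0

    def rate(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return {
        "mcc": float(mcc),
        "accuracy": rate(tp + tn, counts.total),
        "sensitivity": rate(tp, tp + fn),
        "specificity": rate(tn, tn + fp),
        "precision": rate(tp, tp + fp),
    }


@dataclass
class EvalReport:
    """Aggregated evaluation of paired observed/predicted quantities."""

    maae: float | None = None
    mae: float | None = None
    rmse: float | None = None
    pcc: float | None = None
    classification: dict = field(default_factory=dict)
    n_helices: int = 0
    n_residues: int = 0

    def as_dict(self) -> dict:
        out = {
            "maae": self.maae,
            "mae": self.mae,
            "rmse": self.rmse,
            "pcc": self.pcc,
            "n_helices": self.n_helices,
            "n_residues": self.n_residues,
        }
        out.update(self.classification)
        return out


def error_percentile_summary(
    pairs: Iterable[tuple[float, float]],
    thresholds: Sequence[tuple[str, float]] = (("<", 10.0), ("<=", 43.0)),
) -> list[dict]:
    """Count angular errors satisfying each (comparator, threshold) bound.

    Comparators: ``"<"``, ``"<="``, ``">"``, ``">="``.  Comparisons carry a
    1e-9 absolute slack so errors recomputed from rounded printed angles
    count deterministically at exact boundaries.
    """
    errs = np.array([angular_error(x, y) for x, y in pairs], dtype=float)
    if errs.size == 0:
        raise ValueError("no pairs")
    ops = {
        "<": lambda e, t: e < t - _COUNT_ATOL,
        "<=": lambda e, t: e <= t + _COUNT_ATOL,
        ">": lambda e, t: e > t + _COUNT_ATOL,
        ">=": lambda e, t: e >= t - _COUNT_ATOL,
    }
    out = []
    for op, thr in thresholds:
        if op not in ops:
            raise ValueError(f"unknown comparator {op!r}")
        count = int(np.sum(ops[op](errs, float(thr))))
        out.append(
            {
                "comparator": op,
                "threshold": float(thr),
                "count": count,
                "percent": 100.0 * count / errs.size,
            }
        )
    return out
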