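"""Statistical evaluation: Welch t-test and diagnostic accuracy metrics.

The class-separation test is the unequal-variance (Welch) two-sample
t-test with Satterthwaite degrees of freedom — the variant consistent with
a 12-vs-25 comparison of features whose patient-class spread is triple the
normal-class spread.  Classifier performance is summarised as a 2x2
confusion matrix (patient = positive) and the five standard metrics:
sensitivity, specificity, PPV, NPV and accuracy, each available as a
fraction and as a percentage rounded half away from zero to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputError

POSITIVE = "patient"
NEGATIVE = "normal"


@dataclass
class TTestResult:
    t_value: float
    degrees_of_freedom: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.degrees_of_freedom > 0:
            raise InputError(f"df must be > 0, got {self.degrees_of_freedom}")
        if not (0 <= self.p_value <= 1):
            raise InputError(f"p-value outside [0, 1]: {self.p_value}")


def welch_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Two-sided Welch t-test of mean(group_a) - mean(group_b).

    Raises
    ------
    DegenerateInputError
        If a group has fewer than 2 values or both variances are zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateInputError("each group needs >= 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical constant groups: no evidence of difference
            return TTestResult(0.0, float(len(a) + len(b) - 2), 1.0)
        raise DegenerateInputError("both group variances are zero")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


@dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts with patient as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.total < 1:
            raise InputError("confusion matrix must count at least one subject")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def percent(fraction: Optional[float], decimals: int = 1) -> Optional[float]:
    """Render a fraction as a percentage, rounding half away from zero."""
    if fraction is None:
        return None
    scale = 10**decimals
    x = fraction * 100 * scale
    return math.copysign(math.floor(abs(x) + 0.5), x) / scale


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(cm: ConfusionMatrix) -> Dict[str, Optional[float]]:
    """The five diagnostic accuracy metrics as fractions and percents.

    A metric whose denominator is zero is reported as None (undefined),
    never as 0.
    """
    fractions = {
        "sensitivity": _ratio(cm.tp, cm.tp + cm.fn),
        "specificity": _ratio(cm.tn, cm.tn + cm.fp),
        "ppv": _ratio(cm.tp, cm.tp + cm.fp),
        "npv": _ratio(cm.tn, cm.tn + cm.fn),
        "accuracy": _ratio(cm.tp + cm.tn, cm.total),
    }
    out: Dict[str, Optional[float]] = dict(fractions)
    for name, frac in fractions.items():
        out[f"{name}_pct"] = percent(frac)
    return out


def evaluate(
    predicted: Sequence[str], truth: Sequence[str]
) -> Tuple[ConfusionMatrix, Dict[str, Optional[float]]]:
    """Tabulate predictions against gold-standard labels.

    Both sequences use the labels ``"patient"``/``"normal"``; patient is
    the positive class.
    """
    if len(predicted) != len(truth):
        raise InputError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths"
        )
    if len(predicted) == 0:
        raise InputError("empty label lists")
    valid = {POSITIVE, NEGATIVE}
    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for p, t in zip(predicted, truth):
        if p not in valid or t not in valid:
            raise InputError(f"unknown label in pair ({p!r}, {t!r})")
        if t == POSITIVE:
            counts["tp" if p == POSITIVE else "fn"] += 1
        else:
            counts["fp" if p == POSITIVE else "tn"] += 1
    cm = ConfusionMatrix(**counts)
    return cm, confusion_metrics(cm)
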