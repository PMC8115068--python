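"""Group discrimination: effect sizes, ROC analysis and the zero-false-positive
operating point.

The positive class is the treatment non-responder group. Because the
biomarker is expected to be *lower* in non-responders, scores carry an
orientation flag; when unset, orientation is chosen automatically so that
AUC >= 0.5 and the choice is recorded. Sensitivity at 100% specificity uses
a strict threshold inequality, so no negative-class subject is ever flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn import metrics as skmetrics

__all__ = [
    "LabelledScores",
    "RocResult",
    "EffectSizeResult",
    "cohens_d",
    "roc_curve",
    "sensitivity_at_full_specificity",
]


@dataclass(frozen=True)
class LabelledScores:
    """Biomarker values with binary labels (True = non-responder, positive).

    ``low_is_positive``: True if low values indicate the positive class,
    False if high values do, None to auto-orient (AUC >= 0.5).
    """

    values: np.ndarray
    labels: np.ndarray
    low_is_positive: bool | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        if values.shape != labels.shape or values.ndim != 1:
            raise ValueError("values and labels must be equal-length 1-D arrays")
        if labels.all() or not labels.any():
            raise ValueError("both classes must be non-empty")

    @classmethod
    def from_groups(
        cls,
        non_responders,
        responders,
        low_is_positive: bool | None = None,
    ) -> "LabelledScores":
        nr = np.asarray(non_responders, dtype=float)
        r = np.asarray(responders, dtype=float)
        return cls(
            np.concatenate([nr, r]),
            np.concatenate([np.ones(nr.size, bool), np.zeros(r.size, bool)]),
            low_is_positive,
        )


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    p_value: float  # vs. AUC = 0.5, rank-sum equivalence, two-sided
    sens_at_full_spec: float
    low_is_positive: bool  # resolved orientation
    orientation_fixed: bool  # False if auto-oriented


@dataclass(frozen=True)
class EffectSizeResult:
    cohens_d: float
    mean_a: float
    mean_b: float
    pooled_sd: float


def cohens_d(group_a, group_b) -> EffectSizeResult:
    """(mean_a - mean_b) / pooled SD, pooled with n_a + n_b - 2 denominator."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD; effect size undefined")
    return EffectSizeResult(
        float((a.mean() - b.mean()) / pooled), float(a.mean()), float(b.mean()), float(pooled)
    )


def _resolve_orientation(scores: LabelledScores) -> bool:
    if scores.low_is_positive is not None:
        return bool(scores.low_is_positive)
    pos = scores.values[scores.labels]
    neg = scores.values[~scores.labels]
    # auto: orient so that AUC >= 0.5 (rank statistic under each orientation)
    auc_high = stats.mannwhitneyu(pos, neg).statistic / (pos.size * neg.size)
    return bool(auc_high < 0.5)


def roc_curve(scores: LabelledScores) -> RocResult:
    """Empirical ROC over all distinct thresholds; AUC by trapezoid; p value
    from the two-sided Mann-Whitney test of the underlying rank statistic."""
    low_pos = _resolve_orientation(scores)
    oriented = -scores.values if low_pos else scores.values
    y = scores.labels.astype(int)
    if np.ptp(scores.values) == 0:
        warnings.warn("single distinct score value; AUC set to 0.5", stacklevel=2)
        n = scores.values.size
        return RocResult(
            thresholds=np.array([scores.values[0]]),
            sensitivity=np.array([1.0]),
            specificity=np.array([0.0]),
            auc=0.5,
            p_value=1.0,
            sens_at_full_spec=0.0,
            low_is_positive=low_pos,
            orientation_fixed=scores.low_is_positive is not None,
        )
    fpr, tpr, thr = skmetrics.roc_curve(y, oriented)
    auc = float(np.trapezoid(tpr, fpr))
    pos = oriented[scores.labels]
    neg = oriented[~scores.labels]
    p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)
    sens = _sens_full_spec(pos, neg)
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        p_value=p,
        sens_at_full_spec=sens,
        low_is_positive=low_pos,
        orientation_fixed=scores.low_is_positive is not None,
    )


def _sens_full_spec(pos_oriented: np.ndarray, neg_oriented: np.ndarray) -> float:
    # strict inequality: ties with the most extreme negative are not detections
    return float(np.mean(pos_oriented > neg_oriented.max()))


def sensitivity_at_full_specificity(scores: LabelledScores) -> float:
    """Largest sensitivity achievable with zero false positives.

    With low-positive orientation this is the fraction of positives strictly
    below the minimum negative value.
    """
    low_pos = _resolve_orientation(scores)
    oriented = -scores.values if low_pos else scores.values
    return _sens_full_spec(oriented[scores.labels], oriented[~scores.labels])
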