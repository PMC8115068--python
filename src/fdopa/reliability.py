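"""Test-retest statistics: %VAR, two-way ICC, and normality-gated correlation.

The ICC comes from a two-way subject x session ANOVA. Because the wording
"two-way random model with fixed session effects" is ambiguous between the
consistency and absolute-agreement forms, both are computed and tagged
explicitly (ICC(3,1) consistency is primary; ICC(2,1) absolute agreement is
also reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "VarResult",
    "IccResult",
    "GatedCorrelation",
    "percent_var",
    "icc_two_way",
    "gated_correlation",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Test and retest values of one metric in one region, same subjects."""

    subject_ids: tuple
    test: np.ndarray
    retest: np.ndarray

    def __post_init__(self) -> None:
        test = np.asarray(self.test, dtype=float)
        retest = np.asarray(self.retest, dtype=float)
        object.__setattr__(self, "test", test)
        object.__setattr__(self, "retest", retest)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        n = len(self.subject_ids)
        if test.shape != (n,) or retest.shape != (n,):
            raise ValueError("test/retest must be 1-D and match the subject list")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if not (np.all(np.isfinite(test)) and np.all(np.isfinite(retest))):
            raise ValueError("missing/non-finite values are not allowed")


@dataclass(frozen=True)
class VarResult:
    per_subject: np.ndarray  # percent
    mean: float


@dataclass(frozen=True)
class IccResult:
    icc: float  # primary value (consistency form)
    icc_consistency: float  # ICC(3,1)
    icc_absolute: float  # ICC(2,1)
    var_subjects: float
    var_sessions: float
    var_residual: float
    model: str = "two-way, single measure"


@dataclass(frozen=True)
class GatedCorrelation:
    coefficient: float
    method: str  # "pearson" | "spearman"
    p: float
    shapiro_p_x: float
    shapiro_p_y: float


def percent_var(pairs: PairedMeasurements) -> VarResult:
    """Percentage test-retest difference: 2|retest - test| / (test + retest) * 100."""
    denom = pairs.test + pairs.retest
    if np.any(denom <= 0):
        raise ValueError("test + retest must be positive for every subject")
    var = 2.0 * np.abs(pairs.retest - pairs.test) / denom * 100.0
    return VarResult(var, float(var.mean()))


def icc_two_way(pairs: PairedMeasurements) -> IccResult:
    """Single-measure ICC from the two-way subject x session mean squares.

    With n subjects and k = 2 sessions:
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)
        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    n = len(pairs.subject_ids)
    if n < 3:
        raise ValueError("need at least 3 subjects for a two-way ICC")
    data = np.column_stack((pairs.test, pairs.retest))
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom_c = msr + (k - 1) * mse
    icc_c = (msr - mse) / denom_c if denom_c > 0 else 0.0
    denom_a = denom_c + k * (msc - mse) / n
    icc_a = (msr - mse) / denom_a if denom_a > 0 else 0.0
    return IccResult(
        icc=float(icc_c),
        icc_consistency=float(icc_c),
        icc_absolute=float(icc_a),
        var_subjects=float(max((msr - mse) / k, 0.0)),
        var_sessions=float(max((msc - mse) / n, 0.0)),
        var_residual=float(mse),
    )


def gated_correlation(x, y, alpha: float = 0.05) -> GatedCorrelation:
    """Pearson correlation when both variables pass Shapiro-Wilk normality at
    ``alpha``, Spearman otherwise; the choice is recorded."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    p_x = float(stats.shapiro(x).pvalue)
    p_y = float(stats.shapiro(y).pvalue)
    if p_x > alpha and p_y > alpha:
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return GatedCorrelation(float(r), method, float(p), p_x, p_y)
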