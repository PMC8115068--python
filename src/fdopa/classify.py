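"""Voxel-wise responder/non-responder classification with LOOCV.

Features are per-voxel influx values over the striatal mask (default 2847
voxels), used raw with no further pre-processing. Labels follow the +1 =
non-responder / -1 = responder convention. Each model emits a continuous
decision score for every held-out subject; the pooled held-out scores form
one ROC AUC per seed. Regularised linear families minimise
``sum_i l(y_i, W x_i + b) + alpha ||W||^2`` with alpha = 1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .core import MaskVolume
from .patlak import ParametricMap
from .roc import LabelledScores, roc_curve

__all__ = [
    "FeatureMatrix",
    "ModelSpec",
    "CvResult",
    "MODEL_FAMILIES",
    "extract_feature_matrix",
    "loocv_evaluate",
    "combine_cohorts",
]

MODEL_FAMILIES = (
    "bernoulli_logistic",
    "linear_svm",
    "rbf_svm",
    "random_forest",
    "knn",
    "gp_probit",
)
STOCHASTIC_FAMILIES = frozenset({"random_forest"})

LABEL_BY_GROUP = {"non_responder": 1, "responder": -1}


@dataclass(frozen=True)
class FeatureMatrix:
    """N subjects x V voxels of raw influx values with +/-1 labels."""

    X: np.ndarray
    y: np.ndarray
    voxel_index: np.ndarray  # flat mask indices defining column order
    subject_ids: tuple

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "voxel_index", np.asarray(self.voxel_index))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] != len(self.subject_ids):
            raise ValueError("X must be (N, V) matching labels and subject ids")
        if X.shape[1] != self.voxel_index.size:
            raise ValueError("column count must match the voxel index")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be +1 (non-responder) or -1 (responder)")


def extract_feature_matrix(
    maps: list[ParametricMap | np.ndarray],
    groups: list[str],
    mask: MaskVolume,
    subject_ids: list[str] | None = None,
) -> FeatureMatrix:
    """Flatten each subject's striatal voxels (fixed mask linear order) into
    one row; groups must be 'responder' or 'non_responder'."""
    if len(maps) != len(groups):
        raise ValueError("one group label per map required")
    unknown = sorted(set(groups) - set(LABEL_BY_GROUP))
    if unknown:
        raise ValueError(f"groups must be responder/non_responder, got {unknown}")
    idx = mask.region_indices("striatum")
    rows = []
    for m in maps:
        vol = m.ki if isinstance(m, ParametricMap) else np.asarray(m, dtype=float)
        if vol.shape != mask.data.shape:
            raise ValueError(
                f"map shape {vol.shape} does not match mask {mask.data.shape}"
            )
        row = vol.ravel()[idx]
        if not np.all(np.isfinite(row)):
            raise ValueError("subject map has missing voxels inside the mask")
        rows.append(row)
    y = np.array([LABEL_BY_GROUP[g] for g in groups])
    ids = tuple(subject_ids) if subject_ids is not None else tuple(
        f"s{i:03d}" for i in range(len(maps))
    )
    return FeatureMatrix(np.vstack(rows), y, idx, ids)


@dataclass(frozen=True)
class ModelSpec:
    """A member of the fixed model zoo.

    ``alpha`` is the ridge-type penalty weight of the linear families
    (sklearn's C = 1 / (2 alpha)); remaining fields configure the non-linear
    members where the protocol is silent.
    """

    family: str
    alpha: float = 1.0
    k_neighbors: int = 2
    n_trees: int = 100
    kernel_scale: float | None = None  # rbf_svm gamma; None -> 1/(V * var)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    @property
    def stochastic(self) -> bool:
        return self.family in STOCHASTIC_FAMILIES

    def build(self, seed: int = 0):
        c = 1.0 / (2.0 * self.alpha)
        if self.family == "bernoulli_logistic":
            return LogisticRegression(C=c, max_iter=5000)
        if self.family == "linear_svm":
            return SVC(kernel="linear", C=c)
        if self.family == "rbf_svm":
            gamma = "scale" if self.kernel_scale is None else self.kernel_scale
            return SVC(kernel="rbf", C=c, gamma=gamma)
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, max_features="sqrt", random_state=seed
            )
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=self.k_neighbors)
        if self.family == "gp_probit":
            return GaussianProcessClassifier(kernel=RBF(length_scale=1.0), random_state=seed)
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class CvResult:
    family: str
    per_seed_auc: np.ndarray
    mean_auc: float
    sd_auc: float
    n_seeds: int
    n_failed_folds: int = 0


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    col = int(np.flatnonzero(model.classes_ == 1)[0])
    return np.asarray(proba[:, col], dtype=float)


def loocv_evaluate(
    spec: ModelSpec, features: FeatureMatrix, seeds=None
) -> CvResult:
    """Leave-one-out CV: pool the N held-out decision scores into one ROC AUC
    per seed; stochastic families default to 100 seeds, deterministic to 1.

    Each held-out score is referenced to its fold's mean training score.
    Raw pooled scores carry a fold-composition offset (holding out a positive
    subject shifts the training balance negative and vice versa) that biases
    the permutation-null AUC well below 0.5; centering removes the offset
    without touching within-fold ranking.
    """
    X, y = features.X, features.y
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs N >= 4 subjects")
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("need >= 2 subjects per class")
    if seeds is None:
        seeds = range(100) if spec.stochastic else (0,)
    seeds = list(seeds)
    aucs = []
    n_failed = 0
    for seed in seeds:
        scores = np.full(n, np.nan)
        for i in range(n):
            tr = np.arange(n) != i
            model = spec.build(seed=seed)
            try:
                model.fit(X[tr], y[tr])
                held = _decision_scores(model, X[i:i + 1])[0]
                scores[i] = held - _decision_scores(model, X[tr]).mean()
            except Exception:
                n_failed += 1
        ok = np.isfinite(scores)
        labelled = LabelledScores(scores[ok], y[ok] == 1, low_is_positive=False)
        aucs.append(roc_curve(labelled).auc)
    aucs = np.asarray(aucs)
    return CvResult(
        family=spec.family,
        per_seed_auc=aucs,
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0,
        n_seeds=len(seeds),
        n_failed_folds=n_failed,
    )


def combine_cohorts(a: FeatureMatrix, b: FeatureMatrix) -> FeatureMatrix:
    """Row-concatenate two cohorts sharing the same voxel ordering."""
    if a.voxel_index.shape != b.voxel_index.shape or np.any(a.voxel_index != b.voxel_index):
        raise ValueError("cohorts use different masks/voxel orderings")
    return FeatureMatrix(
        np.vstack([a.X, b.X]),
        np.concatenate([a.y, b.y]),
        a.voxel_index,
        a.subject_ids + b.subject_ids,
    )
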