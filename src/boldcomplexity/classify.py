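"""Task-specificity via pairwise SVM classification of complexity maps.

Each fMRI run contributes one feature matrix (subjects × ROIs) of a
complexity statistic. For every unordered pair of runs a binary SVM is
evaluated by stratified k-fold cross-validation with an inner grid search
over the box constraint C (and kernel scale for the RBF kernel), and the
misclassification fraction is recorded. Runs whose complexity profiles are
statistically exchangeable (e.g. two rest runs) should sit near chance
(loss ≈ 0.5); runs with distinct regional complexity separate towards 0.

Both RBF and linear kernels are exposed; the RBF kernel-scale grid is a set
of multipliers of the median heuristic 1/median(pairwise squared distance),
computed once on the pooled pair data (a scale heuristic, not a fitted
parameter, so it does not bias the cross-validated loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ValidationError

DEFAULT_BOX_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_SCALE_GRID = (0.1, 1.0, 10.0)  # multipliers of the median heuristic
DEFAULT_CV_FOLDS = 5
INNER_CV_FOLDS = 3


def _median_heuristic_gamma(features: np.ndarray) -> float:
    # the RBF kernel sees standardised features (the pipeline scales them),
    # so the length-scale heuristic must be computed on the same scale
    scaled = StandardScaler().fit_transform(features)
    d2 = pairwise_distances(scaled, metric="sqeuclidean")
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    if med <= 0:
        return 1.0
    return 1.0 / med


def _build_search(kernel: str, gamma_base: float,
                  box_grid: Sequence[float],
                  scale_grid: Sequence[float],
                  seed: int) -> GridSearchCV:
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel=kernel)),
    ])
    grid: dict[str, list] = {"svc__C": list(box_grid)}
    if kernel == "rbf":
        grid["svc__gamma"] = [gamma_base * s for s in scale_grid]
    inner = StratifiedKFold(n_splits=INNER_CV_FOLDS, shuffle=True,
                            random_state=seed)
    return GridSearchCV(pipe, grid, cv=inner, scoring="accuracy", n_jobs=None)


def pairwise_loss(
    features_a: np.ndarray,
    features_b: np.ndarray,
    cv_folds: int = DEFAULT_CV_FOLDS,
    kernel: str = "rbf",
    box_grid: Sequence[float] = DEFAULT_BOX_GRID,
    scale_grid: Sequence[float] = DEFAULT_SCALE_GRID,
    seed: int = 0,
) -> float:
    """Cross-validated misclassification fraction between two run populations.

    Features are standardised inside each training fold; hyper-parameters
    are chosen by an inner grid search (nested CV keeps the outer loss
    unbiased). Deterministic for a given seed.
    """
    a = np.asarray(features_a, dtype=float)
    b = np.asarray(features_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValidationError("feature matrices must be 2-D with equal width")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("NaN features are not allowed")
    if kernel not in ("rbf", "linear"):
        raise ValidationError("kernel must be 'rbf' or 'linear'")
    if min(a.shape[0], b.shape[0]) < 2 * cv_folds:
        raise ValidationError(
            f"need ≥ {2 * cv_folds} observations per class for "
            f"{cv_folds}-fold CV")
    x = np.vstack([a, b])
    y = np.concatenate([np.zeros(a.shape[0]), np.ones(b.shape[0])])
    gamma_base = _median_heuristic_gamma(x) if kernel == "rbf" else 1.0
    search = _build_search(kernel, gamma_base, box_grid, scale_grid, seed)
    outer = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accuracy = cross_val_score(search, x, y, cv=outer, scoring="accuracy")
    return float(1.0 - accuracy.mean())


@dataclass
class LossMatrix:
    """Symmetric run × run misclassification matrix (diagonal undefined)."""

    runs: list[str]
    loss: np.ndarray
    cv_folds: int
    kernel: str
    box_grid: tuple[float, ...]
    scale_grid: tuple[float, ...]
    selected_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.loss = np.asarray(self.loss, dtype=float)
        k = len(self.runs)
        if self.loss.shape != (k, k):
            raise ValidationError("loss matrix shape must match run count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loss, index=self.runs, columns=self.runs)


def loss_matrix(
    run_features: dict[str, np.ndarray],
    cv_folds: int = DEFAULT_CV_FOLDS,
    kernel: str = "rbf",
    box_grid: Sequence[float] = DEFAULT_BOX_GRID,
    scale_grid: Sequence[float] = DEFAULT_SCALE_GRID,
    seed: int = 0,
) -> LossMatrix:
    """Evaluate every unordered pair of runs once; mirror into a matrix.

    Also records, per pair, the hyper-parameters a grid search selects on
    the pooled pair data (for reporting; the loss itself comes from nested
    cross-validation).
    """
    runs = list(run_features)
    if len(runs) < 2:
        raise ValidationError("need at least two runs")
    k = len(runs)
    loss = np.full((k, k), np.nan)
    selected: dict[str, dict] = {}
    for (i, name_a), (j, name_b) in combinations(enumerate(runs), 2):
        a, b = run_features[name_a], run_features[name_b]
        value = pairwise_loss(a, b, cv_folds=cv_folds, kernel=kernel,
                              box_grid=box_grid, scale_grid=scale_grid,
                              seed=seed)
        loss[i, j] = loss[j, i] = value
        x = np.vstack([a, b])
        y = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
        gamma_base = _median_heuristic_gamma(x) if kernel == "rbf" else 1.0
        search = _build_search(kernel, gamma_base, box_grid, scale_grid, seed)
        search.fit(x, y)
        selected[f"{name_a}|{name_b}"] = {
            key.replace("svc__", ""): float(val)
            for key, val in search.best_params_.items()}
    return LossMatrix(runs=runs, loss=loss, cv_folds=cv_folds, kernel=kernel,
                      box_grid=tuple(box_grid), scale_grid=tuple(scale_grid),
                      selected_params=selected)
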