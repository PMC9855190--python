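"""Two-stage feature selection: univariate ANOVA-F filter, then RFE-CV.

The univariate stage ranks features by the two-group ANOVA F statistic and
keeps the top proportion. The surviving features are handed to recursive
feature elimination: a kernel classifier is fitted, the weakest features
(smallest |coefficient| for linear kernels, smallest impurity importance for
tree kernels) are dropped ``rfe_step`` at a time, and each candidate feature
count is scored by stratified k-fold cross-validated balanced accuracy. The
count with the best mean score wins (ties go to the smaller count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .features import FeatureMatrix

SELECTION_KERNELS = ("lsvm", "lr", "rf", "lgbm")


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the two-stage cascade."""

    univariate_proportion: float = 0.25
    rfe_step: int = 2
    folds: int = 5
    kernel: str = "lsvm"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.univariate_proportion <= 1.0):
            raise ValueError("univariate_proportion must be in (0, 1]")
        if self.rfe_step < 1 or self.folds < 2:
            raise ValueError("require rfe_step >= 1 and folds >= 2")
        if self.kernel not in SELECTION_KERNELS:
            raise ValueError(f"unknown selection kernel {self.kernel!r}")


@dataclass
class SelectionResult:
    kernel: str
    selected_names: list[str]
    cv_score_by_count: dict[int, float]
    best_score: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "selected_names": self.selected_names,
            "cv_score_by_count": {str(k): v for k, v in self.cv_score_by_count.items()},
            "best_score": self.best_score,
            "seed": self.seed,
        }


def univariate_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-group ANOVA F per feature; constant features score 0."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("univariate selection needs two classes")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, _ = f_classif(X, y)
    f = np.asarray(f, dtype=float)
    f[~np.isfinite(f)] = np.inf  # zero within-group variance, non-constant: maximal
    f[X.std(axis=0) == 0.0] = 0.0
    return f


def univariate_f_select(X: FeatureMatrix, y: np.ndarray, proportion: float) -> FeatureMatrix:
    """Keep the ceil(proportion * n_features) features with the largest F.

    Ties are broken by original column order (stable sort on -F).
    """
    if not (0.0 < proportion <= 1.0):
        raise ValueError("proportion must be in (0, 1]")
    f = univariate_f_scores(X.values, y)
    k = math.ceil(proportion * X.n_features)
    order = np.argsort(-f, kind="stable")[:k]
    keep = np.sort(order)  # preserve original column order
    return X.subset([X.feature_names[i] for i in keep])


def make_selection_kernel(kernel: str, seed: int):
    """Build the (possibly scaler-wrapped) RFE kernel estimator.

    Linear kernels are standardized inside each CV fold via a pipeline;
    elimination uses |coef| for linear and impurity importance for trees.
    """
    if kernel == "lsvm":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("est", LinearSVC(C=1.0, dual=False, max_iter=5000, random_state=seed)),
        ])
        getter = "named_steps.est.coef_"
    elif kernel == "lr":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("est", LogisticRegression(C=1.0, max_iter=5000, random_state=seed)),
        ])
        getter = "named_steps.est.coef_"
    elif kernel == "rf":
        est = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
        getter = "auto"
    elif kernel == "lgbm":
        from lightgbm import LGBMClassifier

        est = LGBMClassifier(
            n_estimators=100, random_state=seed, n_jobs=1, verbosity=-1,
            min_child_samples=5,
        )
        getter = "auto"
    else:
        raise ValueError(f"unknown selection kernel {kernel!r}")
    return est, getter


def rfe_cv(X: FeatureMatrix, y: np.ndarray, config: SelectionConfig) -> SelectionResult:
    """Recursive feature elimination scored by stratified k-fold balanced accuracy."""
    if X.n_features < config.rfe_step:
        raise ValueError("fewer features than one elimination step")
    est, getter = make_selection_kernel(config.kernel, config.seed)
    cv = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    selector = RFECV(
        estimator=est,
        step=config.rfe_step,
        min_features_to_select=1,
        cv=cv,
        scoring="balanced_accuracy",
        importance_getter=getter,
        n_jobs=1,
    )
    try:
        selector.fit(X.values, y)
    except Exception as exc:  # pragma: no cover - kernel-specific failure path
        raise RuntimeError(f"RFE kernel {config.kernel!r} failed to fit: {exc}") from exc
    counts = selector.cv_results_["n_features"]
    means = selector.cv_results_["mean_test_score"]
    by_count = {int(c): float(m) for c, m in zip(counts, means)}
    selected = [n for n, keep in zip(X.feature_names, selector.support_) if keep]
    return SelectionResult(
        kernel=config.kernel,
        selected_names=selected,
        cv_score_by_count=by_count,
        best_score=float(np.max(means)),
        seed=config.seed,
    )


def select_features(
    X: FeatureMatrix, y: np.ndarray, config: SelectionConfig
) -> tuple[FeatureMatrix, SelectionResult]:
    """Full cascade: univariate filter then RFE-CV; returns the reduced matrix."""
    reduced = univariate_f_select(X, y, config.univariate_proportion)
    result = rfe_cv(reduced, y, config)
    return reduced.subset(result.selected_names), result


def run_selection_grid(
    X: FeatureMatrix,
    y: np.ndarray,
    kernels: list[str] = list(SELECTION_KERNELS),
    config: SelectionConfig = SelectionConfig(),
) -> list[SelectionResult]:
    """Run the cascade once per kernel with identical folds (shared seed)."""
    reduced = univariate_f_select(X, y, config.univariate_proportion)
    out = []
    for kernel in kernels:
        cfg = SelectionConfig(
            univariate_proportion=config.univariate_proportion,
            rfe_step=config.rfe_step,
            folds=config.folds,
            kernel=kernel,
            seed=config.seed,
        )
        out.append(rfe_cv(reduced, y, cfg))
    return out
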