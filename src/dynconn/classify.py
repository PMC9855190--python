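"""Classifier bank with randomized hyperparameter search and diagnosis metrics.

Six classifier families are benchmarked: linear SVM (lsvm), logistic
regression (lr), random forest (rf), light gradient-boosted trees (lgbm), a
multilayer-perceptron neural network (nn), and an RBF-kernel SVM (svm).
Hyperparameters are tuned by seeded random search under stratified k-fold
cross-validation, optimizing balanced accuracy; the winning configuration is
then re-scored fold by fold to record accuracy, sensitivity, specificity and
balanced accuracy with their dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .features import FeatureMatrix
from .selection import SelectionResult

CLASSIFIERS = ("lsvm", "lr", "rf", "lgbm", "nn", "svm")

#: Classifiers whose inputs are standardized (train-fold statistics) in-fold.
SCALED = {"lsvm", "lr", "nn", "svm"}


def default_search_space(name: str) -> dict:
    """Conventional random-search distributions per classifier family."""
    if name == "lsvm":
        return {"est__C": loguniform(1e-3, 1e3)}
    if name == "lr":
        return {"est__C": loguniform(1e-3, 1e3)}
    if name == "svm":
        return {"est__C": loguniform(1e-3, 1e3), "est__gamma": loguniform(1e-4, 1e1)}
    if name == "rf":
        return {
            "n_estimators": randint(100, 1001),
            "max_depth": [None] + list(range(3, 21)),
        }
    if name == "lgbm":
        return {
            "learning_rate": loguniform(1e-3, 0.3),
            "num_leaves": randint(15, 256),
        }
    if name == "nn":
        return {
            "est__hidden_layer_sizes": [
                (32,), (64,), (128,), (32, 32), (64, 64), (128, 128),
            ],
            "est__alpha": loguniform(1e-5, 1e-1),
        }
    raise ValueError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    search_space: Mapping | None = None
    n_iter: int = 50
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.name!r}")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    def space(self) -> dict:
        return dict(self.search_space) if self.search_space else default_search_space(self.name)


@dataclass
class ClassifierResult:
    name: str
    best_params: dict
    fold_scores: pd.DataFrame  # columns: accuracy, sensitivity, specificity, balanced_accuracy
    seed: int

    @property
    def mean_std(self) -> pd.DataFrame:
        return self.fold_scores.agg(["mean", "std"])

    @property
    def balanced_accuracy(self) -> float:
        return float(self.fold_scores["balanced_accuracy"].mean())


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Diagnosis metrics from a confusion table (positive class = ASD).

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy is the
    overall fraction correct, and balanced accuracy is the mean of
    sensitivity and specificity.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fn < 1 or tn + fp < 1:
        raise ValueError("both classes must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def make_classifier(name: str, params: Mapping | None = None, seed: int = 0):
    """Instantiate one classifier, scaler-wrapped where scale-sensitive."""
    params = dict(params or {})
    if name == "lsvm":
        est = LinearSVC(dual=False, max_iter=5000, random_state=seed)
    elif name == "lr":
        est = LogisticRegression(max_iter=5000, random_state=seed)
    elif name == "svm":
        est = SVC(kernel="rbf", random_state=seed)
    elif name == "nn":
        est = MLPClassifier(max_iter=800, random_state=seed)
    elif name == "rf":
        est = RandomForestClassifier(random_state=seed, n_jobs=1)
    elif name == "lgbm":
        from lightgbm import LGBMClassifier

        est = LGBMClassifier(
            n_estimators=200, random_state=seed, n_jobs=1, verbosity=-1,
            min_child_samples=5,
        )
    else:
        raise ValueError(f"unknown classifier {name!r}")
    model = Pipeline([("scale", StandardScaler()), ("est", est)]) if name in SCALED else est
    if params:
        model.set_params(**params)
    return model


def _fold_metrics(model, X: np.ndarray, y: np.ndarray, cv: StratifiedKFold) -> pd.DataFrame:
    """Fit/predict per fold and compute confusion metrics (positive class = 1)."""
    from sklearn.base import clone

    rows = []
    for train, test in cv.split(X, y):
        m = clone(model)
        m.fit(X[train], y[train])
        pred = m.predict(X[test])
        yt = y[test]
        tp = int(np.sum((pred == 1) & (yt == 1)))
        tn = int(np.sum((pred == 0) & (yt == 0)))
        fp = int(np.sum((pred == 1) & (yt == 0)))
        fn = int(np.sum((pred == 0) & (yt == 1)))
        rows.append(confusion_metrics(tp, tn, fp, fn))
    return pd.DataFrame(rows)


def random_search_cv(
    X: FeatureMatrix | np.ndarray, y: np.ndarray, spec: ClassifierSpec
) -> ClassifierResult:
    """Seeded random search over ``ClassifierSpec.search_space``, scored by balanced accuracy.

    Every sampled configuration is evaluated on the same stratified folds;
    the first configuration attaining the best mean balanced accuracy wins
    and its per-fold confusion metrics are recorded.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(Xv).all():
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("need two classes")
    cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    sampled = list(ParameterSampler(spec.space(), n_iter=spec.n_iter, random_state=spec.seed))
    best: tuple[float, int, dict, pd.DataFrame] | None = None
    for i, params in enumerate(sampled):
        model = make_classifier(spec.name, params, seed=spec.seed)
        folds = _fold_metrics(model, Xv, y, cv)
        score = float(folds["balanced_accuracy"].mean())
        if best is None or score > best[0]:  # strict: ties keep the first sampled
            best = (score, i, params, folds)
    assert best is not None
    _, _, params, folds = best
    return ClassifierResult(name=spec.name, best_params=dict(params), fold_scores=folds, seed=spec.seed)


def nested_evaluate(
    X: FeatureMatrix,
    y: np.ndarray,
    sel_config,
    classifier: str = "lsvm",
    params: Mapping | None = None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Leakage-free protocol: refit the selection cascade inside every fold.

    The default protocol runs feature selection once on the full sample
    before cross-validating classifiers (the literal sequential pipeline),
    which leaks selection information into the test folds and inflates null
    scores. Here the univariate filter and RFE-CV are refit on each
    training fold only, and the classifier is scored on the untouched test
    fold. Returns per-fold confusion metrics.
    """
    from sklearn.base import clone

    from .selection import select_features

    Xv = X.values
    y = np.asarray(y)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for train, test in cv.split(Xv, y):
        fm_train = FeatureMatrix(
            Xv[train], list(X.feature_names), X.representation,
            [X.subject_ids[i] for i in train], X.atlas_tag, X.strategy_tag,
        )
        selected, res = select_features(fm_train, y[train], sel_config)
        cols = [X.feature_names.index(n) for n in res.selected_names]
        model = make_classifier(classifier, params, seed=seed)
        model.fit(Xv[np.ix_(train, cols)], y[train])
        pred = model.predict(Xv[np.ix_(test, cols)])
        yt = y[test]
        tp = int(np.sum((pred == 1) & (yt == 1)))
        tn = int(np.sum((pred == 0) & (yt == 0)))
        fp = int(np.sum((pred == 1) & (yt == 0)))
        fn = int(np.sum((pred == 0) & (yt == 1)))
        rows.append(confusion_metrics(tp, tn, fp, fn))
    return pd.DataFrame(rows)


def evaluate_all(
    runs: Sequence[tuple[FeatureMatrix, SelectionResult]],
    classifiers: Sequence[str] = CLASSIFIERS,
    n_iter: int = 50,
    folds: int = 5,
    seed: int = 0,
    y_by_run: Sequence[np.ndarray] | None = None,
    y: np.ndarray | None = None,
    checkpoint_path=None,
) -> pd.DataFrame:
    """Score every (selected feature matrix, kernel) x classifier cell.

    ``runs`` pairs each already-selected FeatureMatrix with the
    SelectionResult that produced it (carrying the kernel identity). Returns
    the long-format configuration table with one row per
    (representation, atlas, strategy, kernel, classifier). The evaluation
    folds use a seed distinct from the selection folds (fresh random split).
    If ``checkpoint_path`` is given, rows are flushed there as they finish
    and completed cells are skipped on re-run.
    """
    import pandas as pd

    done = pd.DataFrame()
    if checkpoint_path is not None:
        from pathlib import Path

        if Path(checkpoint_path).exists():
            done = pd.read_csv(checkpoint_path)
    rows = [] if done.empty else done.to_dict("records")
    key_cols = ["feat", "atls", "strat", "kernel", "classifier"]
    existing = {tuple(r[c] for c in key_cols) for r in rows}
    eval_seed = int(np.random.SeedSequence([seed, 0x5EED]).generate_state(1)[0] % (2**31))
    for idx, (fm, sel) in enumerate(runs):
        yy = np.asarray(y_by_run[idx] if y_by_run is not None else y)
        for clf in classifiers:
            key = (fm.representation, fm.atlas_tag, fm.strategy_tag, sel.kernel, clf)
            if key in existing:
                continue
            spec = ClassifierSpec(name=clf, n_iter=n_iter, folds=folds, seed=eval_seed)
            res = random_search_cv(fm, yy, spec)
            ms = res.fold_scores.mean()
            sd = res.fold_scores.std()
            rows.append(
                {
                    "feat": fm.representation,
                    "atls": fm.atlas_tag,
                    "strat": fm.strategy_tag,
                    "kernel": sel.kernel,
                    "classifier": clf,
                    "score": float(ms["balanced_accuracy"]),
                    "score_sd": float(sd["balanced_accuracy"]),
                    "accuracy": float(ms["accuracy"]),
                    "accuracy_sd": float(sd["accuracy"]),
                    "sensitivity": float(ms["sensitivity"]),
                    "sensitivity_sd": float(sd["sensitivity"]),
                    "specificity": float(ms["specificity"]),
                    "specificity_sd": float(sd["specificity"]),
                    "n_features": fm.n_features,
                    "best_params": repr(res.best_params),
                    "seed": seed,
                }
            )
            if checkpoint_path is not None:
                pd.DataFrame(rows).to_csv(checkpoint_path, index=False)
    return pd.DataFrame(rows)
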