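"""Self-contained benchmark experiments on synthetic cohorts.

These are the package's standing calibration/validation experiments: each
builds its own synthetic data from an explicit seed, runs the relevant
pipeline stages, and returns the measured quantities. They double as
regression checks (the test suite asserts on their outputs) and as a quick
way for users to sanity-check an installation.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, CLASSIFIERS, random_search_cv
from .factorial import three_way_anova
from .features import GaussianWindowSpec, ThresholdSpec, build_feature_matrix, dfc_pair, pearson, windowed_correlations
from .selection import SelectionConfig, make_selection_kernel, rfe_cv, select_features
from .simulate import GroupEffect, StateModel, simulate_cohort, simulate_subject

#: Seed used by the documented reference runs of these experiments.
DEFAULT_SEED = 0


def nst_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    length_tr: int = 2000,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    base_corr: float = 0.95,
) -> pd.DataFrame:
    """Recovery of planted connected-state fractions by the nst statistic.

    For each requested fraction, a two-region pair is simulated ``n_seeds``
    times; nst (fraction of Gaussian-windowed correlations >= 0.8) is
    averaged over the replicates and compared to the planted fraction.
    """
    win = GaussianWindowSpec()
    thr = ThresholdSpec()
    rows = []
    for f in fractions:
        nsts = []
        for s in range(n_seeds):
            model = StateModel(n_regions=2, base_corr=base_corr,
                               pair_state_fraction={(0, 1): float(f)})
            ts = simulate_subject(model, length_tr, seed=seed + s)
            rhos = windowed_correlations(ts.data[:, 0], ts.data[:, 1], win)
            nsts.append(dfc_pair(rhos, thr)[1])
        rows.append({"fraction": f, "mean_nst": float(np.mean(nsts)),
                     "abs_error": float(abs(np.mean(nsts) - f))})
    return pd.DataFrame(rows)


def windowed_oracle_deviation(seed: int = 0, n_pairs: int = 100) -> float:
    """Max |vectorized - naive| windowed correlation over random series pairs.

    The oracle slices each window, mean-centres, tapers, and calls the plain
    Pearson routine.
    """
    rng = np.random.default_rng(seed)
    win = GaussianWindowSpec()
    worst = 0.0
    for _ in range(n_pairs):
        length = int(rng.integers(40, 160))
        x, y = rng.standard_normal((2, length)) + rng.uniform(-3, 3, (2, 1))
        fast = windowed_correlations(x, y, win)
        g = win.taper()
        slow = []
        for start in range(0, length - win.width_tr + 1, win.step_tr):
            xs = x[start:start + win.width_tr]
            ys = y[start:start + win.width_tr]
            slow.append(pearson((xs - xs.mean()) * g, (ys - ys.mean()) * g))
        worst = max(worst, float(np.max(np.abs(fast - np.array(slow)))))
    return worst


def rfe_vs_exhaustive(seed: int = 0) -> dict[str, float]:
    """RFE-CV selection versus brute-force best subset on 6 features, 40 samples.

    Both routes share the same stratified folds and linear-SVM kernel; the
    exhaustive route scores all 63 non-empty feature subsets.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    from .features import FeatureMatrix

    rng = np.random.default_rng(seed)
    n = 40
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, 6))
    X[:, 0] += 1.5 * y
    X[:, 3] += 1.0 * y
    fm = FeatureMatrix(X, [f"f{i}" for i in range(6)], "FC",
                       [f"s{i}" for i in range(n)])
    cfg = SelectionConfig(kernel="lsvm", seed=seed, rfe_step=1)
    res = rfe_cv(fm, y, cfg)
    cv = StratifiedKFold(cfg.folds, shuffle=True, random_state=cfg.seed)

    def score(cols: list[int]) -> float:
        est, _ = make_selection_kernel("lsvm", cfg.seed)
        return float(cross_val_score(est, X[:, cols], y, cv=cv,
                                     scoring="balanced_accuracy").mean())

    exhaustive_best = max(
        score(list(cols))
        for r in range(1, 7)
        for cols in itertools.combinations(range(6), r)
    )
    rfe_score = score([fm.feature_names.index(nm) for nm in res.selected_names])
    return {"rfe_score": rfe_score, "exhaustive_best": exhaustive_best,
            "gap": rfe_score - exhaustive_best}


def null_calibration(
    seed: int = 0,
    n_subjects_per_group: int = 50,
    length_tr: int = 120,
    n_iter: int = 8,
    classifiers: tuple[str, ...] = CLASSIFIERS,
) -> dict[str, float]:
    """Best cross-validated balanced accuracy per classifier on permuted labels.

    A 6-region cohort (one genuinely connected pair, identical in both
    groups) is simulated, dFC features extracted, and the diagnosis labels
    permuted so any apparent signal is spurious.
    """
    model = StateModel(n_regions=6, base_corr=0.9, pair_state_fraction={(0, 1): 0.7})
    cohort = simulate_cohort(n_subjects_per_group, n_subjects_per_group, model,
                             length_tr=length_tr, seed=seed)
    fm = build_feature_matrix(cohort, "dFC")
    rng = np.random.default_rng(seed + 1)
    y = rng.permutation(cohort.labels)
    return {
        clf: random_search_cv(fm, y, ClassifierSpec(clf, n_iter=n_iter, seed=seed)).balanced_accuracy
        for clf in classifiers
    }


def null_anova_min_p(seed: int = 0, n_tables: int = 20, n_rep: int = 24) -> float:
    """Smallest p-value over full three-way ANOVAs of pure-noise score grids.

    Each table covers the full 2 x 4 x 2 (feat x strat x atls) design with
    ``n_rep`` iid Normal(0.75, 0.05) scores per cell.
    """
    min_p = 1.0
    for k in range(n_tables):
        rng = np.random.default_rng(seed + k)
        rows = []
        for feat, strat, atls in itertools.product(
            ["FC", "dFC"],
            ["filt_global", "filt_noglobal", "nofilt_global", "nofilt_noglobal"],
            ["AAL", "TT"],
        ):
            for _ in range(n_rep):
                rows.append(dict(feat=feat, strat=strat, atls=atls,
                                 score=0.75 + rng.normal(0, 0.05)))
        full, _ = three_way_anova(pd.DataFrame(rows))
        min_p = min(min_p, float(full.terms["PR(>F)"].min()))
    return min_p


def planted_dynamics_benchmark(
    seed: int = 7,
    n_per_group: int = 60,
    length_tr: int = 200,
    selection_seed: int = 13,
    eval_seed: int = 99,
    n_iter: int = 10,
) -> dict[str, float]:
    """Discrimination of a dynamics-only group difference: dFC versus static FC.

    Ten regions, five region-disjoint affected pairs. ASD subjects alternate
    those pairs between correlation +0.9 and -0.9 (connected fraction 0.5);
    TD subjects keep them independent. Full-series correlation is therefore
    ~0 in both groups — static FC carries no group signal — while the
    window-state fractions nst/nwk differ sharply. Both representations run
    through the same cascade (univariate filter, lsvm RFE-CV, lsvm
    classifier with random search).
    """
    pairs = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]
    model = StateModel(n_regions=10, base_corr=0.9)
    effect = GroupEffect(affected_pairs=pairs, fraction_asd=0.5, fraction_td=0.0,
                         off_corr_asd=-0.9, off_corr_td=0.0)
    cohort = simulate_cohort(n_per_group, n_per_group, model, effect,
                             length_tr=length_tr, seed=seed)
    y = cohort.labels
    out: dict[str, float] = {}
    for rep in ("dFC", "FC"):
        fm = build_feature_matrix(cohort, rep)
        selected, _ = select_features(fm, y, SelectionConfig(kernel="lsvm", seed=selection_seed))
        res = random_search_cv(selected, y,
                               ClassifierSpec("lsvm", n_iter=n_iter, seed=eval_seed))
        out[f"{rep.lower()}_balanced_accuracy"] = res.balanced_accuracy
    return out
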