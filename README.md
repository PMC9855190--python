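# dynconn

Static and **dynamic functional-connectivity** pipelines for resting-state
fMRI diagnosis studies — feature extraction from region-mean BOLD time
series, two-stage feature selection, cross-validated classifier
benchmarking, and factorial analysis of pipeline-configuration effects. The
package targets autism (ASD vs typically-developing) classification on
cohorts shaped like the ABIDE-I preprocessed release, and ships a synthetic
cohort generator with plantable connectivity dynamics so every stage can be
exercised and validated without any data download.

## The method

Each subject is a `T x A` matrix of region-mean BOLD values (`T` volumes at
repetition time TR, `A` atlas regions; AAL has 116, Talairach–Tournoux 97).
Two connectivity representations are computed per subject:

* **Static FC** — the Pearson correlation `ρ_ij` of every region pair over
  the full series: `A(A-1)/2` features (6670 for AAL, 4656 for TT).
* **Dynamic FC (dFC)** — a Gaussian-tapered sliding window (width
  `w = 21` TR, taper `σ = 3` TR, step `s = 1` TR) yields
  `M = ⌊(L-w)/s⌋ + 1` windowed correlations per pair; these are reduced to
  two occupancy fractions per pair,

  `nst = #{ρ ≥ 0.8}/M` (strong/over-connectivity) and
  `nwk = #{ρ ≤ 0.25}/M` (weak or no connectivity, the under-connectivity
  marker),

  giving `A(A-1)` features (13 340 for AAL). The point of dFC is that two
  pairs with identical full-series correlation can spend very different
  fractions of time in a connected state — a signal static FC cannot see.

Downstream, features pass a univariate ANOVA-F filter, then recursive
feature elimination with 5-fold cross-validation (kernels: linear SVM,
logistic regression, random forest, gradient-boosted trees), and the
selected features feed a six-classifier bank (lsvm, lr, rf, lgbm, MLP, RBF
SVM) tuned by seeded random search optimizing balanced accuracy
(= (sensitivity + specificity)/2). Scores across the configuration grid
(representation × atlas × preprocessing strategy × kernel × classifier) are
analysed with a three-factor type-III ANOVA under sum-to-zero coding,
pruning interactions with p > 0.001 and refitting.

## Worked example

```python
from dynconn import (StateModel, GroupEffect, simulate_cohort,
                     build_feature_matrix, SelectionConfig, select_features,
                     ClassifierSpec, random_search_cv)

# 60+60 subjects; five pairs alternate between +0.9 and -0.9 correlation in
# the ASD group (connected fraction 0.5) but stay independent in TD, so the
# full-series correlation is ~0 in both groups.
pairs = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)]
effect = GroupEffect(affected_pairs=pairs, fraction_asd=0.5, fraction_td=0.0,
                     off_corr_asd=-0.9)
cohort = simulate_cohort(60, 60, StateModel(n_regions=10, base_corr=0.9),
                         effect, length_tr=200, seed=7)

for rep in ("dFC", "FC"):
    fm = build_feature_matrix(cohort, rep)
    selected, sel = select_features(fm, cohort.labels,
                                    SelectionConfig(kernel="lsvm", seed=13))
    res = random_search_cv(selected, cohort.labels,
                           ClassifierSpec("lsvm", n_iter=10, seed=99))
    print(rep, len(sel.selected_names), round(res.balanced_accuracy, 3))
```

prints

```
dFC 5 0.983
FC 10 0.625
```

i.e. the dynamic representation recovers the planted window-level group
difference almost perfectly (balanced accuracy 0.983, having selected
exactly the 5 affected-pair features), while static FC — blind to dynamics
with matched full-series correlation — stays near chance (0.625; the modest
elevation above 0.5 reflects the sequential, non-nested selection protocol).

The same workflow is available from the shell:

```bash
dynconn simulate --out-dir cohort/ --n-asd 30 --n-td 30 --affected-pairs 3
dynconn features cohort/ dfc.csv --representation dfc
dynconn select dfc.csv cohort/phenotype.csv selection.json --kernel lsvm
dynconn run config.yaml      # full grid from a YAML config
```

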