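# Methods

## Connectivity representations

Input is one `T x A` matrix per subject of region-mean BOLD values (rows =
volumes, columns = atlas regions), with a per-subject repetition time TR.
Series length `L = T` and TR are treated strictly per subject; the package
never pads, truncates or resamples across sites.

**Static FC.** The sample Pearson correlation of every region pair over the
full series, upper triangle in row-major order, names `Ri__Rj`. Values are
raw correlations; no Fisher z-transform is applied. A flat (zero-variance)
region yields ρ = 0 with a degenerate flag rather than NaN, so cohort
feature matrices stay finite and aligned.

**Dynamic FC.** A sliding window of width `w = 21` TR advances in steps of
`s = 1` TR; `M = ⌊(L−w)/s⌋ + 1` window positions are used — every fully
contained window, which differs from a pure floor reading by at most one
window and discards no data. Within each window both segments are
mean-centred, multiplied pointwise by a Gaussian taper
`g(t) = exp(−(t−c)²/2σ²)` centred at `c = (w−1)/2` with `σ = 3` TR, and the
Pearson correlation of the tapered segments is taken. Pre-taper centring is
the standard tapered-window estimator: without it the taper redistributes a
window's mean level into apparent covariance. The literal
multiply-then-correlate variant is available via `center=False` and agrees
with a naive slice–taper–correlate loop to ~1e−15 in the test oracle.

Per pair, the `M` windowed correlations reduce to

* `nst` — fraction of windows with ρ ≥ 0.8 (strong/over-connectivity), and
* `nwk` — fraction with ρ ≤ 0.25 (weak/none; under-connectivity),

named `Ri__Rj_st` / `Ri__Rj_wk` (weak listed first). The weak cutoff is
applied to *signed* ρ by default, exactly as the defining formula prints
it; `abs_weak=True` switches to |ρ| for users who read the criterion as a
magnitude. Flat windows count ρ = 0, i.e. toward `nwk` — a flat signal is
maximally "not connected". Both fractions lie in [0, 1]; with cutoffs
0.25 < 0.8 they satisfy `nst + nwk ≤ 1`.

## Synthetic cohorts

The generator emulates exactly what the dFC statistics measure: per-pair
state switching. Each targeted pair (i, j) follows a stationary two-state
Markov chain; while "connected" the pair is drawn bivariate-normal at
correlation `base_corr` (`x_j = ρ e_i + √(1−ρ²) e_j` against independent
unit-variance noises — exact, and exactly zero correlation elsewhere),
while "disconnected" the correlation is `off_corr` (default 0). Dwell times
are geometric with mean `2·seg·f` (connected) and `2·seg·(1−f)`
(disconnected), so the cycle length is `2·seg` regardless of the occupancy
target `f`. Targeted pairs must be region-disjoint; overlapping requests
raise a model error rather than silently attenuating correlations (this
avoids reconciling arbitrary per-pair fractions with a global
positive-definite covariance). Group effects assign affected pairs a
different `f` (and optionally a different off-state correlation) per
diagnosis group; setting e.g. ASD to alternate ±0.9 at f = 0.5 against an
always-independent TD group plants a dynamics-only difference whose
full-series correlation is matched between groups.

**Mean dwell `seg` defaults to 60 TR.** The choice is driven by the
estimator geometry: windows whose centre lies within ~σ TR of a state
boundary are diluted below the 0.8 cutoff, biasing `nst` low by roughly
σ/seg. At seg = 30 the measured grand-mean recovery error over planted
fractions 0.1–0.9 (L = 2000, 20 replicates averaged per fraction) is
0.059–0.064 — `nst` is not a usable estimator of the planted fraction — at
seg = 60 it is 0.034–0.039. Longer dwells would shrink the bias further
but inflate per-realisation occupancy noise (`√(2f(1−f)τ/L)`), degrading
short-series convergence; 60 TR balances the two. Phenotypes are cosmetic:
age ~ Normal(17, 8) truncated at 6 years, sex Bernoulli at the 84.4% male
proportion typical of ASD cohorts, FIQ ~ Normal(108, 15), one site.

What the generator does *not* model: hemodynamic autocorrelation, scanner
noise spectra, site/batch effects, motion artefacts, or whole-connectome
covariance structure (non-target pairs are independent noise). Passing
tests therefore demonstrate that the pipeline machinery is correct and
calibrated — not that real rs-fMRI cohorts will separate at any particular
accuracy.

## Feature selection

Stage 1 keeps the `⌈p·n⌉` features with the largest two-group ANOVA F
(default proportion p = 0.25 — the fraction is inherently a budget choice;
0.25 keeps a few thousand dFC/AAL features, enough for elimination to
matter while bounding cost). Constant features score F = 0; ties break by
original column order. Stage 2 is recursive feature elimination, dropping
2 features per round, ranked by |coefficient| (linear kernels, standardized
in-fold via a pipeline) or impurity importance (tree kernels), scored by
stratified 5-fold balanced accuracy; the candidate count with the best mean
score wins, ties to the smaller count. All kernels share identical fold
assignments (one seed) so their results are comparable. By default the
cascade runs once on the full sample before classification — the literal
sequential protocol — which leaks selection information into later
cross-validation; the planted-null experiments quantify the resulting
optimism (static-FC balanced accuracy ≈ 0.6 rather than 0.5 on
dynamics-only cohorts).

## Classification and metrics

Six classifiers: linear SVM, logistic regression, random forest, LightGBM,
an MLP, and an RBF SVM. Scale-sensitive models (lsvm, lr, nn, svm) are
standardized with train-fold statistics inside every CV fold. Random
search (default 50 draws) samples conventional spaces — C and γ
log-uniform over [1e−3, 1e3] / [1e−4, 1e1], forest size 100–1000 and depth
{None, 3–20}, learning rate log-uniform [1e−3, 0.3] with 15–255 leaves,
hidden layers {32, 64, 128}×{1, 2} with L2 log-uniform [1e−5, 1e−1] — on a
fixed stratified split, optimizing balanced accuracy; the first
configuration attaining the best mean wins, and its per-fold confusion
metrics (accuracy, sensitivity, specificity, balanced accuracy) are
recomputed directly so the recorded scores are exactly reproducible by
refitting the winning parameters. Final-evaluation folds use a seed
distinct from the selection folds (a fresh random split). ASD is the
positive class throughout.

## Factorial analysis

Configuration scores (one row per representation × atlas × strategy ×
kernel × classifier) are modelled by OLS with sum-to-zero factor coding and
type-III sums of squares over the three pre-learning factors
(representation, strategy, atlas), first with all interactions, then
refitted keeping main effects plus only interactions at p ≤ 0.001. Scores
enter untransformed. Constant score tables raise an error (no variance to
decompose); missing design cells raise a rank-deficiency error listing the
empty cells. Region summaries count each selected feature toward both
endpoint regions (ties ranked alphabetically), and the `_wk`/`_st` split is
reported as fractions of the selection.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; a pipeline run derives
per-stage seeds from one master seed via `SeedSequence([master, stage])`,
and stage outputs are cached by config hash, so warm re-runs are
byte-identical to cold ones. The standing benchmark experiments
(`dynconn.experiments`, also driven by `scripts/acceptance.py`) use desk-
scale sizes chosen to keep every quantity's sampling error well inside its
tolerance: fraction recovery with 20 replicates of a 2000-TR pair per
planted fraction; oracle comparison on 100 random pairs; RFE-vs-exhaustive
on 6 features × 40 samples (63 subsets); null calibration on a 100-subject
permuted-label cohort with 8 search draws per classifier; ANOVA
calibration on twenty 384-row null grids (24 replicates per cell, matching
the 4-kernel × 6-classifier grid); planted-effect discrimination on a
120-subject, 10-region cohort.

## Known limitations

* The non-nested default protocol reports optimistic absolute accuracies;
  `dynconn.classify.nested_evaluate` refits the whole selection cascade
  inside each fold for unbiased estimates when comparing to external
  baselines.
* `nst`/`nwk` conflate state occupancy with window-boundary dilution; they
  are calibrated estimators only when state dwell times are long relative
  to the taper width.
* The generator cannot plant overlapping correlated pairs; connectome-wide
  structure requires a full covariance model outside its scope.
* Phenotype covariates (age, sex, FIQ, site) are generated but not used as
  nuisance regressors; no harmonization across sites is attempted.
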