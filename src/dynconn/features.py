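"""Functional-connectivity feature representations.

Two representations of inter-regional coupling are computed from each
subject's region-mean BOLD series:

* **Static FC** — the Pearson correlation rho of every region pair over the
  full series; A regions give A(A-1)/2 features (upper triangle).

* **Dynamic FC (dFC)** — the series is scanned with a Gaussian-tapered
  sliding window (width w TR, taper sigma TR, step s TR). For each pair the
  M = floor((L-w)/s)+1 windowed correlations are reduced to two occupancy
  fractions: nst, the fraction of windows with rho >= 0.8 ("strong"
  over-connectivity), and nwk, the fraction with rho <= 0.25 ("weak"/no
  connectivity, the under-connectivity marker). A regions give A(A-1)
  features, two per pair.

Feature names are canonical: ``<Ri>__<Rj>`` for FC and ``<Ri>__<Rj>_wk`` /
``<Ri>__<Rj>_st`` for dFC, with pairs in row-major upper-triangle order and
the weak metric first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Cohort, RoiTimeSeries, SchemaError


@dataclass(frozen=True)
class GaussianWindowSpec:
    """Sliding-window geometry: width w, Gaussian taper sigma, step s (all in TR)."""

    width_tr: int = 21
    sigma_tr: float = 3.0
    step_tr: int = 1

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise ValueError("window width must be >= 2 TR")
        if self.sigma_tr <= 0 or self.step_tr < 1:
            raise ValueError("sigma must be positive and step >= 1")

    def taper(self) -> np.ndarray:
        """Gaussian taper g(t) = exp(-(t-c)^2 / (2 sigma^2)) centred at c=(w-1)/2."""
        t = np.arange(self.width_tr, dtype=float)
        c = (self.width_tr - 1) / 2.0
        return np.exp(-((t - c) ** 2) / (2.0 * self.sigma_tr**2))


@dataclass(frozen=True)
class ThresholdSpec:
    """Cutoffs defining strong (rho >= strong_min) and weak (rho <= weak_max) windows.

    ``abs_weak`` applies the weak cutoff to |rho| instead of signed rho.
    """

    strong_min: float = 0.8
    weak_max: float = 0.25
    abs_weak: bool = False

    def __post_init__(self) -> None:
        if not (-1.0 <= self.weak_max < self.strong_min <= 1.0):
            raise ValueError("require -1 <= weak_max < strong_min <= 1")


@dataclass
class FeatureMatrix:
    """Subjects x features table with canonical names and provenance tags."""

    values: np.ndarray
    feature_names: list[str]
    representation: str  # "FC" or "dFC"
    subject_ids: list[str]
    atlas_tag: str = "AAL"
    strategy_tag: str = "filt_global"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SchemaError("feature matrix must be 2-D")
        if self.values.shape != (len(self.subject_ids), len(self.feature_names)):
            raise SchemaError("feature matrix shape disagrees with names/subjects")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise SchemaError("feature names must be unique")
        if self.representation not in ("FC", "dFC"):
            raise SchemaError(f"unknown representation {self.representation!r}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            values=self.values[:, idx],
            feature_names=list(names),
            representation=self.representation,
            subject_ids=list(self.subject_ids),
            atlas_tag=self.atlas_tag,
            strategy_tag=self.strategy_tag,
        )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0.0 for a zero-variance (degenerate) input."""
    r, _ = pearson_flagged(x, y)
    return r


def pearson_flagged(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation plus a flag marking degenerate (flat) input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return 0.0, True
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0)), False


def pair_names(region_labels: list[str]) -> list[str]:
    """Upper-triangle (i<j, row-major) pair names ``Ri__Rj``."""
    a = len(region_labels)
    return [
        f"{region_labels[i]}__{region_labels[j]}"
        for i in range(a)
        for j in range(i + 1, a)
    ]


def static_fc(ts: RoiTimeSeries) -> tuple[np.ndarray, list[str]]:
    """Full-series pairwise Pearson correlations, upper triangle, with names."""
    data = ts.data
    sd = data.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    # flat regions: define rho = 0 rather than NaN
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr[sd == 0.0, :] = 0.0
    corr[:, sd == 0.0] = 0.0
    iu = np.triu_indices(ts.n_regions, k=1)
    return np.clip(corr[iu], -1.0, 1.0), pair_names(ts.region_labels)


def num_windows(length_tr: int, win: GaussianWindowSpec) -> int:
    """Number of fully contained window positions M = floor((L-w)/s) + 1."""
    if length_tr < win.width_tr:
        raise ValueError(
            f"series length {length_tr} shorter than window width {win.width_tr}"
        )
    return (length_tr - win.width_tr) // win.step_tr + 1


def _tapered_segments(data: np.ndarray, win: GaussianWindowSpec, center: bool) -> np.ndarray:
    """Stack of tapered window segments, shape (M, w, A).

    Each segment is mean-centred within the window (unless ``center`` is
    False) and multiplied pointwise by the Gaussian taper.
    """
    length = data.shape[0]
    m = num_windows(length, win)
    starts = np.arange(m) * win.step_tr
    idx = starts[:, None] + np.arange(win.width_tr)[None, :]
    seg = data[idx]  # (M, w, A)
    if center:
        seg = seg - seg.mean(axis=1, keepdims=True)
    return seg * win.taper()[None, :, None]


def _segment_corr(seg: np.ndarray) -> np.ndarray:
    """Pearson correlation matrices of tapered segments: (M, w, A) -> (M, A, A)."""
    seg = seg - seg.mean(axis=1, keepdims=True)
    cov = np.einsum("mti,mtj->mij", seg, seg)
    sd = np.sqrt(np.einsum("mii->mi", cov))
    denom = sd[:, :, None] * sd[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom
    corr[denom == 0.0] = 0.0  # flat window => rho 0 (degenerate)
    return np.clip(corr, -1.0, 1.0)


def windowed_correlations(
    x: np.ndarray,
    y: np.ndarray,
    win: GaussianWindowSpec = GaussianWindowSpec(),
    center: bool = True,
) -> np.ndarray:
    """Gaussian-tapered sliding-window Pearson correlations of one pair.

    Each window is mean-centred, tapered, and correlated; the result has
    num_windows entries. ``center=False`` skips the pre-taper centring
    (the literal multiply-then-correlate variant).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    data = np.stack([x, y], axis=1)
    corr = _segment_corr(_tapered_segments(data, win, center))
    return corr[:, 0, 1]


def windowed_correlation_stack(
    ts: RoiTimeSeries, win: GaussianWindowSpec = GaussianWindowSpec(), center: bool = True
) -> np.ndarray:
    """All-pairs windowed correlation matrices, shape (M, A, A)."""
    return _segment_corr(_tapered_segments(ts.data, win, center))


def dfc_pair(rhos: np.ndarray, thr: ThresholdSpec = ThresholdSpec()) -> tuple[float, float]:
    """Reduce one pair's windowed correlations to (nwk, nst) occupancy fractions."""
    rhos = np.asarray(rhos, dtype=float)
    if rhos.size == 0:
        raise ValueError("empty windowed-correlation series")
    nst = float(np.mean(rhos >= thr.strong_min))
    weak_basis = np.abs(rhos) if thr.abs_weak else rhos
    nwk = float(np.mean(weak_basis <= thr.weak_max))
    return nwk, nst


def dfc_features(
    ts: RoiTimeSeries,
    win: GaussianWindowSpec = GaussianWindowSpec(),
    thr: ThresholdSpec = ThresholdSpec(),
    center: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Per-pair (nwk, nst) features, 2 x A(A-1)/2 values with ``_wk``/``_st`` names."""
    if ts.n_timepoints < win.width_tr:
        raise ValueError(
            f"subject {ts.subject_id}: series length {ts.n_timepoints} < window {win.width_tr}"
        )
    corr = windowed_correlation_stack(ts, win, center)
    iu = np.triu_indices(ts.n_regions, k=1)
    rhos = corr[:, iu[0], iu[1]]  # (M, n_pairs)
    nst = (rhos >= thr.strong_min).mean(axis=0)
    weak_basis = np.abs(rhos) if thr.abs_weak else rhos
    nwk = (weak_basis <= thr.weak_max).mean(axis=0)
    values = np.empty(2 * nst.size)
    values[0::2] = nwk
    values[1::2] = nst
    names: list[str] = []
    for base in pair_names(ts.region_labels):
        names.append(f"{base}_wk")
        names.append(f"{base}_st")
    return values, names


def build_feature_matrix(
    cohort: Cohort,
    representation: str = "dFC",
    win: GaussianWindowSpec = GaussianWindowSpec(),
    thr: ThresholdSpec = ThresholdSpec(),
    center: bool = True,
) -> FeatureMatrix:
    """Assemble the cohort feature matrix for one representation.

    Rows follow cohort subject order; all subjects must yield identically
    named features (guaranteed by the shared atlas).
    """
    rows: list[np.ndarray] = []
    names: list[str] | None = None
    for ts in cohort.subjects:
        try:
            if representation == "FC":
                vec, nm = static_fc(ts)
            elif representation == "dFC":
                vec, nm = dfc_features(ts, win, thr, center)
            else:
                raise ValueError(f"unknown representation {representation!r}")
        except ValueError as exc:
            raise ValueError(f"feature extraction failed for subject {ts.subject_id}: {exc}") from exc
        if names is None:
            names = nm
        rows.append(vec)
    assert names is not None
    ref = cohort.subjects[0]
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        representation=representation,
        subject_ids=cohort.subject_ids,
        atlas_tag=ref.atlas_tag,
        strategy_tag=ref.strategy_tag,
    )
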