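"""Synthetic multi-region BOLD cohorts with planted connectivity dynamics.

Each targeted region pair alternates between a *connected* state, where the
two series are drawn jointly at correlation ``base_corr``, and a
*disconnected* state, where they are (by default) independent. State dwell
times are geometric, so the state sequence is a two-state Markov chain whose
stationary connected fraction equals the requested ``pair_state_fraction``.
Non-target pairs are independent noise (correlation ~ 0).

Group differences are planted by giving affected pairs a different connected
fraction (and optionally a different disconnected-state correlation) per
diagnosis group, emulating under-/over-connectivity differences between ASD
and typically developing (TD) brains while leaving everything else matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Cohort, Phenotype, RoiTimeSeries


class ModelError(ValueError):
    """Infeasible joint correlation structure or invalid state model."""


Pair = tuple[int, int]


@dataclass(frozen=True)
class StateModel:
    """State-switching correlation model for one cohort.

    ``pair_state_fraction`` maps region-index pairs (i, j), i < j, to the
    target long-run fraction of time spent in the connected state.
    ``segment_length_tr`` is the mean state dwell time: connected segments
    have mean length 2*segment_length_tr*f and disconnected ones
    2*segment_length_tr*(1-f), keeping the mean state cycle at
    2*segment_length_tr while realising the requested occupancy f.
    ``off_corr`` is the pair correlation while disconnected (default 0).
    """

    n_regions: int
    base_corr: float = 0.9
    pair_state_fraction: Mapping[Pair, float] = field(default_factory=dict)
    segment_length_tr: int = 60
    off_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ModelError("need at least 2 regions")
        if not (abs(self.base_corr) < 1 and abs(self.off_corr) < 1):
            raise ModelError("state correlations must have magnitude < 1")
        if self.segment_length_tr < 1:
            raise ModelError("segment_length_tr must be a positive integer")
        seen: set[int] = set()
        for (i, j), f in self.pair_state_fraction.items():
            if not (0 <= i < j < self.n_regions):
                raise ModelError(f"invalid pair ({i}, {j})")
            if not (0.0 <= f <= 1.0):
                raise ModelError(f"state fraction {f} for pair ({i}, {j}) outside [0, 1]")
            if i in seen or j in seen:
                raise ModelError(
                    "infeasible joint correlation structure: region in more than one "
                    "correlated pair"
                )
            seen.update((i, j))


@dataclass(frozen=True)
class GroupEffect:
    """Group-specific connectivity on a set of pairs (ASD vs TD).

    Affected pairs use ``fraction_asd``/``fraction_td`` as their connected
    fraction depending on the subject's group; ``off_corr_asd``/``off_corr_td``
    optionally set the disconnected-state correlation per group (default 0),
    which allows planting dynamics-only differences with matched full-series
    correlation.
    """

    affected_pairs: Sequence[Pair] = ()
    fraction_asd: float = 0.5
    fraction_td: float = 0.5
    off_corr_asd: float = 0.0
    off_corr_td: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.fraction_asd, self.fraction_td):
            if not (0.0 <= f <= 1.0):
                raise ModelError(f"group state fraction {f} outside [0, 1]")


def _state_sequence(rng: np.random.Generator, length: int, fraction: float, seg: int) -> np.ndarray:
    """Boolean connected-state sequence: stationary Markov chain with occupancy ``fraction``."""
    if fraction <= 0.0:
        return np.zeros(length, dtype=bool)
    if fraction >= 1.0:
        return np.ones(length, dtype=bool)
    mean_on = 2.0 * seg * fraction
    mean_off = 2.0 * seg * (1.0 - fraction)
    p_leave_on = min(1.0, 1.0 / mean_on)
    p_leave_off = min(1.0, 1.0 / mean_off)
    state = rng.random() < fraction
    u = rng.random(length)
    out = np.empty(length, dtype=bool)
    for t in range(length):
        out[t] = state
        if state:
            state = not (u[t] < p_leave_on)
        else:
            state = u[t] < p_leave_off
    return out


def simulate_subject(
    model: StateModel,
    length_tr: int = 200,
    tr_seconds: float = 2.0,
    seed: int | np.random.SeedSequence = 0,
    subject_id: str = "sim",
    region_labels: Sequence[str] | None = None,
    strategy_tag: str = "filt_global",
    atlas_tag: str = "AAL",
) -> RoiTimeSeries:
    """Simulate one subject's T x A BOLD-like matrix under a state model.

    Deterministic given ``seed``. Targeted pairs are built exactly: within a
    connected segment the second region is ``rho * e_i + sqrt(1 - rho^2) * e_j``
    for independent unit-variance noises, giving pair correlation rho while
    leaving all other pairs uncorrelated.
    """
    if length_tr < 2:
        raise ModelError("length_tr must be >= 2")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((length_tr, model.n_regions))
    for (i, j), frac in model.pair_state_fraction.items():
        on = _state_sequence(rng, length_tr, frac, model.segment_length_tr)
        rho = np.where(on, model.base_corr, model.off_corr)
        ei = data[:, i]
        ej = data[:, j]
        data[:, j] = rho * ei + np.sqrt(1.0 - rho**2) * ej
    labels = list(region_labels) if region_labels else [f"R{k + 1}" for k in range(model.n_regions)]
    return RoiTimeSeries(
        subject_id=subject_id,
        data=data,
        tr_seconds=tr_seconds,
        region_labels=labels,
        strategy_tag=strategy_tag,
        atlas_tag=atlas_tag,
    )


#: Demographic distributions used for cosmetic phenotype realism: age is
#: Normal(17, 8) truncated at 6 years, sex is Bernoulli at the ABIDE male
#: proportion, FIQ is Normal(108, 15).
MALE_PROPORTION = 0.844


def simulate_cohort(
    n_asd: int,
    n_td: int,
    model: StateModel,
    effect: GroupEffect | None = None,
    length_tr: int = 200,
    tr_seconds: float = 2.0,
    seed: int = 0,
    strategy_tag: str = "filt_global",
    atlas_tag: str = "AAL",
) -> Cohort:
    """Simulate a labelled two-group cohort; pure function of its arguments.

    Affected pairs (from ``effect``) override the base model's state fraction
    and disconnected-state correlation per group. Subject seeds are spawned
    deterministically from the master seed.
    """
    if n_asd < 1 or n_td < 1:
        raise ModelError("need at least one subject per group")
    effect = effect or GroupEffect()
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_asd + n_td)
    pheno_rng = np.random.default_rng(root.spawn(1)[0])

    def group_model(dx: str) -> StateModel:
        frac = effect.fraction_asd if dx == "ASD" else effect.fraction_td
        off = effect.off_corr_asd if dx == "ASD" else effect.off_corr_td
        fractions = dict(model.pair_state_fraction)
        for pair in effect.affected_pairs:
            fractions[tuple(pair)] = frac
        return StateModel(
            n_regions=model.n_regions,
            base_corr=model.base_corr,
            pair_state_fraction=fractions,
            segment_length_tr=model.segment_length_tr,
            off_corr=off if effect.affected_pairs else model.off_corr,
        )

    models = {dx: group_model(dx) for dx in ("ASD", "TD")}
    subjects: list[RoiTimeSeries] = []
    phenotypes: dict[str, Phenotype] = {}
    dxs = ["ASD"] * n_asd + ["TD"] * n_td
    for k, (dx, sseq) in enumerate(zip(dxs, subject_seeds)):
        sid = f"sim{k + 1:04d}"
        subjects.append(
            simulate_subject(
                models[dx], length_tr, tr_seconds, sseq, sid,
                strategy_tag=strategy_tag, atlas_tag=atlas_tag,
            )
        )
        age = max(6.0, float(pheno_rng.normal(17.0, 8.0)))
        sex = "M" if pheno_rng.random() < MALE_PROPORTION else "F"
        fiq = float(pheno_rng.normal(108.0, 15.0))
        phenotypes[sid] = Phenotype(
            subject_id=sid, dx=dx, site="SIM", age_years=age, sex=sex, fiq=fiq
        )
    return Cohort(subjects=subjects, phenotypes=phenotypes)


def realized_connected_fraction(
    model: StateModel, pair: Pair, length_tr: int, seed: int
) -> float:
    """Realised connected-state occupancy of one pair for one simulated draw.

    Regenerates the exact state sequence the subject simulation would use for
    ``pair`` under ``seed`` (useful for calibration checks).
    """
    rng = np.random.default_rng(seed)
    rng.standard_normal((length_tr, model.n_regions))  # advance past noise draw
    for (i, j), frac in model.pair_state_fraction.items():
        on = _state_sequence(rng, length_tr, frac, model.segment_length_tr)
        if (i, j) == tuple(pair):
            return float(on.mean())
    raise ModelError(f"pair {pair} not in model")
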