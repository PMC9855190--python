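"""Factorial analysis of pipeline-configuration effects, plus feature summaries.

The configuration score table (one balanced-accuracy entry per pipeline
cell) is analysed with a three-factor type-III ANOVA over feature
representation (feat), preprocessing strategy (strat) and atlas (atls),
using sum-to-zero (effects) coding. The full-interaction model is fitted
first; interactions with p above the pruning threshold are then dropped and
the model refitted.

Also here: summaries of the selected-feature lists — per-region selection
frequencies (each feature counts toward both endpoint regions) and the split
between weak-connectivity (``_wk``) and strong-connectivity (``_st``)
features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm


@dataclass
class AnovaTable:
    """Type-III ANOVA terms plus the residual row."""

    terms: pd.DataFrame  # index: term names; columns: sum_sq, df, F, PR(>F)
    residual_ss: float
    residual_df: float
    ss_type: str = "III"

    @classmethod
    def from_statsmodels(cls, table: pd.DataFrame) -> "AnovaTable":
        resid = table.loc["Residual"]
        terms = table.drop(index="Residual")
        if "Intercept" in terms.index:
            terms = terms.drop(index="Intercept")
        return cls(terms=terms, residual_ss=float(resid["sum_sq"]), residual_df=float(resid["df"]))


def _term(factor: str) -> str:
    return f"C({factor}, Sum)"


def _fit_anova(table: pd.DataFrame, terms: list[str]) -> AnovaTable:
    scores = table["score"].to_numpy()
    if scores.size and scores.min() == scores.max():
        raise ValueError("scores are constant; no variance to decompose")
    formula = "score ~ " + " + ".join(terms)
    model = smf.ols(formula, data=table).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom; cannot test effects")
    return AnovaTable.from_statsmodels(anova_lm(model, typ=3))


def factorial_anova(
    table: pd.DataFrame,
    factors: list[str] = ["feat", "strat", "atls"],
    prune_alpha: float = 0.001,
) -> tuple[AnovaTable, AnovaTable]:
    """Full-interaction type-III ANOVA, then refit keeping only significant interactions.

    Returns (full, pruned). The pruned model retains every main effect and
    exactly those interactions whose full-model p-value is <= prune_alpha.
    """
    if "score" not in table.columns:
        raise ValueError("table must have a 'score' column")
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"missing factor column {f!r}")
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
    _check_full_design(table, factors)
    mains = [_term(f) for f in factors]
    interactions = [
        ":".join(_term(f) for f in combo)
        for r in range(2, len(factors) + 1)
        for combo in combinations(factors, r)
    ]
    full = _fit_anova(table, mains + interactions)
    pvals = full.terms["PR(>F)"]
    keep = [t for t in interactions if t in pvals.index and pvals[t] <= prune_alpha]
    pruned = _fit_anova(table, mains + keep)
    return full, pruned


def three_way_anova(
    table: pd.DataFrame, prune_alpha: float = 0.001
) -> tuple[AnovaTable, AnovaTable]:
    """The configuration-grid analysis: feat x strat x atls with pruning."""
    return factorial_anova(table, ["feat", "strat", "atls"], prune_alpha)


def _check_full_design(table: pd.DataFrame, factors: list[str]) -> None:
    counts = table.groupby(factors, observed=True).size()
    full = int(np.prod([table[f].nunique() for f in factors]))
    if len(counts) < full:
        observed = set(counts.index if len(factors) > 1 else [(i,) for i in counts.index])
        from itertools import product

        levels = [sorted(table[f].unique()) for f in factors]
        empty = [cell for cell in product(*levels) if cell not in observed]
        raise ValueError(f"rank-deficient design; empty cells: {empty}")


def factor_effect_summary(table: pd.DataFrame, factor: str) -> dict:
    """Per-level mean score and signed pairwise mean differences."""
    if factor not in table.columns:
        raise ValueError(f"missing factor column {factor!r}")
    means = table.groupby(factor, observed=True)["score"].mean().sort_index()
    diffs = {
        f"{a}-{b}": float(means[a] - means[b])
        for a, b in combinations(means.index, 2)
    }
    return {"means": means.to_dict(), "differences": diffs}


_FEATURE_NAME = re.compile(r"^(?P<a>.+?)__(?P<b>.+?)(?P<suffix>_wk|_st)?$")


def parse_feature_name(name: str) -> tuple[str, str, str | None]:
    """Split ``Ri__Rj[_wk|_st]`` into endpoints and optional metric suffix."""
    m = _FEATURE_NAME.match(name)
    if not m or not m.group("a") or not m.group("b"):
        raise ValueError(f"malformed feature name {name!r}")
    return m.group("a"), m.group("b"), m.group("suffix")


def region_frequency(selected_names: list[str]) -> pd.DataFrame:
    """Count how often each region appears among selected features.

    Each feature contributes one count to both endpoint regions. Rows are
    ranked by descending count, ties broken alphabetically.
    """
    counts: dict[str, int] = {}
    for name in selected_names:
        a, b, _ = parse_feature_name(name)
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["region", "count"])


def wk_st_proportions(selected_names: list[str]) -> dict[str, float]:
    """Fractions of weak- vs strong-connectivity features in a dFC selection."""
    if not selected_names:
        raise ValueError("empty selection")
    n_wk = n_st = 0
    for name in selected_names:
        _, _, suffix = parse_feature_name(name)
        if suffix == "_wk":
            n_wk += 1
        elif suffix == "_st":
            n_st += 1
        else:
            raise ValueError(
                f"feature {name!r} has no _wk/_st suffix; not a dFC selection"
            )
    total = n_wk + n_st
    return {"wk_fraction": n_wk / total, "st_fraction": n_st / total}
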