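import itertools

import numpy as np
import pandas as pd
import pytest

from dynconn import (
    factor_effect_summary,
    factorial_anova,
    region_frequency,
    three_way_anova,
    wk_st_proportions,
)
from dynconn.factorial import parse_feature_name


def _null_grid(rng, shift_feat=0.0, n_rep=6, noise=0.05):
    rows = []
    for feat, strat, atls in itertools.product(
        ["FC", "dFC"],
        ["filt_global", "filt_noglobal", "nofilt_global", "nofilt_noglobal"],
        ["AAL", "TT"],
    ):
        for _ in range(n_rep):
            score = 0.75 + rng.normal(0, noise)
            if feat == "dFC":
                score += shift_feat
            rows.append(dict(feat=feat, strat=strat, atls=atls, score=score))
    return pd.DataFrame(rows)


def _oneway_f(groups):
    """Closed-form one-way ANOVA F for a list of 1-D arrays."""
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))


class TestThreeWayAnova:
    def test_planted_main_effect_is_the_only_significant_term(self):
        # 24 replicates per cell, matching the 4-kernel x 6-classifier grid
        detections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = _null_grid(rng, shift_feat=0.05, n_rep=24)
            full, pruned = three_way_anova(table)
            p = pruned.terms["PR(>F)"]
            feat_term = "C(feat, Sum)"
            others = [t for t in pruned.terms.index if t != feat_term]
            if p[feat_term] < 0.001 and all(p[t] >= 0.001 for t in others):
                detections += 1
        assert detections >= 18

    def test_constant_scores_are_degenerate(self):
        table = _null_grid(np.random.default_rng(0), noise=0.0)
        table["score"] = 0.8
        with pytest.raises(ValueError, match="constant"):
            three_way_anova(table)

    def test_pruned_model_keeps_mains_plus_significant_interactions(self):
        rng = np.random.default_rng(42)
        table = _null_grid(rng, shift_feat=0.08)
        full, pruned = three_way_anova(table)
        mains = {"C(feat, Sum)", "C(strat, Sum)", "C(atls, Sum)"}
        interactions = set(full.terms.index) - mains
        expected = mains | {
            t for t in interactions if full.terms.loc[t, "PR(>F)"] <= 0.001
        }
        assert set(pruned.terms.index) == expected

    def test_type_iii_invariant_to_row_and_level_permutation(self):
        rng = np.random.default_rng(1)
        table = _null_grid(rng, shift_feat=0.05)
        full, _ = three_way_anova(table)
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        full2, _ = three_way_anova(shuffled)
        pd.testing.assert_frame_equal(full.terms, full2.terms)

    def test_balanced_main_effect_ss_matches_direct_decomposition(self):
        # for a balanced design, type-III main-effect SS equals the classical
        # between-level sum of squares
        rng = np.random.default_rng(2)
        table = _null_grid(rng, shift_feat=0.1)
        full, _ = three_way_anova(table)
        grand = table["score"].mean()
        ss_feat = sum(
            len(g) * (g["score"].mean() - grand) ** 2
            for _, g in table.groupby("feat")
        )
        assert full.terms.loc["C(feat, Sum)", "sum_sq"] == pytest.approx(ss_feat, rel=1e-8)

    def test_one_factor_reduction_equals_classical_oneway_f(self):
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            a = rng.normal(0.7, 0.05, 12)
            b = rng.normal(0.75, 0.05, 12)
            table = pd.DataFrame(
                {"feat": ["FC"] * 12 + ["dFC"] * 12, "score": np.concatenate([a, b])}
            )
            full, _ = factorial_anova(table, ["feat"])
            assert full.terms.loc["C(feat, Sum)", "F"] == pytest.approx(
                _oneway_f([a, b]), abs=1e-8
            )

    def test_missing_cell_is_rank_deficiency_error(self):
        table = _null_grid(np.random.default_rng(4))
        table = table[~((table.feat == "FC") & (table.atls == "TT"))]
        with pytest.raises(ValueError, match="empty cells"):
            three_way_anova(table)

    def test_single_level_factor_rejected(self):
        table = _null_grid(np.random.default_rng(5))
        table = table[table.atls == "AAL"]
        with pytest.raises(ValueError):
            three_way_anova(table)


class TestFactorSummary:
    def test_planted_shift_recovered_in_means(self):
        rng = np.random.default_rng(6)
        table = _null_grid(rng, shift_feat=0.05, n_rep=40, noise=0.02)
        s = factor_effect_summary(table, "feat")
        assert s["differences"]["FC-dFC"] == pytest.approx(-0.05, abs=0.01)

    def test_single_level_factor_gives_one_mean_no_differences(self):
        table = pd.DataFrame({"feat": ["FC", "FC"], "score": [0.7, 0.8]})
        s = factor_effect_summary(table, "feat")
        assert s["means"] == {"FC": pytest.approx(0.75)}
        assert s["differences"] == {}

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(7)
        table = _null_grid(rng)
        s1 = factor_effect_summary(table, "strat")
        s2 = factor_effect_summary(table.sample(frac=1.0, random_state=3), "strat")
        assert s1 == s2


class TestFeatureSummaries:
    def test_region_counts_both_endpoints(self):
        freq = region_frequency(["A__B_wk", "A__C_st"])
        assert freq.values.tolist() == [["A", 2], ["B", 1], ["C", 1]]

    def test_empty_list_gives_empty_table(self):
        assert len(region_frequency([])) == 0

    def test_region_appearing_n_times_counted_n(self):
        names = [f"X__Y{i}_wk" for i in range(24)]
        freq = region_frequency(names)
        assert freq.iloc[0].tolist() == ["X", 24]

    def test_ties_broken_alphabetically(self):
        freq = region_frequency(["B__C_wk", "A__D_st"])
        assert freq["region"].tolist() == ["A", "B", "C", "D"]

    def test_underscored_region_names_parse(self):
        a, b, suf = parse_feature_name("Precentral_L__Rolandic_Oper_R_wk")
        assert (a, b, suf) == ("Precentral_L", "Rolandic_Oper_R", "_wk")
        a, b, suf = parse_feature_name("Frontal_Sup_L__Temporal_Sup_L")
        assert (a, b, suf) == ("Frontal_Sup_L", "Temporal_Sup_L", None)

    def test_malformed_name_raises_with_name(self):
        with pytest.raises(ValueError, match="nodoubleunderscore"):
            region_frequency(["nodoubleunderscore"])

    def test_wk_st_fractions(self):
        names = [f"A__B{i}_wk" for i in range(9)] + ["A__C_st"]
        p = wk_st_proportions(names)
        assert p == {"wk_fraction": 0.9, "st_fraction": 0.1}
        assert wk_st_proportions(["A__B_st"]) == {"wk_fraction": 0.0, "st_fraction": 1.0}

    def test_fc_style_names_rejected(self):
        with pytest.raises(ValueError):
            wk_st_proportions(["A__B", "A__C"])
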