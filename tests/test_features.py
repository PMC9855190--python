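import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynconn import (
    FeatureMatrix,
    GaussianWindowSpec,
    RoiTimeSeries,
    StateModel,
    ThresholdSpec,
    build_feature_matrix,
    dfc_features,
    dfc_pair,
    num_windows,
    pearson,
    simulate_subject,
    static_fc,
    windowed_correlations,
)
from dynconn.features import pair_names, pearson_flagged


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert pearson(x, x) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_closed_form_value(self):
        # cov = 3, sx = sqrt(2), sy = sqrt(42/9) for n=3 sample moments
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    def test_degenerate_series_flagged_zero(self):
        r, degenerate = pearson_flagged([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r == 0.0 and degenerate

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 30))
        r = pearson(x, y)
        assert r == pytest.approx(pearson(y, x))
        assert -1.0 <= r <= 1.0


class TestStaticFC:
    @pytest.mark.parametrize("n_regions,n_features", [(116, 6670), (97, 4656)])
    def test_atlas_feature_counts(self, n_regions, n_features):
        rng = np.random.default_rng(0)
        ts = RoiTimeSeries("s", rng.standard_normal((30, n_regions)), 2.0,
                           [f"R{i}" for i in range(n_regions)])
        vec, names = static_fc(ts)
        assert vec.shape == (n_features,)
        assert len(names) == n_features

    def test_duplicated_region_gives_unit_correlation(self):
        data = np.column_stack([np.arange(10.0), np.arange(10.0)])
        ts = RoiTimeSeries("s", data, 2.0, ["a", "b"])
        vec, names = static_fc(ts)
        assert names == ["a__b"]
        np.testing.assert_allclose(vec, [1.0])

    def test_matches_pairwise_pearson(self):
        rng = np.random.default_rng(1)
        ts = RoiTimeSeries("s", rng.standard_normal((40, 5)), 2.0,
                           [f"R{i}" for i in range(5)])
        vec, names = static_fc(ts)
        k = 0
        for i in range(5):
            for j in range(i + 1, 5):
                assert vec[k] == pytest.approx(pearson(ts.data[:, i], ts.data[:, j]))
                assert names[k] == f"R{i}__R{j}"
                k += 1


class TestWindows:
    def test_single_full_window(self):
        assert num_windows(21, GaussianWindowSpec(21, 3, 1)) == 1

    def test_window_count_matches_enumeration(self):
        win = GaussianWindowSpec(21, 3, 1)
        # every start offset 0..179 leaves a fully contained window
        assert num_windows(200, win) == 180
        win3 = GaussianWindowSpec(21, 3, 3)
        assert num_windows(200, win3) == len(range(0, 200 - 21 + 1, 3))

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            num_windows(20, GaussianWindowSpec(21, 3, 1))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GaussianWindowSpec(1, 3, 1)
        with pytest.raises(ValueError):
            GaussianWindowSpec(21, -1, 1)


def _naive_windowed(x, y, win, center=True):
    """Independent oracle: slice, center, taper, then plain Pearson."""
    g = np.exp(-((np.arange(win.width_tr) - (win.width_tr - 1) / 2) ** 2)
               / (2 * win.sigma_tr**2))
    out = []
    for start in range(0, len(x) - win.width_tr + 1, win.step_tr):
        xs = x[start:start + win.width_tr]
        ys = y[start:start + win.width_tr]
        if center:
            xs = xs - xs.mean()
            ys = ys - ys.mean()
        out.append(pearson(xs * g, ys * g))
    return np.array(out)


class TestWindowedCorrelations:
    def test_identical_series_give_unit_windows(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        rhos = windowed_correlations(x, x)
        np.testing.assert_allclose(rhos, 1.0, atol=1e-12)

    def test_negated_series_give_minus_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        np.testing.assert_allclose(windowed_correlations(x, -x), -1.0, atol=1e-12)

    @pytest.mark.parametrize("center", [True, False], ids=["centered", "literal"])
    def test_agrees_with_naive_loop(self, center):
        rng = np.random.default_rng(4)
        win = GaussianWindowSpec(21, 3, 2)
        for _ in range(5):
            x, y = rng.standard_normal((2, 120)) + rng.uniform(-3, 3, size=(2, 1))
            fast = windowed_correlations(x, y, win, center=center)
            slow = _naive_windowed(x, y, win, center=center)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_planted_half_fraction_recovered(self):
        # average over a few fixed seeds; per-draw occupancy noise ~0.05
        nsts = []
        for seed in range(10):
            m = StateModel(2, 0.95, {(0, 1): 0.5})
            ts = simulate_subject(m, 2000, seed=seed)
            rhos = windowed_correlations(ts.data[:, 0], ts.data[:, 1])
            nsts.append(np.mean(rhos >= 0.8))
        assert abs(np.mean(nsts) - 0.5) <= 0.07


class TestDfc:
    def test_direct_count_example(self):
        nwk, nst = dfc_pair(np.array([0.9, 0.1, 0.3, 0.85]))
        assert (nwk, nst) == (0.25, 0.5)

    @pytest.mark.parametrize(
        "rhos,expected",
        [([0.9, 0.9], (0.0, 1.0)), ([0.5, 0.5], (0.0, 0.0))],
        ids=["all-strong", "mid-band"],
    )
    def test_boundary_examples(self, rhos, expected):
        assert dfc_pair(np.array(rhos)) == expected

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            dfc_pair(np.array([]))

    def test_abs_weak_counts_negative_windows(self):
        rhos = np.array([-0.9, 0.1, 0.9])
        signed = dfc_pair(rhos, ThresholdSpec())
        magnitude = dfc_pair(rhos, ThresholdSpec(abs_weak=True))
        assert signed[0] == pytest.approx(2 / 3)
        assert magnitude[0] == pytest.approx(1 / 3)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        rhos = rng.uniform(-1, 1, 200)
        nst = [dfc_pair(rhos, ThresholdSpec(strong_min=s))[1] for s in (0.5, 0.7, 0.9)]
        assert nst[0] >= nst[1] >= nst[2]
        nwk = [dfc_pair(rhos, ThresholdSpec(weak_max=w))[0] for w in (0.0, 0.25, 0.4)]
        assert nwk[0] <= nwk[1] <= nwk[2]

    def test_aal_dfc_feature_count(self):
        rng = np.random.default_rng(6)
        ts = RoiTimeSeries("s", rng.standard_normal((40, 116)), 2.0,
                           [f"R{i}" for i in range(116)])
        vec, names = dfc_features(ts)
        assert vec.shape == (13340,)

    def test_tt_dfc_feature_count_doubles_fc(self):
        rng = np.random.default_rng(6)
        ts = RoiTimeSeries("s", rng.standard_normal((40, 97)), 2.0,
                           [f"R{i}" for i in range(97)])
        vec, names = dfc_features(ts)
        assert vec.shape == (2 * 4656,)

    def test_canonical_feature_naming(self):
        rng = np.random.default_rng(7)
        labels = ["Precentral_L", "Rolandic_Oper_R", "Fusiform_L"]
        ts = RoiTimeSeries("s", rng.standard_normal((30, 3)), 2.0, labels)
        _, names = dfc_features(ts)
        assert names[0] == "Precentral_L__Rolandic_Oper_R_wk"
        assert names[1] == "Precentral_L__Rolandic_Oper_R_st"
        assert names[2] == "Precentral_L__Fusiform_L_wk"

    def test_short_series_error_names_subject(self):
        rng = np.random.default_rng(8)
        ts = RoiTimeSeries("shorty", rng.standard_normal((10, 3)), 2.0, ["a", "b", "c"])
        with pytest.raises(ValueError, match="shorty"):
            dfc_features(ts)


class TestFeatureMatrix:
    def test_fc_shape_and_bounds(self, small_cohort):
        fm = build_feature_matrix(small_cohort, "FC")
        assert fm.values.shape == (16, 15)
        assert np.all(fm.values >= -1) and np.all(fm.values <= 1)

    def test_dfc_shape_and_bounds(self, small_cohort):
        fm = build_feature_matrix(small_cohort, "dFC")
        assert fm.values.shape == (16, 30)
        assert np.all(fm.values >= 0) and np.all(fm.values <= 1)
        assert all(n.endswith(("_wk", "_st")) for n in fm.feature_names)

    def test_rows_follow_cohort_order(self, small_cohort):
        fm = build_feature_matrix(small_cohort, "FC")
        assert fm.subject_ids == small_cohort.subject_ids

    def test_duplicate_names_rejected(self):
        with pytest.raises(Exception):
            FeatureMatrix(np.zeros((1, 2)), ["a", "a"], "FC", ["s1"])
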