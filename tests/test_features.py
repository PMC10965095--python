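"""Window segment areas, spectrum matrices, and the train-only normalizer."""

import numpy as np
import pandas as pd
import pytest

from swvquant.exceptions import (
    DegenerateFeatureError,
    RangeError,
    SchemaError,
)
from swvquant.features import (
    WindowSpec,
    analytic_features,
    apply_normalizer,
    fit_normalizer,
    logical_features,
    logical_matrix,
    spectrum_matrix,
)
from swvquant.io import Voltammogram
from swvquant.pcr import fit_pca
from swvquant.simulate import SwvSimConfig, simulate_sample_set

WINDOW = WindowSpec()


class TestWindowSpec:
    def test_defaults_give_51_points_17_segments(self):
        assert WINDOW.grid().size == 51
        assert WINDOW.boundaries().size == 18

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            WindowSpec(n_points=20, n_segments=17)


class TestLogicalFeatures:
    def test_constant_current_gives_equal_tiling_areas(self, flat_sweep):
        areas = logical_features(flat_sweep, WINDOW)
        assert areas.size == 17
        np.testing.assert_allclose(areas, 3.0 * 0.1 / 17, rtol=1e-12)
        assert areas.sum() == pytest.approx(3.0 * 0.1, rel=1e-12)

    def test_linear_ramp_total_is_closed_form_integral(self, ramp_sweep):
        # integral of E dE over 1.55..1.65 = (1.65^2 - 1.55^2)/2 = 0.16
        areas = logical_features(ramp_sweep, WINDOW)
        assert areas.sum() == pytest.approx(0.16, abs=1e-12)

    def test_window_outside_sweep_is_range_error(self):
        v = Voltammogram(potentials=[0.0, 1.0], currents=[0.0, 1.0])
        with pytest.raises(RangeError):
            logical_features(v, WINDOW)

    def test_areas_sum_to_full_window_trapezoid_for_random_traces(self, rng):
        pot = np.linspace(1.5, 1.7, 101)
        for _ in range(20):
            v = Voltammogram(potentials=pot, currents=rng.normal(size=pot.size))
            areas = logical_features(v, WINDOW)
            resampled = np.interp(WINDOW.grid(), pot, v.currents)
            whole = np.trapezoid(resampled, WINDOW.grid())
            assert areas.sum() == pytest.approx(whole, abs=1e-10)

    def test_grid_resolution_invariance_on_piecewise_linear_trace(self):
        # a trace linear between the resampled points gives identical areas
        # whether measured coarsely or finely
        coarse = Voltammogram(
            potentials=np.linspace(1.5, 1.7, 11),
            currents=2.0 + 3.0 * np.linspace(1.5, 1.7, 11),
        )
        fine = Voltammogram(
            potentials=np.linspace(1.5, 1.7, 2001),
            currents=2.0 + 3.0 * np.linspace(1.5, 1.7, 2001),
        )
        np.testing.assert_allclose(
            logical_features(coarse, WINDOW), logical_features(fine, WINDOW),
            rtol=1e-12,
        )


class TestMatrices:
    def test_matrix_shapes_and_keys(self):
        data = simulate_sample_set([40, 60], 3, SwvSimConfig(seed=1, grid_step=0.01))
        areas = logical_matrix(data)
        assert areas.shape == (6, 17)
        assert areas.index.names == ["sample_id", "replicate_index"]
        grid = np.linspace(-2.0, 2.0, 101)
        spectra = spectrum_matrix(data, grid)
        assert spectra.shape == (6, 101)


class TestNormalizer:
    def test_two_point_column_zscores_to_plus_minus_one(self):
        train = pd.DataFrame({"a": [1.0, 3.0]})
        norm = fit_normalizer(train)
        out = apply_normalizer(norm, train)
        np.testing.assert_allclose(out["a"], [-1.0, 1.0])

    def test_training_set_maps_to_zero_mean_unit_sd(self, rng):
        train = pd.DataFrame(rng.normal(size=(20, 5)), columns=list("abcde"))
        out = apply_normalizer(fit_normalizer(train), train)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=0), 1.0, rtol=1e-12)

    def test_test_rows_use_training_statistics_verbatim(self, rng):
        train = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        norm = fit_normalizer(train)
        test = pd.DataFrame(
            {"a": [train["a"].mean()], "b": [train["b"].mean()]}
        )
        out = apply_normalizer(norm, test)
        np.testing.assert_allclose(out.iloc[0], 0.0, atol=1e-12)

    def test_zero_variance_column_raises_naming_it(self):
        train = pd.DataFrame({"good": [1.0, 2.0], "dead": [5.0, 5.0]})
        with pytest.raises(DegenerateFeatureError, match="dead"):
            fit_normalizer(train)

    def test_drop_policy_removes_dead_columns(self):
        train = pd.DataFrame({"good": [1.0, 2.0], "dead": [5.0, 5.0]})
        norm = fit_normalizer(train, degenerate="drop")
        assert norm.columns == ("good",)
        out = apply_normalizer(norm, train)
        assert list(out.columns) == ["good"]

    def test_center_mode_preserves_physical_scale(self):
        train = pd.DataFrame({"a": [1.0, 3.0], "b": [10.0, 30.0]})
        out = apply_normalizer(fit_normalizer(train, mode="center"), train)
        np.testing.assert_allclose(out["a"], [-1.0, 1.0])
        np.testing.assert_allclose(out["b"], [-10.0, 10.0])

    def test_minmax_maps_training_range_to_unit_interval(self):
        train = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        out = apply_normalizer(fit_normalizer(train, mode="minmax"), train)
        np.testing.assert_allclose(out["a"], [0.0, 0.5, 1.0])

    def test_schema_mismatch_raises(self):
        norm = fit_normalizer(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(SchemaError):
            apply_normalizer(norm, pd.DataFrame({"b": [1.0]}))


class TestAnalyticFeatures:
    def test_rank_one_scores_are_signed_distances(self):
        x = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]}
        )
        pca = fit_pca(x)
        scores = analytic_features(x, pca, 1)
        centered_norm = np.linalg.norm(
            x.to_numpy() - x.to_numpy().mean(0), axis=1
        )
        np.testing.assert_allclose(np.abs(scores["PC1"]), centered_norm,
                                   atol=1e-12)

    def test_full_rank_scores_preserve_pairwise_distances(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 5)))
        pca = fit_pca(x)
        scores = analytic_features(x, pca, pca.n_components).to_numpy()
        centered = x.to_numpy() - x.to_numpy().mean(0)
        # brute-force distance matrices
        d_orig = np.linalg.norm(centered[:, None] - centered[None], axis=2)
        d_score = np.linalg.norm(scores[:, None] - scores[None], axis=2)
        np.testing.assert_allclose(d_score, d_orig, atol=1e-10)

    def test_duplicated_rows_get_identical_scores(self, rng):
        base = rng.normal(size=(4, 3))
        x = pd.DataFrame(np.vstack([base, base[1]]))
        pca = fit_pca(x)
        scores = analytic_features(x, pca, 2).to_numpy()
        np.testing.assert_allclose(scores[1], scores[4], atol=1e-12)

    def test_k_out_of_range_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 3)))
        pca = fit_pca(x)
        with pytest.raises(ValueError):
            analytic_features(x, pca, 0)
        with pytest.raises(ValueError):
            analytic_features(x, pca, pca.n_components + 1)
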