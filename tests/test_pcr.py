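"""PCA/PCR core: axes, regression, component search, persistence."""

import numpy as np
import pandas as pd
import pytest

from swvquant.exceptions import InsufficientDataError
from swvquant.features import fit_normalizer
from swvquant.pcr import (
    fit_pca,
    fit_pcr,
    grid_search_components,
    load_model,
    predict,
    save_model,
)
from swvquant.simulate import PANEL_CONCENTRATIONS, SwvSimConfig, noiseless, simulate_sample_set


class TestFitPca:
    def test_perfectly_correlated_2d(self):
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        pca = fit_pca(x)
        assert pca.n_components == 1
        np.testing.assert_allclose(np.abs(pca.components[0]),
                                   [1 / np.sqrt(2)] * 2, atol=1e-12)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_four_points_split_variance_evenly(self):
        x = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        pca = fit_pca(x)
        np.testing.assert_allclose(pca.explained_variance_ratio, [0.5, 0.5],
                                   atol=1e-12)

    def test_full_rank_reconstruction(self, rng):
        x = rng.normal(size=(5, 4))
        pca = fit_pca(x)
        centered = x - x.mean(axis=0)
        recon = pca.transform(x) @ pca.components
        np.testing.assert_allclose(recon, centered, atol=1e-10)

    def test_reconstruction_error_non_increasing_in_k(self, rng):
        x = rng.normal(size=(10, 6))
        pca = fit_pca(x)
        centered = x - x.mean(axis=0)
        errs = []
        for k in range(1, pca.n_components + 1):
            recon = pca.transform(x)[:, :k] @ pca.components[:k]
            errs.append(np.linalg.norm(centered - recon))
        assert all(a >= b - 1e-10 for a, b in zip(errs, errs[1:]))

    def test_sign_convention_largest_loading_positive(self, rng):
        pca = fit_pca(rng.normal(size=(9, 5)))
        for axis in pca.components:
            assert axis[np.argmax(np.abs(axis))] > 0

    def test_matches_sklearn_axes(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        x = rng.normal(size=(12, 6))
        ours = fit_pca(x)
        ref = sklearn_pca(n_components=6).fit(x)
        np.testing.assert_allclose(np.abs(ours.components),
                                   np.abs(ref.components_), atol=1e-8)
        np.testing.assert_allclose(ours.explained_variance_ratio,
                                   ref.explained_variance_ratio_, atol=1e-10)

    def test_needs_two_rows(self):
        with pytest.raises(InsufficientDataError):
            fit_pca(np.ones((1, 3)))


class TestFitPcr:
    def test_exact_fit_when_y_is_first_score(self, rng):
        x = rng.normal(size=(8, 4))
        pca = fit_pca(x)
        y = pca.transform(x)[:, 0]
        model, fitted = fit_pcr(x, y, 1)
        np.testing.assert_allclose(fitted, y, atol=1e-10)

    def test_constant_y_gives_intercept_only(self, rng):
        x = rng.normal(size=(6, 3))
        model, fitted = fit_pcr(x, np.full(6, 42.0), 2)
        assert model.coefficients[0] == pytest.approx(42.0)
        np.testing.assert_allclose(model.coefficients[1:], 0.0, atol=1e-10)

    def test_k_equal_rank_matches_multiple_least_squares(self, rng):
        # brute-force OLS oracle on a 6x3 instance
        x = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        model, fitted = fit_pcr(x, y, 3)
        design = np.column_stack([np.ones(6), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(fitted, design @ beta, atol=1e-8)

    def test_training_rmse_non_increasing_in_k(self, rng):
        x = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        rmses = []
        for k in range(1, 6):
            _, fitted = fit_pcr(x, y, k)
            rmses.append(np.sqrt(np.mean((fitted - y) ** 2)))
        assert all(a >= b - 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_k_beyond_rank_rejected(self, rng):
        x = rng.normal(size=(8, 2))
        with pytest.raises(InsufficientDataError):
            fit_pcr(x, rng.normal(size=8), 5)


class TestPredict:
    def test_training_rows_reproduce_training_predictions(self, rng):
        x = rng.normal(size=(7, 4))
        y = rng.normal(size=7)
        model, fitted = fit_pcr(x, y, 2)
        np.testing.assert_allclose(predict(model, x), fitted, atol=1e-12)

    def test_column_means_map_to_intercept(self, rng):
        x = rng.normal(size=(9, 3))
        model, _ = fit_pcr(x, rng.normal(size=9), 2)
        pred = predict(model, x.mean(axis=0, keepdims=True))
        assert pred[0] == pytest.approx(model.coefficients[0], abs=1e-10)

    def test_model_is_immutable_under_predict(self, rng):
        x = rng.normal(size=(7, 4))
        model, _ = fit_pcr(x, rng.normal(size=7), 2)
        before = (model.coefficients.copy(), model.pca.components.copy(),
                  model.pca.mean.copy())
        predict(model, rng.normal(size=(3, 4)))
        np.testing.assert_array_equal(model.coefficients, before[0])
        np.testing.assert_array_equal(model.pca.components, before[1])
        np.testing.assert_array_equal(model.pca.mean, before[2])

    def test_noiseless_simulated_panel_recovered_exactly(self):
        # the full chain on clean, linear-response spectra reproduces truth
        data = simulate_sample_set(
            PANEL_CONCENTRATIONS, 1, noiseless(SwvSimConfig(seed=2))
        )
        from swvquant.features import logical_matrix

        areas = logical_matrix(data)
        y = np.array([s.published_content for s in data], dtype=float)
        norm = fit_normalizer(areas, degenerate="drop")
        model, _ = fit_pcr(areas, y, 1, normalizer=norm)
        np.testing.assert_allclose(predict(model, areas), y, atol=1e-6)


def _grouped_frame(rng, n_samples=6, reps=2, p=4):
    rows = rng.normal(size=(n_samples * reps, p))
    idx = pd.MultiIndex.from_tuples(
        [(f"S{i}", r + 1) for i in range(n_samples) for r in range(reps)],
        names=["sample_id", "replicate_index"],
    )
    return pd.DataFrame(rows, index=idx)


class TestGridSearch:
    def test_selects_one_component_when_y_loads_on_first_axis_only(self, rng):
        # the dominant-variance direction carries y (up to measurement noise);
        # the remaining directions are pure noise, so extra components can
        # only overfit and held-out error picks k = 1
        n = 8
        t = np.repeat(rng.normal(scale=5.0, size=n), 2)
        noise = rng.normal(scale=0.5, size=(2 * n, 3))
        x = np.column_stack([t + noise[:, 0], noise[:, 1], noise[:, 2]])
        idx = pd.MultiIndex.from_tuples(
            [(f"S{i}", r) for i in range(n) for r in (1, 2)],
            names=["sample_id", "replicate_index"],
        )
        frame = pd.DataFrame(x, index=idx, columns=["a", "b", "c"])
        result = grid_search_components(frame, t, k_max=3, mode="center")
        assert result.selected_k == 1

    def test_tie_breaks_to_smaller_k(self, rng):
        frame = _grouped_frame(rng)
        y = rng.normal(size=len(frame))
        result = grid_search_components(frame, y, k_max=3)
        table = result.table.set_index("k")["rmse"]
        best_rmse = table.min()
        smallest_best = min(k for k, v in table.items() if v == best_rmse)
        assert result.selected_k == smallest_best

    def test_k_max_one_returns_one_with_score_table(self, rng):
        frame = _grouped_frame(rng)
        result = grid_search_components(frame, rng.normal(size=len(frame)), 1)
        assert result.selected_k == 1
        assert list(result.table["k"]) == [1]

    def test_needs_three_samples(self, rng):
        frame = _grouped_frame(rng, n_samples=2)
        with pytest.raises(InsufficientDataError):
            grid_search_components(frame, rng.normal(size=len(frame)), 2)


class TestPersistence:
    def test_round_trip_is_exact(self, tmp_path, rng):
        x = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        y = rng.normal(size=8)
        norm = fit_normalizer(x)
        model, _ = fit_pcr(x, y, 2, normalizer=norm)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        np.testing.assert_array_equal(back.pca.components, model.pca.components)
        np.testing.assert_array_equal(back.pca.mean, model.pca.mean)
        assert back.k == model.k
        test = pd.DataFrame(rng.normal(size=(3, 4)), columns=list("abcd"))
        np.testing.assert_array_equal(predict(back, test), predict(model, test))
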