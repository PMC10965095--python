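"""Principal-component analysis, regression, and component-count search.

PCA is computed by singular value decomposition of the centered matrix, which
is the eigendecomposition of the column covariance but remains stable when
features far outnumber measurements (a 2451-potential spectrum against ~27
replicates).  The sign of each axis is fixed so its largest-magnitude loading
is positive, making runs bit-reproducible across platforms.

The component count is chosen by leave-one-sample-out cross-validation on the
training set: all replicates of a held-out sample leave together, mirroring
the unknown-solution protocol and preventing replicate leakage.  Ties go to
the smaller count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, SchemaError
from .features import Normalizer, apply_normalizer, fit_normalizer

__all__ = [
    "PCAModel",
    "PCRModel",
    "PCRFit",
    "GridSearchResult",
    "fit_pca",
    "fit_pcr",
    "predict",
    "grid_search_components",
    "save_model",
    "load_model",
]

_RANK_RTOL = 1e-12


@dataclass(frozen=True)
class PCAModel:
    """Column means, orthonormal principal axes, and explained-variance shares."""

    mean: np.ndarray                      # (n_features,)
    components: np.ndarray                # (rank, n_features), orthonormal rows
    explained_variance: np.ndarray        # (rank,), descending
    explained_variance_ratio: np.ndarray  # (rank,), descending, sums to <= 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "components", np.asarray(self.components, dtype=float))
        object.__setattr__(
            self, "explained_variance", np.asarray(self.explained_variance, dtype=float)
        )
        object.__setattr__(
            self,
            "explained_variance_ratio",
            np.asarray(self.explained_variance_ratio, dtype=float),
        )
        if np.any(np.diff(self.explained_variance_ratio) > 1e-12):
            raise ValueError("explained-variance shares must be non-increasing")

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project (rows of) ``x`` onto the principal axes."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.mean) @ self.components.T


def fit_pca(x: np.ndarray | pd.DataFrame, n_components: int | None = None) -> PCAModel:
    """Fit PCA on rows of ``x`` (already on the normalized scale).

    Axes are ordered by explained variance; numerically null directions
    (singular value below ``1e-12`` of the largest) are discarded.
    """
    values = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise InsufficientDataError("PCA needs a 2-D matrix with >= 2 rows")
    n = values.shape[0]
    mean = values.mean(axis=0)
    centered = values - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > _RANK_RTOL * (s[0] if s.size else 0.0)))
    if rank == 0:
        raise InsufficientDataError("matrix has no variation; PCA undefined")
    if n_components is not None:
        rank = min(rank, int(n_components))
    components = vt[:rank]
    # sign convention: largest-magnitude loading of each axis is positive
    flip = np.sign(components[np.arange(rank), np.argmax(np.abs(components), axis=1)])
    components = components * flip[:, None]
    explained = s[:rank] ** 2 / (n - 1)
    total = float(np.sum(centered**2)) / (n - 1)
    return PCAModel(
        mean=mean,
        components=components,
        explained_variance=explained,
        explained_variance_ratio=explained / total,
    )


@dataclass(frozen=True)
class PCRModel:
    """Normalizer + PCA + least-squares coefficients on the leading scores."""

    pca: PCAModel
    k: int
    coefficients: np.ndarray  # (k + 1,): intercept followed by k slopes
    normalizer: Normalizer | None = None

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if coef.shape != (self.k + 1,):
            raise ValueError("need exactly k + 1 coefficients (intercept + slopes)")


class PCRFit(NamedTuple):
    model: PCRModel
    fitted: np.ndarray  # training predictions, one per row


def fit_pcr(
    x: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    k: int,
    *,
    normalizer: Normalizer | None = None,
) -> PCRFit:
    """Least squares of ``y`` on the ``k`` leading component scores of ``x``.

    If ``normalizer`` is given, ``x`` is raw and is normalized first (and the
    normalizer is stored in the model so prediction applies the same chain);
    otherwise ``x`` is used as-is.
    """
    if normalizer is not None:
        if not isinstance(x, pd.DataFrame):
            raise SchemaError("a normalizer requires a named-column DataFrame")
        x = apply_normalizer(normalizer, x)
    values = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if values.shape[0] != y.size:
        raise ValueError("row count of x must equal length of y")
    if y.size < k + 1:
        raise InsufficientDataError("need at least k + 1 rows to fit k components")
    pca = fit_pca(values)
    if k > pca.n_components:
        raise InsufficientDataError(
            f"k={k} exceeds the rank {pca.n_components} of the training matrix"
        )
    scores = pca.transform(values)[:, :k]
    design = np.column_stack([np.ones(y.size), scores])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    model = PCRModel(pca=pca, k=k, coefficients=coef, normalizer=normalizer)
    return PCRFit(model=model, fitted=design @ coef)


def predict(model: PCRModel, x: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predict concentrations (mg/100 g) for raw feature rows.

    Applies the stored normalizer (if any), projects onto the stored axes and
    applies the regression coefficients; the model is never mutated.
    """
    if model.normalizer is not None:
        if not isinstance(x, pd.DataFrame):
            raise SchemaError("this model requires a named-column DataFrame")
        x = apply_normalizer(model.normalizer, x)
    values = x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)
    scores = model.pca.transform(values)[:, : model.k]
    return model.coefficients[0] + scores @ model.coefficients[1:]


@dataclass(frozen=True)
class GridSearchResult:
    selected_k: int
    table: pd.DataFrame = field(repr=False)  # columns: k, rmse


def grid_search_components(
    x: pd.DataFrame,
    y: Sequence[float],
    k_max: int,
    *,
    groups: Sequence | None = None,
    mode: str = "zscore",
) -> GridSearchResult:
    """Choose the component count by leave-one-sample-out RMSE on training data.

    ``x`` holds raw feature rows; ``groups`` assigns each row to a sample (by
    default the ``sample_id`` level of the row index).  For each held-out
    sample the normalizer and PCA are re-fitted on the remainder, so the
    selection never sees the held-out replicates.  Ties prefer the smaller k.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    y = np.asarray(y, dtype=float)
    if groups is None:
        groups = x.index.get_level_values("sample_id")
    groups = np.asarray(groups)
    unique_groups = pd.unique(groups)
    if len(unique_groups) < 3:
        raise InsufficientDataError(
            f"grid search needs >= 3 training samples, got {len(unique_groups)}"
        )
    sq_err: dict[int, list[float]] = {}
    k_cap = k_max
    for g in unique_groups:
        held = groups == g
        train_x, train_y = x.loc[~held], y[~held]
        norm = fit_normalizer(train_x, mode=mode, degenerate="drop")
        normed = apply_normalizer(norm, train_x)
        pca = fit_pca(normed)
        fold_cap = min(k_max, pca.n_components, len(train_y) - 1)
        k_cap = min(k_cap, fold_cap)
        test_scores = pca.transform(apply_normalizer(norm, x.loc[held]).to_numpy())
        train_scores = pca.transform(normed.to_numpy())
        for k in range(1, fold_cap + 1):
            design = np.column_stack([np.ones(len(train_y)), train_scores[:, :k]])
            coef, *_ = np.linalg.lstsq(design, train_y, rcond=None)
            pred = coef[0] + test_scores[:, :k] @ coef[1:]
            sq_err.setdefault(k, []).extend((pred - y[held]) ** 2)
    ks = [k for k in sorted(sq_err) if k <= k_cap]
    if not ks:
        raise InsufficientDataError("no feasible component count across folds")
    rmse = {k: float(np.sqrt(np.mean(sq_err[k]))) for k in ks}
    table = pd.DataFrame({"k": ks, "rmse": [rmse[k] for k in ks]})
    best = min(ks, key=lambda k: (rmse[k], k))
    return GridSearchResult(selected_k=int(best), table=table)


def _normalizer_to_dict(norm: Normalizer | None) -> dict | None:
    if norm is None:
        return None
    return {
        "mode": norm.mode,
        "columns": list(norm.center.index),
        "center": [float(v) for v in norm.center],
        "scale": [float(v) for v in norm.scale],
        "all_columns": list(norm.all_columns),
    }


def _normalizer_from_dict(d: dict | None) -> Normalizer | None:
    if d is None:
        return None
    idx = pd.Index(d["columns"])
    return Normalizer(
        center=pd.Series(d["center"], index=idx),
        scale=pd.Series(d["scale"], index=idx),
        mode=d["mode"],
        all_columns=tuple(d["all_columns"]),
    )


def save_model(model: PCRModel, path: str | Path) -> None:
    """Persist a fitted model as JSON; floats keep full (repr) precision."""
    payload = {
        "format": "swvquant-pcr",
        "version": 1,
        "k": model.k,
        "coefficients": model.coefficients.tolist(),
        "pca": {
            "mean": model.pca.mean.tolist(),
            "components": model.pca.components.tolist(),
            "explained_variance": model.pca.explained_variance.tolist(),
            "explained_variance_ratio": model.pca.explained_variance_ratio.tolist(),
        },
        "normalizer": _normalizer_to_dict(model.normalizer),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PCRModel:
    """Load a model written by :func:`save_model`; round-trip is exact."""
    d = json.loads(Path(path).read_text())
    if d.get("format") != "swvquant-pcr":
        raise SchemaError(f"{path}: not a saved PCR model")
    pca = PCAModel(
        mean=np.array(d["pca"]["mean"]),
        components=np.array(d["pca"]["components"]),
        explained_variance=np.array(d["pca"]["explained_variance"]),
        explained_variance_ratio=np.array(d["pca"]["explained_variance_ratio"]),
    )
    return PCRModel(
        pca=pca,
        k=int(d["k"]),
        coefficients=np.array(d["coefficients"]),
        normalizer=_normalizer_from_dict(d["normalizer"]),
    )
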