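"""Dual feature representations of a sweep: full-spectrum and window areas.

The *analytic* branch works on the full resampled spectrum (one column per
grid potential) and is later reduced to leading principal-component scores.
The *logical* branch integrates the caffeine oxidation window (1.55–1.65 V)
into 17 contiguous segment areas.

Segmentation: the sweep is resampled to ``n_points`` equally spaced potentials
on the window (51 by default) and the resulting piecewise-linear curve is
integrated over ``n_segments`` equal-width sub-windows.  The sub-windows tile
the window exactly, so the 17 areas always sum to the trapezoidal integral of
the whole window, and a constant current yields 17 identical areas.  Feature
matrices are pandas DataFrames keyed by (sample_id, replicate_index).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .exceptions import DegenerateFeatureError, InsufficientDataError, SchemaError
from .io import Sample, SampleSet, Voltammogram, resample_to_grid

__all__ = [
    "WindowSpec",
    "Normalizer",
    "logical_features",
    "logical_matrix",
    "spectrum_matrix",
    "analytic_features",
    "fit_normalizer",
    "apply_normalizer",
]

ROW_KEY = ("sample_id", "replicate_index")


@dataclass(frozen=True)
class WindowSpec:
    """The caffeine oxidation window and its segmentation."""

    low: float = 1.55       # V
    high: float = 1.65      # V
    n_points: int = 51
    n_segments: int = 17

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("window low must be < high")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.n_points < 2 * self.n_segments:
            raise ValueError("n_points must be >= 2 * n_segments")

    def grid(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_points)

    def boundaries(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_segments + 1)


def logical_features(v: Voltammogram, window: WindowSpec = WindowSpec()) -> np.ndarray:
    """Segment areas (µA·V) of the caffeine window, ordered by potential.

    Raises a range error if the sweep does not span the window.
    """
    grid = window.grid()
    resampled = resample_to_grid(v, grid)  # range-checked, no extrapolation
    cur = resampled.currents
    bounds = window.boundaries()
    tol = 1e-12 * (window.high - window.low)
    areas = np.empty(window.n_segments)
    for j in range(window.n_segments):
        lo, hi = bounds[j], bounds[j + 1]
        inside = grid[(grid > lo + tol) & (grid < hi - tol)]
        xs = np.concatenate(([lo], inside, [hi]))
        ys = np.interp(xs, grid, cur)
        areas[j] = np.trapezoid(ys, xs)
    return areas


def _row_index(pairs: Iterable[tuple[str, int]]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(list(pairs), names=ROW_KEY)


def logical_matrix(
    samples: SampleSet | Iterable[Sample], window: WindowSpec = WindowSpec()
) -> pd.DataFrame:
    """One row of segment areas per replicate; columns ``seg_01 .. seg_NN``."""
    rows, keys = [], []
    for sample in samples:
        for rep in sample.replicates:
            rows.append(logical_features(rep, window))
            keys.append((sample.sample_id, rep.replicate_index))
    columns = [f"seg_{j + 1:02d}" for j in range(window.n_segments)]
    df = pd.DataFrame(rows, index=_row_index(keys), columns=columns)
    df.attrs["branch"] = "logical"
    return df


def spectrum_matrix(
    samples: SampleSet | Iterable[Sample], grid: np.ndarray
) -> pd.DataFrame:
    """One row of resampled currents per replicate; one column per potential."""
    grid = np.asarray(grid, dtype=float)
    rows, keys = [], []
    for sample in samples:
        for rep in sample.replicates:
            rows.append(resample_to_grid(rep, grid).currents)
            keys.append((sample.sample_id, rep.replicate_index))
    columns = [f"E{p:+.4f}" for p in grid]
    df = pd.DataFrame(rows, index=_row_index(keys), columns=columns)
    df.attrs["branch"] = "analytic"
    return df


@dataclass(frozen=True)
class Normalizer:
    """Per-column centering/scaling statistics learned from training rows only.

    ``columns`` are the features retained at fit time; prediction-time inputs
    must contain exactly the training feature names (extra or missing columns
    are a schema error) and are reduced to the retained ones.
    """

    center: pd.Series
    scale: pd.Series
    mode: str = "zscore"
    all_columns: tuple[str, ...] = ()

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.center.index)


def fit_normalizer(
    train: pd.DataFrame,
    mode: Literal["zscore", "minmax", "center"] = "zscore",
    *,
    degenerate: Literal["error", "drop"] = "error",
) -> Normalizer:
    """Learn per-column center/scale from training rows.

    ``zscore`` centers by the mean and scales by the (population) standard
    deviation; ``minmax`` maps the training range onto [0, 1]; ``center``
    subtracts the mean and leaves the physical scale untouched — the usual
    choice for spectral channels, where per-channel variance scaling would
    inflate noise-only channels to the same weight as signal.  For the scaled
    modes a column with no usable variation is an error by default;
    ``degenerate="drop"`` removes such columns instead (including columns
    whose variation is at floating-point roundoff level relative to their
    magnitude, which would otherwise z-score to pure roundoff noise).
    """
    if len(train) < 2:
        raise InsufficientDataError("normalizer needs >= 2 training rows")
    if mode == "center":
        center = train.mean(axis=0)
        return Normalizer(
            center=center,
            scale=pd.Series(1.0, index=center.index),
            mode=mode,
            all_columns=tuple(train.columns),
        )
    if mode == "zscore":
        center = train.mean(axis=0)
        scale = train.std(axis=0, ddof=0)
    elif mode == "minmax":
        center = train.min(axis=0)
        scale = train.max(axis=0) - center
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    bad = scale <= 1e-8 * (center.abs() + scale)
    if bad.any():
        names = list(scale.index[bad])
        if degenerate == "error":
            shown = ", ".join(map(str, names[:5]))
            raise DegenerateFeatureError(
                f"{len(names)} degenerate training column(s): {shown}"
                + ("..." if len(names) > 5 else "")
            )
        keep = ~bad
        center, scale = center[keep], scale[keep]
        if center.empty:
            raise DegenerateFeatureError("every training column is degenerate")
    return Normalizer(
        center=center, scale=scale, mode=mode, all_columns=tuple(train.columns)
    )


def apply_normalizer(norm: Normalizer, x: pd.DataFrame) -> pd.DataFrame:
    """Apply training statistics verbatim (no re-fitting on test rows)."""
    expected = set(norm.all_columns) if norm.all_columns else set(norm.columns)
    got = set(x.columns)
    if got != expected:
        missing, extra = sorted(expected - got), sorted(got - expected)
        raise SchemaError(
            f"feature names do not match training: missing={missing[:5]} extra={extra[:5]}"
        )
    reduced = x[list(norm.columns)]
    out = (reduced - norm.center) / norm.scale
    out.attrs = dict(x.attrs)
    return out


def analytic_features(spectra: pd.DataFrame, pca, k: int) -> pd.DataFrame:
    """Scores on the ``k`` leading principal axes, one row per measurement.

    ``spectra`` must already be on the normalized scale the PCA was fitted on.
    """
    if k < 1 or k > pca.n_components:
        raise ValueError(f"k must be in 1..{pca.n_components}, got {k}")
    scores = pca.transform(spectra.to_numpy())[:, :k]
    df = pd.DataFrame(
        scores, index=spectra.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    df.attrs["branch"] = "analytic"
    return df
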