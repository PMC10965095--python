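"""Hierarchical "graded" aggregation of the two prediction branches.

Per replicate i, the analytic prediction X_i (full-spectrum PCR) and the
logical prediction Y_i (window-area PCR) are paired and averaged:

    pair sums   alpha = X_1 + Y_1,  beta = X_2 + Y_2,  gamma = X_3 + Y_3
    graded      Ave_i = (X_i + Y_i) / 2
    final       mu    = median(alpha, beta, gamma) / 2  ==  median(Ave_i)

The two formulations are algebraically identical (the median commutes with a
positive scaling), and the final prediction always lies within the range of
the graded values.  Replicate counts other than three are handled generically;
three is the study default.  Full precision is carried throughout — rounding
happens only in the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, PairingError

__all__ = [
    "PredictionRecord",
    "graded_values",
    "median_prediction",
    "aggregate",
]


def graded_values(
    analytic: Sequence[float], logical: Sequence[float]
) -> np.ndarray:
    """Element-wise mean of paired branch predictions, order preserved."""
    a = np.asarray(analytic, dtype=float)
    b = np.asarray(logical, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(
            f"branch predictions must pair one-to-one, got {a.shape} vs {b.shape}"
        )
    if a.size < 1:
        raise InsufficientDataError("need >= 1 replicate prediction per branch")
    return (a + b) / 2.0


def median_prediction(values: Sequence[float]) -> float:
    """Sample median; even counts average the two central order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InsufficientDataError("median of an empty prediction list")
    return float(np.median(v))


@dataclass(frozen=True)
class PredictionRecord:
    """Per-sample prediction hierarchy (all values mg/100 g, full precision)."""

    sample_id: str
    analytic: tuple[float, ...]       # X_1 .. X_n
    logical: tuple[float, ...]        # Y_1 .. Y_n
    pair_sums: tuple[float, ...]      # alpha, beta, gamma, ...
    graded: tuple[float, ...]         # Ave_i = pair_sums_i / 2
    median_pair_sum: float            # epsilon
    final: float                      # mu = epsilon / 2
    analytic_median: float
    logical_median: float

    def __post_init__(self) -> None:
        for name in ("analytic", "logical", "pair_sums", "graded"):
            vals = getattr(self, name)
            if not all(np.isfinite(vals)):
                raise ValueError(f"{name} predictions must all be finite")

    @property
    def n_replicates(self) -> int:
        return len(self.analytic)

    @property
    def replicate_spread(self) -> float:
        """Max − min of the graded values: a replicate-stability diagnostic.

        No automatic action is taken on it; it is exposed so a caller can
        judge whether the triplicate was stable.
        """
        return float(np.max(self.graded) - np.min(self.graded))


def aggregate(
    sample_id: str, analytic: Sequence[float], logical: Sequence[float]
) -> PredictionRecord:
    """Build the full prediction hierarchy for one sample."""
    a = np.asarray(analytic, dtype=float)
    b = np.asarray(logical, dtype=float)
    graded = graded_values(a, b)
    pair_sums = a + b
    eps = median_prediction(pair_sums)
    return PredictionRecord(
        sample_id=sample_id,
        analytic=tuple(a),
        logical=tuple(b),
        pair_sums=tuple(pair_sums),
        graded=tuple(graded),
        median_pair_sum=eps,
        final=eps / 2.0,
        analytic_median=median_prediction(a),
        logical_median=median_prediction(b),
    )
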