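"""Accuracy bookkeeping: recovery, accuracy, signed error, and summaries.

Definitions (all concentrations mg/100 g):

    recovery  = 100 * predicted / published          (%)
    accuracy  = 100 - |recovery - 100|               (%)
    error     = published - predicted                (signed, mg/100 g)

Full precision is carried internally; the *reporting* layer reproduces the
conventional table arithmetic: predictions and errors rounded half-up to two
decimals, recovery computed from the two-decimal prediction in decimal
arithmetic and rounded half-up to one decimal, accuracy derived from the
one-decimal recovery.  Summary statistics (mean and median accuracy) are taken
over those one-decimal accuracies and reported to two decimals — the order of
rounding matters and is fixed here.

The threshold-containment table reports, for each threshold t, the percentage
of samples whose (one-decimal) accuracy is >= t; these fractions are
non-increasing in t by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import PredictionRecord
from .exceptions import InsufficientDataError, LabelError

__all__ = [
    "EvaluationRow",
    "EvaluationSummary",
    "round_half_up",
    "evaluate_sample",
    "reported_row",
    "summarize",
    "error_table",
    "replicate_table",
    "sample_table",
    "summary_table",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = (80.0, 85.0, 90.0)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the tabulation convention; 0.5 rounds away)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EvaluationRow:
    """Full-precision evaluation of one sample against its published value."""

    sample_id: str
    published: float
    predicted: float
    recovery: float   # %
    accuracy: float   # %
    error: float      # mg/100 g, published - predicted


def evaluate_sample(
    published: float, predicted: float, sample_id: str = ""
) -> EvaluationRow:
    """Compute recovery/accuracy/error for one sample (published > 0)."""
    if not published > 0:
        raise ValueError(f"published value must be > 0, got {published}")
    recovery = 100.0 * predicted / published
    return EvaluationRow(
        sample_id=sample_id,
        published=float(published),
        predicted=float(predicted),
        recovery=recovery,
        accuracy=100.0 - abs(recovery - 100.0),
        error=published - predicted,
    )


def reported_row(row: EvaluationRow) -> dict:
    """Table-convention rounding of one evaluation row.

    Recovery is recomputed from the two-decimal prediction in exact decimal
    arithmetic so the printed table is self-consistent.
    """
    pred_2 = Decimal(repr(row.predicted)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    recovery = (100 * pred_2 / Decimal(repr(row.published))).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    accuracy = Decimal(100) - abs(recovery - Decimal(100))
    return {
        "sample_id": row.sample_id,
        "published": row.published,
        "predicted": float(pred_2),
        "recovery_pct": float(recovery),
        "accuracy_pct": float(accuracy),
        "error": round_half_up(row.error, 2),
    }


@dataclass(frozen=True)
class EvaluationSummary:
    """Mean/median accuracy (%) and the threshold-containment table."""

    mean_accuracy: float
    median_accuracy: float
    containment: tuple[tuple[float, float], ...]  # (threshold %, % of samples >=)
    n_samples: int


def summarize(
    rows: Sequence[EvaluationRow],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> EvaluationSummary:
    """Summary statistics over the one-decimal reported accuracies."""
    if len(rows) < 1:
        raise InsufficientDataError("cannot summarize zero evaluation rows")
    acc = np.array([reported_row(r)["accuracy_pct"] for r in rows])
    containment = tuple(
        (float(t), round_half_up(100.0 * float(np.mean(acc >= t)), 2))
        for t in thresholds
    )
    return EvaluationSummary(
        mean_accuracy=round_half_up(float(np.mean(acc)), 2),
        median_accuracy=round_half_up(float(np.median(acc)), 2),
        containment=containment,
        n_samples=len(rows),
    )


def error_table(
    records: Sequence[PredictionRecord], published: Mapping[str, float]
) -> pd.DataFrame:
    """Signed error (published − branch median) per sample and branch."""
    rows = []
    for rec in records:
        if rec.sample_id not in published:
            raise LabelError(f"no published value for sample {rec.sample_id!r}")
        pub = published[rec.sample_id]
        rows.append(
            {
                "sample_id": rec.sample_id,
                "analysis_error": pub - rec.analytic_median,
                "logical_error": pub - rec.logical_median,
                "graded_error": pub - rec.final,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def replicate_table(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    """Per-replicate branch and graded predictions (full precision)."""
    rows = []
    for rec in records:
        for i, (x, y, g) in enumerate(zip(rec.analytic, rec.logical, rec.graded)):
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "replicate_index": i + 1,
                    "analysis": x,
                    "logical": y,
                    "graded": g,
                }
            )
    return pd.DataFrame(rows)


def sample_table(
    records: Sequence[PredictionRecord], published: Mapping[str, float]
) -> pd.DataFrame:
    """Per-sample final predictions with reported recovery and accuracy."""
    rows = []
    for rec in records:
        if rec.sample_id not in published:
            raise LabelError(f"no published value for sample {rec.sample_id!r}")
        row = evaluate_sample(published[rec.sample_id], rec.final, rec.sample_id)
        rows.append(reported_row(row))
    return pd.DataFrame(rows).set_index("sample_id")


def summary_table(summary: EvaluationSummary) -> pd.DataFrame:
    """The containment + average/median summary as a tidy frame."""
    rows = [
        {"statistic": f"accuracy >= {t:g}%", "value_pct": v}
        for t, v in summary.containment
    ]
    rows.append({"statistic": "mean accuracy", "value_pct": summary.mean_accuracy})
    rows.append({"statistic": "median accuracy", "value_pct": summary.median_accuracy})
    return pd.DataFrame(rows)
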