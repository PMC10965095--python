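"""Bundled reference data.

The *beverage panel* is the published per-replicate prediction table for ten
commercial coffee samples from five brands (40–82 mg caffeine / 100 g,
triplicate SWV measurements; one sample is decaffeinated coffee spiked with
60 mg/100 g anhydrous caffeine).  It carries the analytic (full-spectrum PCR)
and logical (window-area PCR) branch predictions per replicate together with
the manufacturer-published content, and is the canonical input for the graded
ensemble and the evaluation tables.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ensemble import PredictionRecord, aggregate

__all__ = ["load_beverage_panel", "panel_records", "panel_published"]


def load_beverage_panel() -> pd.DataFrame:
    """The beverage-panel table, one row per (sample, replicate).

    Columns: ``sample_id``, ``published_mg_per_100g``, ``replicate_index``,
    ``analytic_prediction``, ``logical_prediction``.
    """
    ref = resources.files("swvquant") / "data" / "beverage_panel.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def panel_records(panel: pd.DataFrame | None = None) -> list[PredictionRecord]:
    """Aggregate the panel's branch predictions into per-sample records."""
    if panel is None:
        panel = load_beverage_panel()
    records = []
    for sid, grp in panel.groupby("sample_id", sort=False):
        grp = grp.sort_values("replicate_index")
        records.append(
            aggregate(
                str(sid),
                grp["analytic_prediction"].to_numpy(),
                grp["logical_prediction"].to_numpy(),
            )
        )
    return records


def panel_published(panel: pd.DataFrame | None = None) -> dict[str, float]:
    """Manufacturer-published content (mg/100 g) per panel sample."""
    if panel is None:
        panel = load_beverage_panel()
    return {
        str(sid): float(grp["published_mg_per_100g"].iloc[0])
        for sid, grp in panel.groupby("sample_id", sort=False)
    }
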