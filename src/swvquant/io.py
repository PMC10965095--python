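"""Voltammogram data model and plain-text I/O.

Potentials are in volts (V) and currents in microamperes (µA) at every module
boundary; unit conversion is the caller's responsibility.  A sweep is stored
sorted by ascending potential with duplicate potentials collapsed by averaging,
so re-reading an already-clean file is a no-op.

On-disk layout of a sample set::

    <dir>/manifest.csv      sample_id, replicate_index,
                            published_content_mg_per_100g (blank = unknown),
                            file, technique, scan_rate_mV_s
    <dir>/<per-replicate two-column CSV files>

Per-replicate files are two-column delimited text (potential_V, current_uA);
comma or tab is auto-detected and a single non-numeric header line is skipped.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, ParseError, RangeError

__all__ = [
    "Voltammogram",
    "Sample",
    "SampleSet",
    "read_voltammogram",
    "write_sample_set",
    "read_sample_set",
    "resample_to_grid",
]

_TECHNIQUES = ("SWV", "CV")


@dataclass(frozen=True)
class Voltammogram:
    """One potential sweep: aligned potential (V) and current (µA) series.

    ``scan_rate`` (mV/s) is required for CV sweeps and must be absent for SWV.
    """

    potentials: np.ndarray
    currents: np.ndarray
    technique: str = "SWV"
    sample_id: str = ""
    replicate_index: int = 1
    scan_rate: float | None = None

    def __post_init__(self) -> None:
        pot = np.asarray(self.potentials, dtype=float)
        cur = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "potentials", pot)
        object.__setattr__(self, "currents", cur)
        if pot.ndim != 1 or cur.ndim != 1 or pot.size != cur.size:
            raise ValueError("potentials and currents must be 1-D and equal length")
        if pot.size < 2:
            raise InsufficientDataError(
                f"voltammogram needs >= 2 points, got {pot.size}"
            )
        if not np.all(np.diff(pot) > 0):
            raise ValueError("potentials must be strictly increasing")
        if not (np.all(np.isfinite(pot)) and np.all(np.isfinite(cur))):
            raise ValueError("potentials and currents must be finite")
        if self.technique not in _TECHNIQUES:
            raise ValueError(f"technique must be one of {_TECHNIQUES}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")
        if self.technique == "CV":
            if self.scan_rate is None or not self.scan_rate > 0:
                raise ValueError("CV sweeps require scan_rate > 0 (mV/s)")
        elif self.scan_rate is not None:
            raise ValueError("scan_rate is only meaningful for CV sweeps")

    def __len__(self) -> int:
        return int(self.potentials.size)

    @property
    def potential_range(self) -> tuple[float, float]:
        return float(self.potentials[0]), float(self.potentials[-1])

    def with_metadata(self, **kwargs) -> "Voltammogram":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Sample:
    """A beverage with its replicate sweeps and (for training) its label.

    ``published_content`` is the manufacturer-published caffeine content in
    mg per 100 g; ``None`` marks an unknown (test-only) sample.
    """

    sample_id: str
    replicates: tuple[Voltammogram, ...]
    published_content: float | None = None

    def __post_init__(self) -> None:
        reps = tuple(self.replicates)
        object.__setattr__(self, "replicates", reps)
        if len(reps) < 1:
            raise InsufficientDataError("a sample needs >= 1 replicate")
        if any(r.sample_id != self.sample_id for r in reps):
            raise ValueError("all replicates must share the sample's sample_id")
        idx = [r.replicate_index for r in reps]
        if len(set(idx)) != len(idx):
            raise ValueError("replicate_index values must be distinct")
        if self.published_content is not None:
            if not (math.isfinite(self.published_content) and self.published_content >= 0):
                raise ValueError("published_content must be finite and >= 0")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


@dataclass(frozen=True)
class SampleSet:
    """An ordered collection of samples with unique identifiers."""

    samples: tuple[Sample, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique within a SampleSet")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def labeled(self) -> tuple[Sample, ...]:
        return tuple(s for s in self.samples if s.published_content is not None)

    def potential_overlap(self) -> tuple[float, float]:
        """Largest potential range covered by every replicate of every sample."""
        los, his = zip(
            *(r.potential_range for s in self.samples for r in s.replicates)
        )
        lo, hi = max(los), min(his)
        if not lo < hi:
            raise RangeError("replicate sweeps have no common potential range")
        return lo, hi


def _parse_rows(path: Path) -> list[tuple[float, float]]:
    text = path.read_text()
    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        for delim in (",", "\t", ";", None):  # None = any whitespace
            parts = [p for p in line.split(delim) if p.strip()]
            if len(parts) >= 2:
                break
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected two columns, got {line!r}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if lineno == 1 and not rows:
                continue  # a single non-numeric header line is allowed
            raise ParseError(
                f"{path}: line {lineno}: non-numeric row {line!r}"
            ) from None
    return rows


def read_voltammogram(
    path: str | Path,
    *,
    technique: str = "SWV",
    sample_id: str | None = None,
    replicate_index: int = 1,
    scan_rate: float | None = None,
) -> Voltammogram:
    """Read a two-column (potential, current) text table.

    Rows may be unordered; they are sorted by ascending potential and rows
    sharing a potential are collapsed by averaging their currents.
    """
    path = Path(path)
    rows = _parse_rows(path)
    if not rows:
        raise InsufficientDataError(f"{path}: no data rows")
    pot = np.array([r[0] for r in rows])
    cur = np.array([r[1] for r in rows])
    order = np.argsort(pot, kind="stable")
    pot, cur = pot[order], cur[order]
    uniq, inverse, counts = np.unique(pot, return_inverse=True, return_counts=True)
    if uniq.size < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 distinct potentials")
    mean_cur = np.bincount(inverse, weights=cur) / counts
    return Voltammogram(
        potentials=uniq,
        currents=mean_cur,
        technique=technique,
        sample_id=sample_id if sample_id is not None else path.stem,
        replicate_index=replicate_index,
        scan_rate=scan_rate,
    )


_MANIFEST_COLUMNS = [
    "sample_id",
    "replicate_index",
    "published_content_mg_per_100g",
    "file",
    "technique",
    "scan_rate_mV_s",
]


def write_sample_set(sample_set: SampleSet, directory: str | Path) -> Path:
    """Write a sample set as a manifest plus per-replicate tables.

    Returns the manifest path.  Numeric series are written with ``repr``
    precision so that a read-back reproduces them exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for sample in sample_set:
            for rep in sample.replicates:
                fname = f"{sample.sample_id}_r{rep.replicate_index}.csv"
                with (directory / fname).open("w", newline="") as rf:
                    rw = csv.writer(rf)
                    rw.writerow(["potential_V", "current_uA"])
                    for p, c in zip(rep.potentials, rep.currents):
                        rw.writerow([repr(float(p)), repr(float(c))])
                writer.writerow(
                    [
                        sample.sample_id,
                        rep.replicate_index,
                        "" if sample.published_content is None
                        else repr(float(sample.published_content)),
                        fname,
                        rep.technique,
                        "" if rep.scan_rate is None else repr(float(rep.scan_rate)),
                    ]
                )
    return manifest


def read_sample_set(manifest: str | Path) -> SampleSet:
    """Read a sample set written by :func:`write_sample_set`.

    ``manifest`` may be the manifest file or the directory containing
    ``manifest.csv``.
    """
    manifest = Path(manifest)
    if manifest.is_dir():
        manifest = manifest / "manifest.csv"
    directory = manifest.parent
    by_sample: dict[str, dict] = {}
    with manifest.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{manifest}: missing manifest columns {sorted(missing)}")
        for row in reader:
            sid = row["sample_id"]
            entry = by_sample.setdefault(sid, {"published": None, "reps": []})
            pub = row["published_content_mg_per_100g"].strip()
            if pub:
                entry["published"] = float(pub)
            rate = row["scan_rate_mV_s"].strip()
            rep = read_voltammogram(
                directory / row["file"],
                technique=row["technique"],
                sample_id=sid,
                replicate_index=int(row["replicate_index"]),
                scan_rate=float(rate) if rate else None,
            )
            entry["reps"].append(rep)
    samples = tuple(
        Sample(
            sample_id=sid,
            replicates=tuple(sorted(e["reps"], key=lambda r: r.replicate_index)),
            published_content=e["published"],
        )
        for sid, e in by_sample.items()
    )
    return SampleSet(samples=samples)


def resample_to_grid(
    v: Voltammogram, grid: Sequence[float] | np.ndarray
) -> Voltammogram:
    """Linearly interpolate a sweep onto ``grid`` (strictly increasing, V).

    Every grid point must lie inside the measured range; extrapolation is
    refused so that window features can never be fabricated.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a non-empty 1-D sequence")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    lo, hi = v.potential_range
    tol = 1e-12 * max(1.0, abs(lo), abs(hi))
    if grid[0] < lo - tol or grid[-1] > hi + tol:
        raise RangeError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] outside measured range [{lo:g}, {hi:g}]"
        )
    clipped = np.clip(grid, lo, hi)
    currents = np.interp(clipped, v.potentials, v.currents)
    return replace(v, potentials=grid, currents=currents)
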