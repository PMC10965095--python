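"""Phenomenological simulators for SWV sample sets and CV capacitance sweeps.

The SWV model is additive, not first-principles: a flat baseline, a broad
interferent band over 0–1 V (oxidation of hydroxyl-bearing organics in the
beverage matrix), a caffeine oxidation peak at 1.6 V whose height is affine in
concentration, a secondary caffeine-coupled response near 0.6 V, multiplicative
electrode-to-electrode gain, and additive per-point replicate noise:

    i(E) = gain * [ baseline + sum_b h_b G(E; c_b, w_b)
                    + (slope*conc + intercept) * (G(E; 1.6, s) + f*G(E; 0.6, s')) ]
           + noise,

with G a unit-height Gaussian.  With zero noise and unit gain the trace is a
deterministic function of (concentration, config), and linear in concentration
at every potential when the intercept is zero.

Randomness contract: a single master seed; per-sample and per-replicate
sub-streams are derived through ``numpy.random.SeedSequence`` spawn keys, so
appending a sample never perturbs earlier samples' draws.  Electrode gain and
interferent-band jitter are drawn once per sample (shared by its triplicate);
replicate noise is independent per trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError
from .io import Sample, SampleSet, Voltammogram

__all__ = [
    "SwvSimConfig",
    "CvSimConfig",
    "noiseless",
    "simulate_swv",
    "simulate_sample_set",
    "simulate_cv_set",
    "PANEL_CONCENTRATIONS",
]

#: Reference-panel label set: ten commercial coffees, mg caffeine per 100 g.
PANEL_CONCENTRATIONS: tuple[float, ...] = (40, 40, 60, 60, 62, 70, 70, 78, 80, 82)


def _gauss(e: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((e - center) / width) ** 2)


@dataclass(frozen=True)
class SwvSimConfig:
    """Study conditions for simulated SWV sweeps.

    The grid spans −2.4 … 2.5 V at 0.002 V so the 1.55–1.65 V caffeine window
    holds exactly 51 points.  Defaults put a ~30 µA caffeine peak on a 60
    mg/100 g beverage over a ~10 µA interferent band, with near-overlapping
    triplicates (0.3 µA noise) and 5 % electrode-to-electrode gain spread.
    """

    grid_start: float = -2.4          # V
    grid_end: float = 2.5             # V
    grid_step: float = 0.002          # V
    caffeine_peak_center: float = 1.6  # V
    caffeine_peak_width: float = 0.05  # V (Gaussian sigma)
    response_slope: float = 0.5       # µA per (mg/100 g)
    response_intercept: float = 0.0   # µA
    secondary_peak_center: float = 0.6  # V
    secondary_peak_width: float = 0.1   # V (Gaussian sigma)
    secondary_fraction: float = 0.3   # of main peak height
    interferent_band: tuple[tuple[float, float, float], ...] = (
        (0.15, 6.0, 0.12),
        (0.45, 10.0, 0.22),
        (0.75, 7.0, 0.18),
    )  # (center V, height µA, sigma V)
    baseline_level: float = 2.0       # µA
    replicate_noise_sd: float = 0.3   # µA
    electrode_gain_sd: float = 0.05   # dimensionless
    interferent_jitter_sd: float = 0.15  # lognormal sigma, per sample & band
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid_start < self.grid_end:
            raise ValueError("grid_start must be < grid_end")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be > 0")
        if not (self.caffeine_peak_width > 0 and self.secondary_peak_width > 0):
            raise ValueError("peak widths must be > 0")
        for c, h, w in self.interferent_band:
            if not (0.0 <= c <= 1.0) or h < 0 or not w > 0:
                raise ValueError(
                    "interferent bands need center in [0, 1], height >= 0, width > 0"
                )
        for name in ("replicate_noise_sd", "electrode_gain_sd", "interferent_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def grid(self) -> np.ndarray:
        n = round((self.grid_end - self.grid_start) / self.grid_step)
        return np.linspace(self.grid_start, self.grid_end, n + 1)


@dataclass(frozen=True)
class CvSimConfig:
    """Study conditions for simulated CV capacitance sweeps.

    An ideal double-layer capacitor: anodic current density +Cdl*nu, cathodic
    −Cdl*nu (nu in V/s), over a 0–0.1 V non-faradaic window for scan rates 10
    to 100 mV/s in 10 mV/s steps.  Currents are densities in µA/cm².
    """

    cdl_true: float = 0.18            # µF/cm²
    scan_rates: tuple[float, ...] = tuple(range(10, 101, 10))  # mV/s
    potential_start: float = 0.0      # V
    potential_end: float = 0.1        # V
    n_points: int = 51
    noise_sd: float = 0.0             # µA/cm²
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cdl_true > 0:
            raise ValueError("cdl_true must be > 0")
        if len(self.scan_rates) < 2:
            raise ValueError("need >= 2 scan rates")
        if any(not r > 0 for r in self.scan_rates):
            raise ValueError("scan rates must be > 0")
        if not self.potential_start < self.potential_end:
            raise ValueError("potential range must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def noiseless(cfg: SwvSimConfig) -> SwvSimConfig:
    """The same study conditions with every stochastic term switched off."""
    return replace(
        cfg, replicate_noise_sd=0.0, electrode_gain_sd=0.0, interferent_jitter_sd=0.0
    )


def clean_response(concentration: float, cfg: SwvSimConfig) -> np.ndarray:
    """Deterministic (zero-noise, unit-gain) trace for one concentration."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    e = cfg.grid()
    background = np.full_like(e, float(cfg.baseline_level))
    for center, height, width in cfg.interferent_band:
        background += height * _gauss(e, center, width)
    shape = _gauss(e, cfg.caffeine_peak_center, cfg.caffeine_peak_width)
    shape = shape + cfg.secondary_fraction * _gauss(
        e, cfg.secondary_peak_center, cfg.secondary_peak_width
    )
    amplitude = cfg.response_slope * concentration + cfg.response_intercept
    return background + amplitude * shape


def simulate_swv(
    concentration: float,
    cfg: SwvSimConfig,
    *,
    electrode_gain: float = 1.0,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
    replicate_index: int = 1,
) -> Voltammogram:
    """Simulate one SWV sweep at the given concentration (mg/100 g).

    With ``replicate_noise_sd == 0`` and ``electrode_gain == 1`` the output is
    a deterministic function of (concentration, cfg).
    """
    currents = electrode_gain * clean_response(concentration, cfg)
    if cfg.replicate_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        currents = currents + cfg.replicate_noise_sd * rng.standard_normal(
            currents.size
        )
    return Voltammogram(
        potentials=cfg.grid(),
        currents=currents,
        technique="SWV",
        sample_id=sample_id,
        replicate_index=replicate_index,
    )


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sample_index,))
    )


def _replicate_rng(seed: int, sample_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(sample_index, rep))
    )


def simulate_sample_set(
    concentrations: Sequence[float],
    n_replicates: int = 3,
    cfg: SwvSimConfig = SwvSimConfig(),
    *,
    labeled: bool = True,
) -> SampleSet:
    """Simulate one sample per concentration, each measured ``n_replicates`` times.

    Each sample draws one electrode gain ~ Normal(1, electrode_gain_sd) and one
    lognormal height multiplier per interferent band (different "brands" have
    different backgrounds); its replicates share those and differ only by
    additive noise.  ``published_content`` is the input concentration unless
    ``labeled`` is false.
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise InsufficientDataError("concentration list must not be empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    samples = []
    for i, conc in enumerate(concentrations):
        srng = _sample_rng(cfg.seed, i)
        gain = 1.0 + cfg.electrode_gain_sd * srng.standard_normal()
        jitter = np.exp(
            cfg.interferent_jitter_sd * srng.standard_normal(len(cfg.interferent_band))
        )
        sample_cfg = replace(
            cfg,
            interferent_band=tuple(
                (c, h * j, w) for (c, h, w), j in zip(cfg.interferent_band, jitter)
            ),
        )
        sid = f"S{i + 1:02d}"
        reps = tuple(
            simulate_swv(
                conc,
                sample_cfg,
                electrode_gain=gain,
                rng=_replicate_rng(cfg.seed, i, r),
                sample_id=sid,
                replicate_index=r,
            )
            for r in range(1, n_replicates + 1)
        )
        samples.append(
            Sample(
                sample_id=sid,
                replicates=reps,
                published_content=float(conc) if labeled else None,
            )
        )
    return SampleSet(samples=tuple(samples))


def simulate_cv_set(
    cfg: CvSimConfig = CvSimConfig(),
) -> list[tuple[Voltammogram, Voltammogram]]:
    """Simulate (anodic, cathodic) CV branch pairs, one per scan rate.

    Currents are densities (µA/cm²): for an ideal capacitor the anodic branch
    carries +cdl_true*nu and the cathodic −cdl_true*nu, nu in V/s; Gaussian
    noise of ``noise_sd`` is added per point.  Deterministic at noise_sd = 0.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.linspace(cfg.potential_start, cfg.potential_end, cfg.n_points)
    pairs = []
    for nu_mv in cfg.scan_rates:
        nu = nu_mv / 1000.0  # V/s
        level = cfg.cdl_true * nu  # µF/cm² * V/s = µA/cm²
        anodic = np.full(cfg.n_points, level)
        cathodic = np.full(cfg.n_points, -level)
        if cfg.noise_sd > 0:
            anodic = anodic + cfg.noise_sd * rng.standard_normal(cfg.n_points)
            cathodic = cathodic + cfg.noise_sd * rng.standard_normal(cfg.n_points)
        meta = dict(technique="CV", scan_rate=float(nu_mv))
        pairs.append(
            (
                Voltammogram(grid, anodic, sample_id=f"cv_{nu_mv:g}_anodic", **meta),
                Voltammogram(grid, cathodic, sample_id=f"cv_{nu_mv:g}_cathodic", **meta),
            )
        )
    return pairs
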