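"""Synthetic acquisition: everything the measurement hardware would produce.

This module stands in for a 64-chip impedance plate reader.  It generates

* the plate layout (64 chips on an 8×8 logical grid, 8 electrodes per chip,
  512 electrodes total, each chip spanning six microtiter wells),
* compensation-board spectra (known resistors seen through the parasitic
  network),
* noisy per-chip measured spectra, and
* treatment-driven barrier-resistance time courses over a 44–48 h exposure.

The barrier scenarios emulate endothelial inflammation phenotypes:

``control``
    constant baseline barrier.
``ifng``
    IFN-γ-like slow exponential decline whose rate increases with dose.
``tnfa``
    TNFα-like sharp transient dip centred near 2 h that recovers toward
    baseline well before the endpoint.
``combo``
    TNFα+IFN-γ-like dip of the same onset whose floor persists — no
    recovery.
``disruptor``
    apoptosis-inducer-like (staurosporine) rapid monotone collapse of the
    barrier toward zero.

Dose dependence enters through a saturating Hill function with half-maximum
well below 10 ng/ml, so 10 and 100 ng/ml produce nearly the same amplitude
while 0.1 and 1 ng/ml remain clearly dose-ordered — the qualitative pattern
seen in cytokine exposures of endothelial tubules.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so a simulated dataset is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circuits import (
    DEFAULT_F_MAX_HZ,
    DEFAULT_F_MIN_HZ,
    DEFAULT_N_POINTS,
    ChipCircuitParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    ParasiticParams,
    chip_impedance,
    error_network_forward,
)
from .compensation import DEFAULT_LOADS_OHM, CompensationSet

__all__ = [
    "PlateLayout",
    "NoiseModel",
    "BarrierScenario",
    "MeasurementSchedule",
    "TimelapseRecord",
    "TimelapseDataset",
    "SCENARIO_KINDS",
    "make_frequency_grid",
    "default_frequency_grid",
    "default_plate_layout",
    "barrier_trajectory",
    "simulate_chip_spectrum",
    "simulate_compensation_boards",
    "simulate_timelapse",
    "DEFAULT_CHIP_PARAMS",
    "DEFAULT_PARASITICS",
]

SCENARIO_KINDS = ("control", "ifng", "tnfa", "combo", "disruptor")

#: Baseline chip circuit: ~25 kΩ series path with a modest endothelial
#: barrier.  The CPE magnitude corresponds to ≈1 µF/cm² of cell-layer
#: capacitance over the ≈0.0057 cm² interface, mildly depressed (α = 0.95).
DEFAULT_CHIP_PARAMS = ChipCircuitParams(
    r_series=25_000.0, r_barrier=2_000.0, q_cpe=5.7e-9, alpha=0.95
)

#: Default parasitic path: 100 Ω lead plus 10 pF stray capacitance — a
#: PCB-trace-level stray that visibly bends the spectrum near 1 MHz at the
#: 25 kΩ level without drowning the high-frequency signal.
DEFAULT_PARASITICS = ParasiticParams(r_lead=100.0, c_par=10.0e-12)


def make_frequency_grid(
    f_min: float = DEFAULT_F_MIN_HZ,
    f_max: float = DEFAULT_F_MAX_HZ,
    n_points: int = DEFAULT_N_POINTS,
) -> FrequencyGrid:
    """Log-equally-spaced sweep, endpoints included.

    The default reproduces the acquisition sweep: 121 points from 1 kHz to
    1 MHz (40 per decade over three decades, plus the endpoint).
    """
    if not f_min < f_max:
        raise ValueError(f"need f_min < f_max, got {f_min} >= {f_max}")
    if n_points < 2:
        raise ValueError(f"need n_points >= 2, got {n_points}")
    values = np.logspace(math.log10(f_min), math.log10(f_max), n_points)
    # pin endpoints exactly despite floating-point logspace rounding
    values[0], values[-1] = f_min, f_max
    return FrequencyGrid(values)


def default_frequency_grid() -> FrequencyGrid:
    return make_frequency_grid()


@dataclass(frozen=True)
class PlateLayout:
    """Chip and electrode layout of a multi-chip microfluidic plate."""

    n_chips: int = 64
    chips: tuple[tuple[str, int, int], ...] = ()
    electrodes_per_chip: int = 8
    wells_per_chip: int = 6

    def __post_init__(self) -> None:
        if self.n_chips < 1:
            raise ValueError("n_chips must be >= 1")
        if len(self.chips) != self.n_chips:
            raise ValueError("chips list length must equal n_chips")
        ids = [c[0] for c in self.chips]
        if len(set(ids)) != len(ids):
            raise ValueError("chip ids must be unique")

    @property
    def chip_ids(self) -> list[str]:
        return [c[0] for c in self.chips]

    @property
    def total_electrodes(self) -> int:
        return self.n_chips * self.electrodes_per_chip


def default_plate_layout() -> PlateLayout:
    """64 chips on an 8×8 logical grid; 8 electrodes each; 512 total.

    Each chip carries one current-carrying and one voltage-sensing loop, each
    loop terminal shorted to a pair of electrodes in the inlet and outlet of
    its perfusion channel — 4 terminals × 2 electrodes = 8 per chip.
    """
    chips = tuple(
        (f"{chr(ord('A') + row)}{col + 1:02d}", row, col)
        for row in range(8)
        for col in range(8)
    )
    return PlateLayout(n_chips=64, chips=chips, electrodes_per_chip=8, wells_per_chip=6)


@dataclass(frozen=True)
class NoiseModel:
    """Relative i.i.d. Gaussian noise on each measured impedance point.

    The real and imaginary parts are perturbed independently, each with a
    standard deviation of ``sigma_rel`` times that part's own magnitude:
    ``Re' = Re·(1 + σε₁)``, ``Im' = Im·(1 + σε₂)``."""

    sigma_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")


@dataclass(frozen=True)
class BarrierScenario:
    """Parametric time course of the true barrier resistance under treatment.

    Shape parameters (defaults chosen to emulate the cytokine phenotypes):

    dip_time_h:
        Centre of the transient TNFα-type dip, h.
    dip_depth_max:
        Maximal fractional barrier loss at saturating dose (0–1).
    decline_rate_max_per_h:
        Maximal IFN-γ-type exponential decline rate at saturating dose, /h.
    combo_onset_tau_h:
        Time constant of the persistent combo decline onset, h.
    disruptor_rate_per_h:
        Exponential collapse rate of the barrier-disruptor scenario, /h.
    hill_k_ng_ml, hill_n:
        Half-maximum and slope of the dose-saturation Hill curve; with the
        defaults the response at 10 ng/ml is already ≈98% of saturation.
    """

    kind: str
    dose: float = 0.0
    baseline_r_barrier: float = 2_000.0
    dip_time_h: float = 2.0
    dip_depth_max: float = 0.5
    decline_rate_max_per_h: float = 0.012
    combo_onset_tau_h: float = 1.0
    disruptor_rate_per_h: float = 1.0
    hill_k_ng_ml: float = 1.5
    hill_n: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}"
            )
        if not self.baseline_r_barrier > 0:
            raise ValueError("baseline_r_barrier must be > 0")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if not 0 <= self.dip_depth_max < 1:
            raise ValueError("dip_depth_max must be in [0, 1)")

    def dose_effect(self) -> float:
        """Saturating Hill response in [0, 1)."""
        if self.dose == 0:
            return 0.0
        dn = self.dose**self.hill_n
        return dn / (dn + self.hill_k_ng_ml**self.hill_n)


def barrier_trajectory(scenario: BarrierScenario, t_hours) -> np.ndarray | float:
    """True barrier resistance (Ω) at time ``t_hours`` after exposure.

    Accepts a scalar or array of times (``t >= 0``); the value is strictly
    positive at all times for every scenario.
    """
    t = np.asarray(t_hours, dtype=float)
    if np.any(t < 0):
        raise ValueError("trajectory times must be >= 0 (hours after exposure)")
    base = scenario.baseline_r_barrier
    e = scenario.dose_effect()
    kind = scenario.kind

    if kind == "control":
        rel = np.ones_like(t)
    elif kind == "ifng":
        rel = np.exp(-scenario.decline_rate_max_per_h * e * t)
    elif kind == "tnfa":
        # gamma-pulse dip: unit amplitude at t = dip_time, recovers to ~0
        tau = scenario.dip_time_h
        pulse = (t / tau) * np.exp(1.0 - t / tau)
        rel = 1.0 - scenario.dip_depth_max * e * pulse
    elif kind == "combo":
        # same onset speed as the dip, but the floor persists (no recovery)
        onset = 1.0 - np.exp(-t / scenario.combo_onset_tau_h)
        rel = 1.0 - scenario.dip_depth_max * e * onset
    elif kind == "disruptor":
        rel = np.exp(-scenario.disruptor_rate_per_h * t)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown scenario kind {kind!r}")

    out = base * rel
    if t.ndim == 0:
        return float(out)
    return out


def simulate_chip_spectrum(
    params: ChipCircuitParams,
    parasitics: ParasiticParams,
    grid: FrequencyGrid,
    noise: NoiseModel,
) -> ImpedanceSpectrum:
    """One measured spectrum: true circuit → parasitic network → noise."""
    z_true = error_network_forward(parasitics, chip_impedance(params, grid))
    if noise.sigma_rel == 0.0:
        return z_true
    rng = np.random.default_rng(noise.seed)
    z = _add_relative_noise(z_true.z, noise.sigma_rel, rng)
    return ImpedanceSpectrum(grid=grid, z=z)


def _add_relative_noise(z: np.ndarray, sigma_rel: float, rng) -> np.ndarray:
    n = z.size
    return z.real * (1.0 + sigma_rel * rng.standard_normal(n)) + 1j * z.imag * (
        1.0 + sigma_rel * rng.standard_normal(n)
    )


def simulate_compensation_boards(
    parasitics: ParasiticParams,
    loads=DEFAULT_LOADS_OHM,
    grid: FrequencyGrid | None = None,
    noise: NoiseModel = NoiseModel(),
) -> CompensationSet:
    """Measured spectra of the reference boards: each chip path replaced by a
    known resistor, seen through the same parasitic network."""
    if grid is None:
        grid = default_frequency_grid()
    loads_arr = np.asarray(loads, dtype=float)
    if loads_arr.size < 3 or np.unique(loads_arr).size != loads_arr.size:
        raise ValueError("at least 3 pairwise-distinct loads are required")
    ss = np.random.SeedSequence(noise.seed)
    children = ss.spawn(loads_arr.size)
    spectra = []
    for load, child in zip(loads_arr, children):
        z_load = ImpedanceSpectrum(
            grid=grid, z=np.full(len(grid), load, dtype=complex)
        )
        z_meas = error_network_forward(parasitics, z_load)
        if noise.sigma_rel > 0:
            rng = np.random.default_rng(child)
            z_meas = ImpedanceSpectrum(
                grid=grid, z=_add_relative_noise(z_meas.z, noise.sigma_rel, rng)
            )
        spectra.append(z_meas)
    return CompensationSet(loads=loads_arr, spectra=spectra)


@dataclass(frozen=True)
class MeasurementSchedule:
    """Timelapse schedule in minutes relative to exposure at t = 0.

    Defaults: a baseline reading shortly before exposure (T₋₁), a reading at
    exposure, a fast phase every 4 min through 44 min, a slow phase every
    64 min through 43 h, and one endpoint inside the 44–48 h window.
    """

    baseline_time_min: float = -6.0
    fast_interval_min: float = 4.0
    fast_duration_min: float = 44.0
    slow_interval_min: float = 64.0
    slow_duration_min: float = 43.0 * 60.0
    endpoint_time_min: float = 46.0 * 60.0

    def __post_init__(self) -> None:
        if self.baseline_time_min >= 0:
            raise ValueError("baseline must precede exposure at t=0")
        if self.fast_interval_min <= 0 or self.slow_interval_min <= 0:
            raise ValueError("intervals must be positive")
        if not (
            self.fast_duration_min
            < self.slow_duration_min
            < self.endpoint_time_min
        ):
            raise ValueError("phases must be strictly ordered in time")

    def times_min(self) -> np.ndarray:
        """All measurement times in minutes, strictly increasing."""
        fast = np.arange(0.0, self.fast_duration_min + 1e-9, self.fast_interval_min)
        slow_start = self.fast_duration_min + self.slow_interval_min
        slow = np.arange(
            slow_start, self.slow_duration_min + 1e-9, self.slow_interval_min
        )
        times = np.concatenate(
            [[self.baseline_time_min], fast, slow, [self.endpoint_time_min]]
        )
        if not np.all(np.diff(times) > 0):
            raise ValueError("schedule times must be strictly increasing")
        return times


@dataclass(frozen=True)
class TimelapseRecord:
    chip_id: str
    time_min: float
    spectrum: ImpedanceSpectrum


@dataclass
class TimelapseDataset:
    """Simulated plate timelapse: one spectrum per chip per scheduled time."""

    layout: PlateLayout
    schedule: MeasurementSchedule
    condition_map: dict[str, tuple[str, float]]
    records: list[TimelapseRecord] = field(default_factory=list)

    def spectra_for_chip(self, chip_id: str) -> list[TimelapseRecord]:
        return [r for r in self.records if r.chip_id == chip_id]


def simulate_timelapse(
    layout: PlateLayout,
    condition_map: dict[str, tuple[str, float]],
    schedule: MeasurementSchedule,
    chip_params_base: ChipCircuitParams = DEFAULT_CHIP_PARAMS,
    parasitics: ParasiticParams = DEFAULT_PARASITICS,
    noise: NoiseModel = NoiseModel(),
    chip_cv: float = 0.10,
    scenario_kwargs: dict | None = None,
    grid: FrequencyGrid | None = None,
) -> TimelapseDataset:
    """Simulate a full plate timelapse.

    Each chip gets seeded lognormal multiplicative factors (σ = ``chip_cv``)
    on its baseline series resistance, barrier resistance and CPE magnitude;
    its barrier resistance then follows :func:`barrier_trajectory` for the
    scenario assigned in ``condition_map`` (pre-exposure times sit at
    baseline).  Measurement noise is drawn independently per chip and
    timepoint from seeds derived deterministically from ``noise.seed``.
    """
    missing = [cid for cid in layout.chip_ids if cid not in condition_map]
    if missing:
        raise ValueError(f"chips missing from condition_map: {missing}")
    scenario_kwargs = scenario_kwargs or {}

    times = schedule.times_min()
    ss = np.random.SeedSequence(noise.seed)
    chip_seeds = ss.spawn(layout.n_chips)

    records: list[TimelapseRecord] = []
    if grid is None:
        grid = default_frequency_grid()
    for chip_idx, chip_id in enumerate(layout.chip_ids):
        chip_ss = chip_seeds[chip_idx]
        rng = np.random.default_rng(chip_ss)
        if chip_cv > 0:
            factors = np.exp(rng.normal(0.0, chip_cv, size=3))
        else:
            factors = np.ones(3)
        r_series = chip_params_base.r_series * factors[0]
        r_barrier0 = chip_params_base.r_barrier * factors[1]
        q_cpe = chip_params_base.q_cpe * factors[2]
        alpha = chip_params_base.alpha

        kind, dose = condition_map[chip_id]
        scenario = BarrierScenario(
            kind=kind,
            dose=dose,
            baseline_r_barrier=r_barrier0,
            **scenario_kwargs,
        )
        time_seeds = chip_ss.spawn(times.size)
        for t_min, t_seed in zip(times, time_seeds):
            t_h = max(t_min, 0.0) / 60.0  # pre-exposure times sit at baseline
            r_b = float(barrier_trajectory(scenario, t_h))
            params_t = ChipCircuitParams(
                r_series=r_series,
                r_barrier=max(r_b, 1e-6),
                q_cpe=q_cpe,
                alpha=alpha,
            )
            point_noise = NoiseModel(
                sigma_rel=noise.sigma_rel,
                seed=int(t_seed.generate_state(1)[0] % (2**31)),
            )
            spectrum = simulate_chip_spectrum(params_t, parasitics, grid, point_noise)
            records.append(
                TimelapseRecord(chip_id=chip_id, time_min=float(t_min), spectrum=spectrum)
            )

    return TimelapseDataset(
        layout=layout,
        schedule=schedule,
        condition_map=dict(condition_map),
        records=records,
    )
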