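"""File formats and run configuration.

No community standard exists for TEER impedance spectra, so the interchange
dialect is documented here and kept deliberately plain:

* **Spectra CSV** (RFC-4180, UTF-8, ``.`` decimal): long format with columns
  ``plate_id, chip_id, time_min, frequency_hz, z_real_ohm, z_imag_ohm``.
  Within one ``(chip_id, time_min)`` block frequencies are strictly
  increasing; duplicate ``(chip, time, frequency)`` rows are an error.
  Floats are written with 17 significant digits so a write→read round trip
  is lossless at double precision.
* **Load sidecar CSV**: ``load_id, resistance_ohm`` naming each compensation
  board.
* **Run config JSON**: everything a full in-silico experiment needs — grid,
  loads, parasitics, noise, schedule, condition layout, fit options — under
  a single seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .circuits import ChipCircuitParams, FrequencyGrid, ImpedanceSpectrum, ParasiticParams
from .compensation import CompensationSet
from .fitting import DEFAULT_INTERFACE_AREA_CM2, FitOptions
from .synthetic import (
    MeasurementSchedule,
    NoiseModel,
    PlateLayout,
    TimelapseDataset,
    default_plate_layout,
    make_frequency_grid,
)

__all__ = [
    "SPECTRA_COLUMNS",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "dataset_to_table",
    "table_to_spectra",
    "write_loads",
    "read_loads",
    "compensation_set_from_tables",
    "RunConfig",
    "load_config",
    "example_config_path",
]

SPECTRA_COLUMNS = [
    "plate_id",
    "chip_id",
    "time_min",
    "frequency_hz",
    "z_real_ohm",
    "z_imag_ohm",
]

_FLOAT_FMT = "%.17g"


class SpectraFormatError(ValueError):
    """Malformed spectra table (missing columns, duplicates, bad ordering)."""


def write_spectra(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format spectra table as CSV, lossless at double precision."""
    missing = [c for c in SPECTRA_COLUMNS if c not in table.columns]
    if missing:
        raise SpectraFormatError(f"spectra table missing columns: {missing}")
    table[SPECTRA_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra(path: str | Path) -> pd.DataFrame:
    """Read and validate a spectra CSV.

    Raises :class:`SpectraFormatError` with offending row numbers (1-based,
    counting the header as row 1) for duplicate keys or non-monotone
    frequency blocks.
    """
    path = Path(path)
    try:
        # round_trip parser: the default fast parser is not correctly rounded
        # and would break last-ulp equality of the dialect
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SpectraFormatError(f"{path}: empty spectra file") from None
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SpectraFormatError(f"{path}: no data rows")

    dup = df.duplicated(subset=["chip_id", "time_min", "frequency_hz"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise SpectraFormatError(
            f"{path}: duplicate (chip_id, time_min, frequency_hz) at rows {rows[:10]}"
        )
    for (chip, t), g in df.groupby(["chip_id", "time_min"], sort=False):
        freqs = g["frequency_hz"].to_numpy()
        if freqs.size > 1 and not np.all(np.diff(freqs) > 0):
            bad = int(g.index[np.argmin(np.diff(freqs))] + 3)
            raise SpectraFormatError(
                f"{path}: non-increasing frequencies for chip {chip!r} at "
                f"time {t} (near row {bad})"
            )
    return df


def dataset_to_table(dataset: TimelapseDataset, plate_id: str = "plate01") -> pd.DataFrame:
    """Flatten a simulated timelapse into the long spectra format."""
    frames = []
    for rec in dataset.records:
        g = rec.spectrum.grid.values
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "chip_id": rec.chip_id,
                    "time_min": rec.time_min,
                    "frequency_hz": g,
                    "z_real_ohm": rec.spectrum.z.real,
                    "z_imag_ohm": rec.spectrum.z.imag,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def table_to_spectra(df: pd.DataFrame) -> list[tuple[str, float, ImpedanceSpectrum]]:
    """Expand a validated spectra table into (chip_id, time_min, spectrum)."""
    out = []
    for (chip, t), g in df.groupby(["chip_id", "time_min"], sort=True):
        grid = FrequencyGrid(g["frequency_hz"].to_numpy())
        z = g["z_real_ohm"].to_numpy() + 1j * g["z_imag_ohm"].to_numpy()
        out.append((str(chip), float(t), ImpedanceSpectrum(grid=grid, z=z)))
    return out


def write_loads(loads, path: str | Path) -> None:
    pd.DataFrame(
        {
            "load_id": [f"board{i + 1}" for i in range(len(loads))],
            "resistance_ohm": np.asarray(loads, dtype=float),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_loads(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    if "resistance_ohm" not in df.columns:
        raise SpectraFormatError(f"{path}: missing column 'resistance_ohm'")
    return df["resistance_ohm"].to_numpy(dtype=float)


def compensation_set_from_tables(
    spectra: pd.DataFrame, loads: np.ndarray
) -> CompensationSet:
    """Assemble a CompensationSet from a board-spectra table and its sidecar.

    Board spectra use the chip_id column for the load id (board1, board2, …)
    in sidecar order, all at time_min = 0.
    """
    entries = table_to_spectra(spectra)
    by_id = {chip: spec for chip, _, spec in entries}
    specs = []
    for i in range(len(loads)):
        key = f"board{i + 1}"
        if key not in by_id:
            raise SpectraFormatError(f"board spectra missing entry {key!r}")
        specs.append(by_id[key])
    return CompensationSet(loads=np.asarray(loads, dtype=float), spectra=specs)


# --------------------------------------------------------------------------
# Run configuration


class GridConfig(BaseModel):
    f_min_hz: float = 1.0e3
    f_max_hz: float = 1.0e6
    n_points: int = 121

    def build(self) -> FrequencyGrid:
        return make_frequency_grid(self.f_min_hz, self.f_max_hz, self.n_points)


class CircuitConfig(BaseModel):
    r_series_ohm: float = 25_000.0
    r_barrier_ohm: float = 2_000.0
    q_cpe: float = 5.7e-9
    alpha: float = 0.95

    def build(self) -> ChipCircuitParams:
        return ChipCircuitParams(
            r_series=self.r_series_ohm,
            r_barrier=self.r_barrier_ohm,
            q_cpe=self.q_cpe,
            alpha=self.alpha,
        )


class ParasiticConfig(BaseModel):
    r_lead_ohm: float = 100.0
    c_par_farad: float = 10.0e-12

    def build(self) -> ParasiticParams:
        return ParasiticParams(r_lead=self.r_lead_ohm, c_par=self.c_par_farad)


class ScheduleConfig(BaseModel):
    baseline_time_min: float = -6.0
    fast_interval_min: float = 4.0
    fast_duration_min: float = 44.0
    slow_interval_min: float = 64.0
    slow_duration_min: float = 43.0 * 60.0
    endpoint_time_min: float = 46.0 * 60.0

    def build(self) -> MeasurementSchedule:
        return MeasurementSchedule(**self.model_dump())


class ConditionConfig(BaseModel):
    kind: str
    dose_ng_ml: float = 0.0
    n_chips: int = Field(ge=1)


class FitConfig(BaseModel):
    weighting: str = "modulus"
    multistart: int = 3
    max_iterations: int = 200
    tolerance: float = 1e-12

    def build(self, interface_area_cm2: float) -> FitOptions:
        return FitOptions(
            weighting=self.weighting,
            multistart=self.multistart,
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            interface_area_cm2=interface_area_cm2,
        )


class RunConfig(BaseModel):
    """Declarative description of a full in-silico TEER experiment."""

    seed: int = 0
    plate_id: str = "plate01"
    grid: GridConfig = GridConfig()
    loads_ohm: list[float] = [24_000.0, 30_000.0, 36_000.0]
    interface_area_cm2: float = DEFAULT_INTERFACE_AREA_CM2
    sigma_rel: float = 0.005
    board_sigma_rel: float = 0.0
    chip_cv: float = 0.10
    chip_base: CircuitConfig = CircuitConfig()
    parasitics: ParasiticConfig = ParasiticConfig()
    schedule: ScheduleConfig = ScheduleConfig()
    conditions: list[ConditionConfig] = [
        ConditionConfig(kind="control", dose_ng_ml=0.0, n_chips=64)
    ]
    fit: FitConfig = FitConfig()

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if len(self.loads_ohm) < 3 or len(set(self.loads_ohm)) != len(self.loads_ohm):
            raise ValueError("loads_ohm must contain >= 3 distinct values")
        if self.sigma_rel < 0 or self.board_sigma_rel < 0:
            raise ValueError("noise levels must be >= 0")
        total = sum(c.n_chips for c in self.conditions)
        if total < 1:
            raise ValueError("conditions must cover at least one chip")
        return self

    def build_layout(self) -> PlateLayout:
        """Layout sized to the configured conditions (64-chip default plate
        when the conditions fill it; otherwise a leading subset)."""
        total = sum(c.n_chips for c in self.conditions)
        full = default_plate_layout()
        if total > full.n_chips:
            raise ValueError(
                f"conditions require {total} chips; plate has {full.n_chips}"
            )
        if total == full.n_chips:
            return full
        return PlateLayout(
            n_chips=total,
            chips=full.chips[:total],
            electrodes_per_chip=full.electrodes_per_chip,
            wells_per_chip=full.wells_per_chip,
        )

    def build_condition_map(self) -> dict[str, tuple[str, float]]:
        layout = self.build_layout()
        cmap: dict[str, tuple[str, float]] = {}
        ids = iter(layout.chip_ids)
        for cond in self.conditions:
            for _ in range(cond.n_chips):
                cmap[next(ids)] = (cond.kind, cond.dose_ng_ml)
        return cmap

    def build_noise(self) -> NoiseModel:
        return NoiseModel(sigma_rel=self.sigma_rel, seed=self.seed)


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return RunConfig.model_validate(json.load(fh))


def example_config_path() -> Path:
    """Path of the packaged example config (a cytokine-panel experiment)."""
    return Path(__file__).parent / "data" / "example_config.json"
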