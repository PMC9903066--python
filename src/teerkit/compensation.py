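"""Multi-load compensation of parasitic measurement networks.

Long electrode paths into a 64-chip plate behave as a linear one-port error
network between the true chip impedance and what the analyzer reads; the
visible symptom is a loss of high-frequency signal from stray capacitance.
Any linear one-port distortion is a bilinear (fractional linear) map per
frequency,

.. math:: Z_m = \\frac{a Z + b}{c Z + 1},

with three complex unknowns ``(a, b, c)`` after fixing the denominator
constant to 1 to remove the gauge freedom.  Measuring three calibration
boards — the chip electrodes replaced by known resistors (default 24, 30 and
36 kΩ) — identifies the map exactly at every frequency; with more loads the
system is solved per frequency in the complex least-squares sense.  Inverting
the map on a chip spectrum removes the parasitics before circuit fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import FrequencyGrid, ImpedanceSpectrum

__all__ = [
    "DEFAULT_LOADS_OHM",
    "CompensationSet",
    "ErrorModel",
    "CalibrationRangeWarning",
    "estimate_error_model",
    "apply_compensation",
]

#: Reference-board resistances, Ω (E24 values bracketing typical chip impedance).
DEFAULT_LOADS_OHM = (24_000.0, 30_000.0, 36_000.0)


class CalibrationRangeWarning(UserWarning):
    """Compensated spectrum magnitude far outside the calibration load range."""


@dataclass
class CompensationSet:
    """Measured spectra of known resistive loads on a shared frequency grid."""

    loads: np.ndarray
    spectra: list[ImpedanceSpectrum]

    def __post_init__(self) -> None:
        loads = np.asarray(self.loads, dtype=float)
        if loads.ndim != 1 or loads.size < 3:
            raise ValueError("at least 3 calibration loads are required")
        if np.unique(loads).size != loads.size:
            raise ValueError("calibration loads must be pairwise distinct")
        if not np.all(loads > 0):
            raise ValueError("calibration loads must be positive")
        if len(self.spectra) != loads.size:
            raise ValueError("one spectrum per load is required")
        grid = self.spectra[0].grid
        for s in self.spectra[1:]:
            if s.grid != grid:
                raise ValueError("all compensation spectra must share one grid")
        self.loads = loads

    @property
    def grid(self) -> FrequencyGrid:
        return self.spectra[0].grid


@dataclass
class ErrorModel:
    """Per-frequency bilinear error coefficients ``Zm = (a·Z + b)/(c·Z + 1)``."""

    grid: FrequencyGrid
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name in ("a", "b", "c"):
            arr = np.asarray(getattr(self, name), dtype=complex)
            if arr.shape != (n,):
                raise ValueError(f"coefficient {name} must have shape ({n},)")
            setattr(self, name, arr)

    def forward(self, spectrum: ImpedanceSpectrum) -> ImpedanceSpectrum:
        """Apply the error map to a true spectrum (simulation/diagnostics)."""
        if spectrum.grid != self.grid:
            raise ValueError("spectrum grid does not match error-model grid")
        z = spectrum.z
        return ImpedanceSpectrum(
            grid=self.grid, z=(self.a * z + self.b) / (self.c * z + 1.0)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: frequency plus Re/Im of each coefficient."""
        return pd.DataFrame(
            {
                "frequency_hz": self.grid.values,
                "a_real": self.a.real,
                "a_imag": self.a.imag,
                "b_real": self.b.real,
                "b_imag": self.b.imag,
                "c_real": self.c.real,
                "c_imag": self.c.imag,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ErrorModel":
        grid = FrequencyGrid(df["frequency_hz"].to_numpy())
        return cls(
            grid=grid,
            a=df["a_real"].to_numpy() + 1j * df["a_imag"].to_numpy(),
            b=df["b_real"].to_numpy() + 1j * df["b_imag"].to_numpy(),
            c=df["c_real"].to_numpy() + 1j * df["c_imag"].to_numpy(),
        )


# Relative reciprocal condition number below which the per-frequency
# calibration system is treated as singular.
_RCOND_FLOOR = 1e-12


def _det3(m: np.ndarray) -> np.clongdouble:
    return (
        m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
        - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
        + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
    )


def _solve3_extended(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cramer's rule for a 3×3 complex system in extended precision."""
    a_l = a.astype(np.clongdouble)
    b_l = b.astype(np.clongdouble)
    det = _det3(a_l)
    out = np.empty(3, dtype=np.clongdouble)
    for j in range(3):
        m = a_l.copy()
        m[:, j] = b_l
        out[j] = _det3(m) / det
    return out.astype(complex)


def estimate_error_model(comp: CompensationSet) -> ErrorModel:
    """Identify the bilinear error model from known-load measurements.

    At each frequency the model gives, for load ``R_i`` with measured
    impedance ``M_i``, one complex linear equation

    ``a·R_i + b − M_i·c·R_i = M_i``.

    Three distinct loads determine ``(a, b, c)`` exactly; more loads are
    solved by complex least squares.  Frequencies at which the system is
    numerically singular raise ``ValueError``: a degenerate calibration set
    cannot be silently patched.
    """
    loads = comp.loads
    n_freq = len(comp.grid)
    m = np.stack([s.z for s in comp.spectra])  # (n_loads, n_freq)

    # Design tensor (n_freq, n_loads, 3): rows [R_i, 1, -M_i R_i]
    design = np.empty((n_freq, loads.size, 3), dtype=complex)
    design[:, :, 0] = loads[None, :]
    design[:, :, 1] = 1.0
    design[:, :, 2] = -(m.T * loads[None, :])
    rhs = m.T  # (n_freq, n_loads)

    coeffs = np.empty((n_freq, 3), dtype=complex)
    for k in range(n_freq):
        a_k = design[k]
        # column equilibration: columns (R, 1, -M·R) span many decades, which
        # would make a raw condition check reject well-posed systems
        col_scale = np.abs(a_k).max(axis=0)
        if np.any(col_scale == 0):
            raise ValueError(
                f"singular calibration system at frequency index {k} "
                f"({comp.grid.values[k]:.6g} Hz)"
            )
        a_scaled = a_k / col_scale[None, :]
        if loads.size == 3:
            if 1.0 / np.linalg.cond(a_scaled) < _RCOND_FLOOR:
                raise ValueError(
                    f"singular calibration system at frequency index {k} "
                    f"({comp.grid.values[k]:.6g} Hz)"
                )
            # extended-precision Cramer solve: nearly coincident loads make
            # identification ill-conditioned and double precision can lose
            # several digits of the coefficients
            sol = _solve3_extended(a_scaled, rhs[k])
        else:
            sol, _, rank, _ = np.linalg.lstsq(a_scaled, rhs[k], rcond=None)
            if rank < 3:
                raise ValueError(
                    f"rank-deficient calibration system at frequency index {k} "
                    f"({comp.grid.values[k]:.6g} Hz)"
                )
        coeffs[k] = sol / col_scale

    return ErrorModel(grid=comp.grid, a=coeffs[:, 0], b=coeffs[:, 1], c=coeffs[:, 2])


def apply_compensation(
    spectrum: ImpedanceSpectrum,
    model: ErrorModel,
    *,
    denominator_floor: float = 1e-9,
    range_warning_factor: float = 10.0,
    load_range: tuple[float, float] | None = None,
) -> ImpedanceSpectrum:
    """Invert the bilinear error map on a measured spectrum.

    Per frequency, ``Z = (b − Zm)/(Zm·c − a)``.  Points where the denominator
    magnitude falls below ``denominator_floor`` (relative to ``|a|``) are
    flagged invalid in the returned spectrum rather than producing wild
    values.

    The calibration is an interpolation: loads are chosen to bracket typical
    chip impedance.  When ``load_range`` is given and the median compensated
    magnitude lies more than ``range_warning_factor``× outside it, a
    :class:`CalibrationRangeWarning` is emitted.
    """
    if spectrum.grid != model.grid:
        raise ValueError("spectrum grid does not match error-model grid")
    zm = spectrum.z
    denom = zm * model.c - model.a
    floor = denominator_floor * np.maximum(np.abs(model.a), 1.0)
    bad = np.abs(denom) < floor
    safe_denom = np.where(bad, 1.0, denom)
    z = (model.b - zm) / safe_denom
    z = np.where(bad, 0.0, z)
    valid = spectrum.valid & ~bad

    if load_range is not None and valid.any():
        lo, hi = load_range
        med = float(np.median(np.abs(z[valid])))
        if med < lo / range_warning_factor or med > hi * range_warning_factor:
            warnings.warn(
                f"median compensated |Z| = {med:.3g} Ω lies far outside the "
                f"calibration load range [{lo:.3g}, {hi:.3g}] Ω; the "
                "compensation is extrapolating",
                CalibrationRangeWarning,
                stacklevel=2,
            )
    return ImpedanceSpectrum(grid=spectrum.grid, z=z, valid=valid)
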