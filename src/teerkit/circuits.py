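"""Equivalent-circuit models for microfluidic TEER chips.

A chip measured in a multi-lane microfluidic barrier plate behaves, to first
order, as a series resistance (culture medium plus channel path) in series
with the paracellular barrier: a barrier resistance in parallel with a
constant-phase element (CPE) representing the distributed capacitance of the
cell layer.  This is the minimal topology with a low-frequency plateau at
``r_series + r_barrier``, a high-frequency plateau at ``r_series`` and a
dispersive transition between them, which is what makes "barrier resistance"
a well-defined fitted parameter.

The measurement path adds parasitics: a series lead resistance and a parallel
stray capacitance.  That two-element network is the simplest one that
reproduces the characteristic loss of high-frequency signal in long electrode
paths, and it is exactly bilinear in the true impedance — the property the
three-load compensation in :mod:`teerkit.compensation` relies on.

Conventions: frequencies ``f`` in Hz, angular frequency ``ω = 2πf``,
impedances in Ω, CPE impedance ``1/(q·(jω)^α)`` with the principal branch of
the complex power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "ChipCircuitParams",
    "ParasiticParams",
    "ImpedanceSpectrum",
    "chip_impedance",
    "error_network_forward",
    "DEFAULT_F_MIN_HZ",
    "DEFAULT_F_MAX_HZ",
    "DEFAULT_N_POINTS",
]

#: Default acquisition sweep: 121 points log-spaced over 1 kHz – 1 MHz
#: (40 points per decade over three decades, endpoints included).
DEFAULT_F_MIN_HZ = 1.0e3
DEFAULT_F_MAX_HZ = 1.0e6
DEFAULT_N_POINTS = 121


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered acquisition frequencies in Hz (strictly increasing, positive)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(values > 0):
            raise ValueError("frequencies must be positive")
        if values.size > 1 and not np.all(np.diff(values) > 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def f_min(self) -> float:
        return float(self.values[0])

    @property
    def f_max(self) -> float:
        return float(self.values[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.values.tobytes())


@dataclass(frozen=True)
class ChipCircuitParams:
    """Analog-model parameters of one chip.

    Parameters
    ----------
    r_series:
        Series path resistance (medium + channels), Ω.  Strictly positive.
    r_barrier:
        Paracellular barrier resistance, Ω.  Non-negative; this is the
        parameter that, multiplied by the cell–matrix interface area, yields
        the TEER in Ω·cm².
    q_cpe:
        CPE magnitude, S·s^α.  Strictly positive.
    alpha:
        CPE exponent in (0, 1]; ``alpha == 1`` is an ideal capacitor.
    """

    r_series: float
    r_barrier: float
    q_cpe: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.r_series > 0:
            raise ValueError(f"r_series must be > 0, got {self.r_series}")
        if self.r_barrier < 0:
            raise ValueError(f"r_barrier must be >= 0, got {self.r_barrier}")
        if not self.q_cpe > 0:
            raise ValueError(f"q_cpe must be > 0, got {self.q_cpe}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


@dataclass(frozen=True)
class ParasiticParams:
    """Series lead resistance (Ω) and parallel stray capacitance (F)."""

    r_lead: float = 0.0
    c_par: float = 0.0

    def __post_init__(self) -> None:
        if self.r_lead < 0:
            raise ValueError(f"r_lead must be >= 0, got {self.r_lead}")
        if self.c_par < 0:
            raise ValueError(f"c_par must be >= 0, got {self.c_par}")


@dataclass
class ImpedanceSpectrum:
    """Complex impedance values on a frequency grid.

    ``valid`` marks per-frequency points usable downstream; compensation can
    flag points where its inverse map is ill-conditioned.
    """

    grid: FrequencyGrid
    z: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.shape != (len(self.grid),):
            raise ValueError(
                f"z has shape {z.shape}, expected ({len(self.grid)},)"
            )
        if not np.all(np.isfinite(z)):
            raise ValueError("impedance values must all be finite")
        self.z = z
        if self.valid is None:
            self.valid = np.ones(z.shape, dtype=bool)
        else:
            valid = np.asarray(self.valid, dtype=bool)
            if valid.shape != z.shape:
                raise ValueError("valid mask must match impedance shape")
            self.valid = valid

    def __len__(self) -> int:
        return len(self.grid)


def chip_impedance(params: ChipCircuitParams, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Impedance of ``r_series`` in series with ``r_barrier ∥ CPE``.

    .. math::

        Z(f) = R_s + \\frac{R_b}{1 + R_b\\, q\\,(j 2\\pi f)^{\\alpha}}

    The low-frequency limit is ``r_series + r_barrier`` and the
    high-frequency limit is ``r_series``; the real part is non-increasing in
    frequency for ``alpha <= 1``.
    """
    jw = 1j * 2.0 * np.pi * grid.values
    z = params.r_series + params.r_barrier / (
        1.0 + params.r_barrier * params.q_cpe * jw**params.alpha
    )
    return ImpedanceSpectrum(grid=grid, z=z)


def error_network_forward(
    parasitics: ParasiticParams, z_true: ImpedanceSpectrum
) -> ImpedanceSpectrum:
    """Distort a true spectrum through the parasitic one-port network.

    The measured impedance is ``Zm = r_lead + (Z ∥ Zc)`` with
    ``Zc = 1/(jωc_par)``; for ``c_par == 0`` this degenerates to
    ``Zm = r_lead + Z``.  The map is bilinear in ``Z``, i.e. of the form
    ``(A·Z + B)/(C·Z + 1)``, which is why three known loads identify it
    exactly (see :func:`teerkit.compensation.estimate_error_model`).
    """
    z = z_true.z
    if parasitics.c_par == 0.0:
        zm = parasitics.r_lead + z
    else:
        jwc = 1j * 2.0 * np.pi * z_true.grid.values * parasitics.c_par
        # Z ∥ Zc written as Z / (1 + jωC·Z) to stay finite for any Z
        zm = parasitics.r_lead + z / (1.0 + jwc * z)
    return ImpedanceSpectrum(grid=z_true.grid, z=zm, valid=z_true.valid.copy())
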