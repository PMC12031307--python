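"""Equivalent-circuit forward model for fruit bioimpedance spectra.

The circuit is a modified Hayden network: an electrode block (contact
resistance ``R_e`` in parallel with a constant-phase element ``CPE_e``)
in series with the tissue block (extracellular resistance ``R_ex`` in
parallel with the series combination of intracellular resistance ``R_i``
and the membrane constant-phase element ``CPE_m``).  A constant-phase
element (CPE) generalizes the capacitor,

    Z_CPE(omega) = 1 / (Q * (j * omega) ** alpha),

where ``Q`` is the non-ideal capacitance magnitude (s^alpha / Ohm) and
``alpha`` in [0, 1] is the ideality factor: ``alpha = 1`` is an ideal
capacitor, ``alpha = 0`` a pure resistor of value ``1/Q``.

All public interfaces take frequency ``f`` in Hz; the angular frequency
``omega = 2 * pi * f`` is formed internally.  Complex impedances are
plain (numpy) complex numbers; :func:`to_polar` converts to the
magnitude/phase representation used by impedance analyzers, with phase
in degrees, quadrant-correct, capacitive phase negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FrequencyGrid",
    "CPEParameters",
    "ECParameters",
    "SpectrumMetadata",
    "ImpedanceSpectrum",
    "EC_PARAMETER_NAMES",
    "cpe_impedance",
    "circuit_impedance",
    "to_polar",
    "from_polar",
    "simulate_spectrum",
    "DegenerateCircuitError",
]

#: Canonical ordering of the seven free circuit parameters.
EC_PARAMETER_NAMES = ("r_e", "q_e", "alpha_e", "r_ex", "r_i", "q_m", "alpha_m")

DEFAULT_N_FREQUENCIES = 30
DEFAULT_F_MIN_HZ = 50.0
DEFAULT_F_MAX_HZ = 1.0e6


class DegenerateCircuitError(ArithmeticError):
    """A parallel combination has a (numerically) zero denominator."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing measurement frequencies in Hz.

    The default grid is the 30-point logarithmic sweep from 50 Hz to
    1 MHz used for fruit spectroscopy.
    """

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D sequence")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def default(
        cls,
        n: int = DEFAULT_N_FREQUENCIES,
        f_min: float = DEFAULT_F_MIN_HZ,
        f_max: float = DEFAULT_F_MAX_HZ,
    ) -> "FrequencyGrid":
        """Log-spaced grid with *n* points from *f_min* to *f_max* (Hz)."""
        return cls(np.logspace(math.log10(f_min), math.log10(f_max), n))

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies ``2*pi*f`` in rad/s."""
        return 2.0 * math.pi * self.frequencies

    @property
    def is_log_spaced(self) -> bool:
        """True when consecutive ratios are constant to 1e-9 relative."""
        r = self.frequencies[1:] / self.frequencies[:-1]
        return bool(np.all(np.abs(r / r[0] - 1.0) < 1e-9))

    def __len__(self) -> int:
        return int(self.frequencies.size)


@dataclass(frozen=True)
class CPEParameters:
    """Constant-phase element: magnitude ``q`` > 0 and ``alpha`` in [0, 1]."""

    q: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.q > 0:
            raise ValueError(f"CPE magnitude q must be positive, got {self.q}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass(frozen=True)
class ECParameters:
    """The seven free parameters of the modified Hayden circuit.

    ``r_e``   electrode contact resistance (Ohm)
    ``cpe_e`` electrode constant-phase element
    ``r_ex``  extracellular resistance (Ohm)
    ``r_i``   intracellular resistance (Ohm)
    ``cpe_m`` membrane constant-phase element
    """

    r_e: float
    cpe_e: CPEParameters
    r_ex: float
    r_i: float
    cpe_m: CPEParameters

    def __post_init__(self) -> None:
        for name in ("r_e", "r_ex", "r_i"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def as_array(self) -> np.ndarray:
        """Flatten to the canonical 7-vector (:data:`EC_PARAMETER_NAMES`)."""
        return np.array(
            [
                self.r_e,
                self.cpe_e.q,
                self.cpe_e.alpha,
                self.r_ex,
                self.r_i,
                self.cpe_m.q,
                self.cpe_m.alpha,
            ]
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ECParameters":
        v = np.asarray(values, dtype=float)
        if v.shape != (7,):
            raise ValueError("expected exactly 7 parameter values")
        return cls(
            r_e=float(v[0]),
            cpe_e=CPEParameters(q=float(v[1]), alpha=float(v[2])),
            r_ex=float(v[3]),
            r_i=float(v[4]),
            cpe_m=CPEParameters(q=float(v[5]), alpha=float(v[6])),
        )

    def scaled(self, **factors: float) -> "ECParameters":
        """Return a copy with named parameters multiplied by given factors.

        Keys are entries of :data:`EC_PARAMETER_NAMES` (alpha factors are
        applied and then clipped to [0, 1]).
        """
        arr = self.as_array()
        for name, fac in factors.items():
            idx = EC_PARAMETER_NAMES.index(name)
            arr[idx] *= fac
        arr[2] = min(max(arr[2], 0.0), 1.0)
        arr[6] = min(max(arr[6], 0.0), 1.0)
        return ECParameters.from_array(arr)


@dataclass(frozen=True)
class SpectrumMetadata:
    """Per-measurement annotations: fruit id, day, group labels, diameter."""

    sample_id: str = ""
    day: int = 0
    size: str = ""
    storage: str = ""
    diameter_mm: float = float("nan")


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance at each grid frequency, plus metadata."""

    grid: FrequencyGrid
    values: np.ndarray
    metadata: SpectrumMetadata = field(default_factory=SpectrumMetadata)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"values length {v.shape} does not match grid length {len(self.grid)}"
            )
        if np.any(np.abs(v) <= 0):
            raise ValueError("impedance magnitudes must be positive")
        object.__setattr__(self, "values", v)

    @property
    def magnitude(self) -> np.ndarray:
        """|Z| in Ohm at each frequency."""
        return np.abs(self.values)

    @property
    def phase_deg(self) -> np.ndarray:
        """Quadrant-correct phase angle in degrees, in (-180, 180]."""
        return np.degrees(np.angle(self.values))

    def with_values(self, values: np.ndarray) -> "ImpedanceSpectrum":
        return replace(self, values=values)


def cpe_impedance(cpe: CPEParameters, omega) -> complex | np.ndarray:
    """Impedance of a constant-phase element at angular frequency *omega*.

    Evaluates ``1 / (Q * (j*omega)**alpha)`` with
    ``(j*omega)**alpha = omega**alpha * (cos(alpha*pi/2) + j*sin(alpha*pi/2))``,
    so the phase of the result is exactly ``-alpha * 90`` degrees.

    Parameters
    ----------
    cpe : CPEParameters
    omega : float or array
        Angular frequency in rad/s, strictly positive.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w <= 0):
        raise ValueError("omega must be strictly positive")
    half_pi_alpha = 0.5 * math.pi * cpe.alpha
    rot = complex(math.cos(half_pi_alpha), math.sin(half_pi_alpha))
    out = 1.0 / (cpe.q * np.power(w, cpe.alpha) * rot)
    if np.isscalar(omega):
        return complex(out)
    return out


def _parallel(a, b):
    """Complex parallel combination a*b/(a+b); rejects zero denominators."""
    denom = a + b
    if np.any(np.abs(denom) == 0):
        raise DegenerateCircuitError("parallel combination has zero denominator")
    return a * b / denom


def circuit_impedance(
    params: ECParameters,
    omega,
    topology: str = "parallel_electrode",
) -> complex | np.ndarray:
    """Total impedance of the modified Hayden circuit at *omega* (rad/s).

    Default topology (``"parallel_electrode"``)::

        Z(w) = [R_e || Z_CPE_e(w)] + [R_ex || (R_i + Z_CPE_m(w))]

    where ``a || b = a*b/(a+b)`` over complex values.  The alternative
    ``"series_electrode"`` wiring places the electrode elements in
    series: ``Z = R_e + Z_CPE_e + [R_ex || (R_i + Z_CPE_m)]``.

    Limits for ideal CPEs (alpha = 1): the CPE impedances diverge as
    omega -> 0, so Z -> R_e + R_ex; they vanish as omega -> inf, so
    Z -> R_ex*R_i/(R_ex + R_i).
    """
    z_e = cpe_impedance(params.cpe_e, omega)
    z_m = cpe_impedance(params.cpe_m, omega)
    tissue = _parallel(params.r_ex, params.r_i + z_m)
    if topology == "parallel_electrode":
        electrode = _parallel(params.r_e, z_e)
    elif topology == "series_electrode":
        electrode = params.r_e + z_e
    else:
        raise ValueError(f"unknown topology {topology!r}")
    total = electrode + tissue
    if np.isscalar(omega):
        return complex(total)
    return total


def to_polar(z) -> tuple:
    """Convert complex impedance to (|Z| in Ohm, phase in degrees).

    Phase is computed with the quadrant-correct arctangent and lies in
    (-180, 180].  A zero vector has no defined phase and raises.
    """
    z = np.asarray(z, dtype=complex)
    if np.any(z == 0):
        raise ValueError("phase undefined for zero impedance")
    return np.abs(z), np.degrees(np.angle(z))


def from_polar(magnitude, phase_deg) -> np.ndarray:
    """Inverse of :func:`to_polar`: rebuild z = |Z| * exp(j*theta)."""
    mag = np.asarray(magnitude, dtype=float)
    ph = np.radians(np.asarray(phase_deg, dtype=float))
    return mag * (np.cos(ph) + 1j * np.sin(ph))


def simulate_spectrum(
    params: ECParameters,
    grid: Optional[FrequencyGrid] = None,
    metadata: Optional[SpectrumMetadata] = None,
    topology: str = "parallel_electrode",
) -> ImpedanceSpectrum:
    """Evaluate the circuit at every grid frequency (deterministic)."""
    if grid is None:
        grid = FrequencyGrid.default()
    values = circuit_impedance(params, grid.omega, topology=topology)
    return ImpedanceSpectrum(
        grid=grid,
        values=values,
        metadata=metadata if metadata is not None else SpectrumMetadata(),
    )
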