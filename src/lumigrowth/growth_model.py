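"""Two-compartment proliferative/necrotic tumor growth model.

The tumor is modeled as a proliferative compartment ``P`` (living,
light-emitting cells following logistic growth) and a necrotic compartment
``N`` fed by the cells that lose the competition for space and nutrients::

    dP/dt = a * P * (1 - P/K),    P(0) = P0
    dN/dt = a * P**2 / K,         N(0) = 0

``P`` is expressed in bioluminescence units (photons/sec), since the light
signal is proportional to the number of viable cells.  The total volume
signal is ``V = P + N``: necrotic tissue no longer emits light but still
occupies volume.  Because ``dV/dt = a*P -> a*K``, the total volume grows
exponentially at first and then linearly — the biphasic pattern seen in
caliper data.

Both equations admit closed forms (validated here against adaptive numerical
integration):

    P(t) = K / (1 + (K/P0 - 1) * exp(-a t))
    N(t) = K * log(1 + (P0/K) * (exp(a t) - 1)) - P(t) + P0

All closed forms are evaluated in log-domain rearrangements so that extreme
parameter proposals during population fitting (``a*t`` in the hundreds) never
overflow.

Unit conversions: a cells-to-light ratio (photons/sec per cell, 88.4 in the
calibrated default) and the approximation 1 cm^3 = 1e9 cells turn signal into
cell-mass volume; a dimensionless proportionality constant ``lambda`` maps
cell-mass volume to caliper-measured volume, its excess over 1 being
interpreted as the stromal (non-tumor-cell) fraction of the tumor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "Trajectory",
    "ConversionConstants",
    "proliferative_signal",
    "necrotic_signal",
    "total_signal",
    "simulate_ode",
    "signal_to_volume_cm3",
    "volume_cm3_to_signal",
    "predicted_caliper_volume",
    "stroma_fraction",
    "carlsson_volume",
    "DEFAULT_PHOTONS_PER_CELL",
    "DEFAULT_CELLS_PER_CM3",
]

#: Cells-to-light ratio established by the calibration-plate regression.
DEFAULT_PHOTONS_PER_CELL = 88.4
#: Packing rule: one cubic centimeter holds about 1e9 cells.
DEFAULT_CELLS_PER_CM3 = 1e9


@dataclass(frozen=True)
class ModelParameters:
    """Structural parameters of one animal.

    Parameters
    ----------
    a : float
        Proliferation rate, day^-1. Strictly positive.
    K : float
        Carrying capacity of the proliferative compartment, photons/sec.
    P0 : float
        Initial proliferative signal (injected cells converted to
        photons/sec). Must satisfy ``P0 < K``.
    lam : float
        Caliper-to-cell-mass volume proportionality constant
        (dimensionless, >= 1 in the physical regime; > 0 accepted).
    """

    a: float
    K: float
    P0: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "K", "P0", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.P0 >= self.K:
            raise ValueError(
                f"P0 must be below the carrying capacity K (P0={self.P0!r}, K={self.K!r})"
            )

    @property
    def cell_cycle_days(self) -> float:
        """Cell-cycle length implied by ``a`` under the reading tau = ln2/a.

        This is an interpretation of the proliferation rate as a doubling
        time, exposed for convenience; ``a`` is the primitive parameter.
        """
        return float(np.log(2.0) / self.a)


@dataclass(frozen=True)
class ConversionConstants:
    """Constants converting bioluminescence signal to cell-mass volume."""

    photons_per_cell: float = DEFAULT_PHOTONS_PER_CELL
    cells_per_cm3: float = DEFAULT_CELLS_PER_CM3

    def __post_init__(self) -> None:
        if self.photons_per_cell <= 0 or self.cells_per_cm3 <= 0:
            raise ValueError("conversion constants must be > 0")


@dataclass(frozen=True)
class Trajectory:
    """Simulated (t, P, N, V) curve in signal units.

    ``V = P + N`` elementwise; ``N`` is non-decreasing and starts at 0 when
    the grid starts at the injection day.
    """

    times: np.ndarray
    P: np.ndarray
    N: np.ndarray
    V: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        P = np.asarray(self.P, dtype=float)
        N = np.asarray(self.N, dtype=float)
        if self.V is None:
            object.__setattr__(self, "V", P + N)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "N", N)
        if not (len(t) == len(P) == len(N) == len(self.V)):
            raise ValueError("times, P, N, V must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative (days post-graft)")
    return t


def proliferative_signal(t, params: ModelParameters):
    """Logistic proliferative signal P(t), photons/sec.

    Evaluated as ``K / (1 + (K/P0 - 1) * exp(-a t))``, which cannot overflow
    for any non-negative ``a*t`` (the naive ``exp(a t)`` form fails past
    ``a*t ~ 700``).
    """
    t = _check_times(t)
    ratio = params.K / params.P0 - 1.0
    out = params.K / (1.0 + ratio * np.exp(-params.a * t))
    return out if out.shape else float(out)


def necrotic_signal(t, params: ModelParameters):
    """Necrotic signal-equivalent N(t), photons/sec.

    Closed form ``K * log(1 + (P0/K)(e^{at} - 1)) - P(t) + P0``, computed as
    ``K * logaddexp(log(1 - P0/K), log(P0/K) + a t)`` so that large ``a*t``
    stays in the log domain.  N(0) = 0 and N is non-decreasing.
    """
    t = _check_times(t)
    r = params.P0 / params.K
    # log(1 + r*(e^{at} - 1)) = log((1-r) + r e^{at})
    log_term = np.logaddexp(np.log1p(-r), np.log(r) + params.a * t)
    P = params.K / (1.0 + (1.0 / r - 1.0) * np.exp(-params.a * t))
    out = params.K * log_term - P + params.P0
    out = np.maximum(out, 0.0)  # guards tiny negative round-off near t=0
    return out if out.shape else float(out)


def total_signal(t, params: ModelParameters):
    """Total signal-equivalent volume V(t) = P(t) + N(t), photons/sec.

    Grows exponentially while P << K, then linearly with asymptotic slope
    ``a*K`` once the proliferative compartment saturates.
    """
    return proliferative_signal(t, params) + necrotic_signal(t, params)


def simulate_ode(params: ModelParameters, times, rtol: float = 1e-10) -> Trajectory:
    """Adaptive-step numerical integration of the two-compartment system.

    Serves as the numerical oracle for the closed forms; agreement is at
    relative tolerance 1e-6 or better over the biologically relevant ranges.
    Integration always starts at the injection day (t = 0) from (P0, 0).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly ascending")
    if times[0] < 0:
        raise ValueError("times must start at or after the injection day (t >= 0)")

    a, K = params.a, params.K

    def rhs(_t, y):
        P = y[0]
        return [a * P * (1.0 - P / K), a * P * P / K]

    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1e-9)
    sol = solve_ivp(
        rhs,
        t_span,
        [params.P0, 0.0],
        t_eval=np.maximum(times, 0.0),
        method="LSODA",
        rtol=rtol,
        atol=[params.P0 * 1e-12, params.K * 1e-12],
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Trajectory(times=times, P=sol.y[0], N=np.maximum(sol.y[1], 0.0))


def signal_to_volume_cm3(signal, conv: ConversionConstants = ConversionConstants()):
    """Convert a bioluminescence signal (photons/sec) to cell-mass volume (cm^3)."""
    signal = np.asarray(signal, dtype=float)
    if np.any(signal < 0):
        raise ValueError("signal must be non-negative")
    out = signal / conv.photons_per_cell / conv.cells_per_cm3
    return out if out.shape else float(out)


def volume_cm3_to_signal(volume, conv: ConversionConstants = ConversionConstants()):
    """Inverse of :func:`signal_to_volume_cm3` (exact round-trip)."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise ValueError("volume must be non-negative")
    out = volume * conv.photons_per_cell * conv.cells_per_cm3
    return out if out.shape else float(out)


def predicted_caliper_volume(
    t, params: ModelParameters, conv: ConversionConstants = ConversionConstants()
):
    """Model-predicted caliper volume, cm^3: ``lam * (P + N) / conversion``."""
    return params.lam * signal_to_volume_cm3(total_signal(t, params), conv)


def stroma_fraction(lam: float) -> float:
    """Stromal percentage of the total volume implied by ``lambda``.

    A caliper volume ``lam`` times larger than the cell-mass volume means a
    fraction ``1 - 1/lam`` of the tumor is not tumor cells: returns
    ``100 * (1 - 1/lam)`` percent.  ``lam < 1`` (volume below cell mass) is
    unphysical under this model and raises.
    """
    if not np.isfinite(lam) or lam < 1.0:
        raise ValueError(f"lambda must be >= 1 for a stroma interpretation, got {lam!r}")
    return 100.0 * (1.0 - 1.0 / lam)


def growth_phase_transitions(
    params: ModelParameters,
    t_min: float = 0.25,
    t_max: float = 43.0,
    n: int = 800,
    tol: float = 1e-9,
) -> int:
    """Count sign changes of the log-log curvature of the total volume.

    The total volume grows exponentially and then linearly.  On log-log
    axes, exponential growth is convex (curvature d^2 log V / d (log t)^2
    positive) and linear growth concave, so the biphasic pattern shows up
    as exactly one sign change of this curvature.  (The curvature of log V
    in plain time is negative throughout and does not discriminate the two
    phases.)  Curvature values below ``tol`` are treated as zero.
    """
    u = np.linspace(np.log(t_min), np.log(t_max), n)
    w = np.log(total_signal(np.exp(u), params))
    curv = np.diff(w, 2) / (u[1] - u[0]) ** 2
    s = np.sign(curv[np.abs(curv) > tol])
    return int(np.sum(np.diff(s) != 0))


def carlsson_volume(length: float, width: float) -> float:
    """Caliper tumor volume by the Carlsson formula, V = length * width^2 / 2 (cm^3).

    Caliper operators record the two axes inconsistently; if ``width`` exceeds
    ``length`` the arguments are swapped with a warning instead of erroring.
    """
    if length <= 0 or width <= 0:
        raise ValueError("caliper dimensions must be > 0")
    if width > length:
        warnings.warn(
            f"width ({width}) exceeds length ({length}); swapping axes",
            stacklevel=2,
        )
        length, width = width, length
    return length * width * width / 2.0
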