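"""Closed-form mathematics of the dynamic van der Pol temperature model.

The circadian component of a tail skin temperature trace is modelled as a
weakly nonlinear oscillator with a stable limit cycle.  Instead of
integrating the oscillator numerically, fitting works with its second-order
perturbation solution

    x(t) = a(t) cos(wt + psi) - eps * a(t)^3 / (8 gamma^2) * sin(3wt + 3psi)

whose envelope is the closed-form dynamic amplitude

    a(t) = [ (1/(4k)) e^{-eps w t} + 1/gamma^2 ]^{-1/2},

interpolating from the start amplitude ``a0 = a(0)`` toward the limit-cycle
amplitude ``gamma`` at a pace set by the flexibility ``eps`` and the angular
frequency ``w = 2 pi / tau``.  An affine trend c(t) = c0 + c1 t carries the
baseline, and observation noise is independent Gaussian with one variance
per daily regime (morning / afternoon / night).

Everything in this module is pure, vectorised math; simulation, fitting and
inference build on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TAU_DEFAULT",
    "N_PARAMETERS",
    "REGIME_LABELS",
    "VanDerPolParams",
    "TrendParams",
    "NoiseParams",
    "VarianceSchedule",
    "FullModelParams",
    "integration_constant",
    "amplitude_at",
    "amplitude_derivative",
    "circadian_component",
    "circadian_derivative",
    "trend_at",
    "model_mean",
]

#: Circadian period (hours) imposed by the 12:12 light-dark schedule.
TAU_DEFAULT = 24.0

#: Scalar parameters of the full observation model:
#: (a0, gamma, eps, psi, tau) + (c0, c1) + three regime variances.
N_PARAMETERS = 10

#: Daily noise regimes, in code order 0, 1, 2.
REGIME_LABELS = ("day1", "day2", "night")

_PI = math.pi


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class VanDerPolParams:
    """Oscillator parameter vector (a0, gamma, eps, psi, tau).

    Parameters
    ----------
    a0 : float
        Start amplitude a(0) in degrees Celsius.
    gamma : float
        Limit-cycle amplitude in degrees Celsius; the asymptote of a(t).
    epsilon : float
        Dimensionless flexibility; 0 gives a pure harmonic oscillator,
        larger values approach the limit cycle faster.  Fitting confines
        it to [0.2, 1]; simulation allows any nonnegative value.
    psi : float
        Angular phase shift in radians, in [-pi, pi].
    tau : float
        Period in hours (fixed to 24 during fitting).
    """

    a0: float
    gamma: float
    epsilon: float
    psi: float = 0.0
    tau: float = TAU_DEFAULT

    def __post_init__(self) -> None:
        _require_positive("a0", self.a0)
        _require_positive("gamma", self.gamma)
        _require_positive("tau", self.tau)
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be nonnegative, got {self.epsilon!r}")
        if not (-_PI - 1e-9 <= self.psi <= _PI + 1e-9):
            raise ValueError(f"psi must lie in [-pi, pi], got {self.psi!r}")

    @property
    def omega(self) -> float:
        """Angular frequency 2*pi/tau in radians per hour."""
        return 2.0 * _PI / self.tau

    @property
    def k(self) -> float:
        """Integration constant of the amplitude solution (inf if a0 == gamma)."""
        return integration_constant(self.a0, self.gamma)


@dataclass(frozen=True)
class TrendParams:
    """Affine baseline c(t) = c0 + c1*t with t in hours and c0 > 0 (deg C)."""

    c0: float
    c1: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("c0", self.c0)


@dataclass(frozen=True)
class NoiseParams:
    """Observation-noise variances (deg C squared) for the three daily regimes.

    Zero variances are tolerated so the noiseless simulation limit is exact;
    likelihood evaluation requires all three to be strictly positive.
    """

    var_day1: float
    var_day2: float
    var_night: float

    def __post_init__(self) -> None:
        for name in ("var_day1", "var_day2", "var_night"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def as_array(self) -> np.ndarray:
        """Variances in regime-code order (day1, day2, night)."""
        return np.array([self.var_day1, self.var_day2, self.var_night])


@dataclass(frozen=True)
class VarianceSchedule:
    """Partition of the 24 h day into the three noise regimes.

    Default boundaries follow the husbandry schedule: morning (lights on,
    husbandry and dosing disturbances) 06:00-12:00, quiet afternoon
    12:00-18:00, active night 18:00-06:00.  Intervals are half-open,
    left-closed, so every clock time maps to exactly one regime.
    """

    day1_start: float = 6.0
    day2_start: float = 12.0
    night_start: float = 18.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.day1_start < self.day2_start < self.night_start < 24.0):
            raise ValueError("regime boundaries must satisfy 0 <= day1 < day2 < night < 24")

    def regime_codes(self, clock_hours) -> np.ndarray:
        """Map clock times (hours in [0, 24)) to regime codes 0/1/2."""
        h = np.asarray(clock_hours, dtype=float) % 24.0
        codes = np.full(h.shape, 2, dtype=np.intp)
        codes[(h >= self.day1_start) & (h < self.day2_start)] = 0
        codes[(h >= self.day2_start) & (h < self.night_start)] = 1
        return codes

    def regime_of(self, clock_hour: float) -> str:
        """Regime label ('day1' | 'day2' | 'night') for one clock time."""
        return REGIME_LABELS[int(self.regime_codes(clock_hour))]


@dataclass(frozen=True)
class FullModelParams:
    """All ten scalar parameters of the observation model."""

    vdp: VanDerPolParams
    trend: TrendParams
    noise: NoiseParams


def integration_constant(a0: float, gamma: float) -> float:
    """Integration constant k of the amplitude solution.

    Defined through 1/(4k) = 1/a0^2 - 1/gamma^2, so k > 0 iff the amplitude
    grows (a0 < gamma) and k < 0 iff it decays.  When a0 == gamma the right
    side vanishes and ``math.inf`` is returned as a sentinel: the amplitude
    is constant and k plays no role.
    """
    _require_positive("a0", a0)
    _require_positive("gamma", gamma)
    inv4k = a0 ** -2 - gamma ** -2
    if inv4k == 0.0:
        return math.inf
    return 0.25 / inv4k


def amplitude_at(t, params: VanDerPolParams):
    """Dynamic amplitude a(t) in deg C at time t (hours since phase start).

    Evaluates [ (1/a0^2 - 1/gamma^2) e^{-eps w t} + 1/gamma^2 ]^{-1/2},
    which equals a0 at t=0 and tends monotonically to gamma.  Accepts a
    scalar or array of nonnegative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    inv4k = params.a0 ** -2 - params.gamma ** -2
    val = inv4k * np.exp(-params.epsilon * params.omega * t_arr) + params.gamma ** -2
    out = val ** -0.5
    return float(out) if out.ndim == 0 else out


def amplitude_derivative(t, params: VanDerPolParams):
    """Exact time derivative of :func:`amplitude_at`.

    Differentiating the closed form gives da/dt = eps*w*a/2 * (1 - a^2/gamma^2),
    i.e. the amplitude obeys its defining ODE exactly (the O(eps^2) error of the
    perturbation expansion lives in the oscillation, not in this envelope).
    """
    a = amplitude_at(t, params)
    return 0.5 * params.epsilon * params.omega * a * (1.0 - a ** 2 / params.gamma ** 2)


def circadian_component(t, params: VanDerPolParams, dynamic_amplitude: bool = True):
    """Second-order perturbation solution x(t) of the oscillator, in deg C.

    ``dynamic_amplitude=False`` freezes the leading amplitude at a0
    (the literal constant-amplitude reading of the first term); the default
    uses a(t) in both terms.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    a = amplitude_at(t_arr, params) if dynamic_amplitude else params.a0
    theta = params.omega * t_arr + params.psi
    out = a * np.cos(theta) - (
        params.epsilon * np.asarray(a) ** 3 / (8.0 * params.gamma ** 2)
    ) * np.sin(3.0 * theta)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def circadian_derivative(t, params: VanDerPolParams):
    """Analytic dx/dt of the perturbation solution (for ODE cross-checks)."""
    t_arr = np.asarray(t, dtype=float)
    a = np.asarray(amplitude_at(t_arr, params))
    da = np.asarray(amplitude_derivative(t_arr, params))
    w = params.omega
    theta = w * t_arr + params.psi
    coef = params.epsilon / (8.0 * params.gamma ** 2)
    out = (
        da * np.cos(theta)
        - a * w * np.sin(theta)
        - coef * (3.0 * a ** 2 * da * np.sin(3.0 * theta) + 3.0 * w * a ** 3 * np.cos(3.0 * theta))
    )
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def trend_at(t, trend: TrendParams):
    """Baseline c(t) = c0 + c1*t (t in hours), in deg C."""
    out = np.asarray(trend.c0 + trend.c1 * np.asarray(t, dtype=float))
    return float(out) if out.ndim == 0 else out


def model_mean(t, params: FullModelParams, dynamic_amplitude: bool = True):
    """Noiseless expectation of an observation: circadian component + trend."""
    return circadian_component(t, params.vdp, dynamic_amplitude) + trend_at(t, params.trend)
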