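"""Pseudo-maximum-likelihood fitting of one animal-phase series.

The ten-parameter observation model is not optimised jointly.  Following the
pseudo-ML scheme: the affine trend is fixed first by ordinary least squares;
the period tau is pinned to 24 h by the imposed light-dark cycle; the three
regime variances are profiled from the current residuals at every objective
evaluation; and only the four oscillator parameters (a0, gamma, eps, psi)
are optimised by bounded quasi-Newton (L-BFGS-B).

Box constraints: eps in [0.2, 1] — the lower bound prevents degenerate fits
in which an enormous limit-cycle amplitude is masked by a vanishing
flexibility, the upper bound keeps the perturbation solution close to the
true oscillator; psi in [-pi, pi]; the upper bounds for a0 and gamma are
half the span of the raw temperatures over the first and last day of the
phase.  Start values come from one-day harmonic (cosinor) regressions,
except a0 = 0.5 in phase P1 where post-surgery transients make the first
day unreliable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import (
    REGIME_LABELS,
    FullModelParams,
    NoiseParams,
    TrendParams,
    VanDerPolParams,
    VarianceSchedule,
    amplitude_at,
    circadian_component,
    model_mean,
    trend_at,
)
from .simulate import TemperatureSeries

__all__ = [
    "FitConfig",
    "PhaseFit",
    "HarmonicFit",
    "fit_trend",
    "harmonic_init",
    "negative_log_likelihood",
    "profile_variances",
    "compute_bounds",
    "fit_phase",
    "aic",
    "residual_acf",
    "harmonic_reference_fit",
]

_PI = math.pi


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the pseudo-ML fit (defaults follow the study protocol)."""

    tau_fixed: float = 24.0
    epsilon_bounds: tuple = (0.2, 1.0)
    psi_bounds: tuple = (-_PI, _PI)
    a0_init_p1: float = 0.5
    epsilon_init: float = 0.5
    amplitude_lower: float = 0.05
    variance_floor: float = 1e-6
    ftol: float = 1e-8
    maxiter: int = 500
    #: "per_eval" re-profiles variances inside every objective evaluation
    #: (profile likelihood); "outer" alternates optimisation with re-profiling.
    profile_mode: str = "per_eval"
    max_outer: int = 20
    #: Free parameters counted in the AIC: 4 optimised + 2 trend + 3 variances
    #: (tau is fixed).  Set to 10 to count every model parameter instead.
    n_free_params: int = 9

    def __post_init__(self) -> None:
        if self.epsilon_bounds[0] >= self.epsilon_bounds[1]:
            raise ValueError("epsilon bounds must be ordered")
        if self.psi_bounds[0] >= self.psi_bounds[1]:
            raise ValueError("psi bounds must be ordered")
        if self.ftol <= 0 or self.variance_floor <= 0:
            raise ValueError("tolerances must be positive")
        if self.profile_mode not in ("per_eval", "outer"):
            raise ValueError("profile_mode must be 'per_eval' or 'outer'")


@dataclass
class PhaseFit:
    """Result of fitting one animal-phase series."""

    animal_id: str
    group: str
    phase: str
    params: FullModelParams
    negloglik: float
    aic: float
    a_at_T: float
    duration_hours: float
    n_obs: int
    converged: bool
    bounds: dict
    initial: dict
    n_free_params: int
    residuals: np.ndarray
    regime_codes: np.ndarray
    time_unit: str = "hours"

    def residuals_by_regime(self) -> dict:
        return {
            label: self.residuals[self.regime_codes == code]
            for code, label in enumerate(REGIME_LABELS)
        }


def fit_trend(series: TemperatureSeries) -> TrendParams:
    """OLS affine trend of temperature on hours since phase start.

    The estimated (c0, c1) stay fixed during the oscillator optimisation.
    """
    t = series.time_hours
    if series.n < 2 or np.ptp(t) == 0:
        raise ValueError("trend fit needs >= 2 samples spanning distinct times")
    slope, intercept = np.polyfit(t, series.temperature, 1)
    return TrendParams(c0=float(intercept), c1=float(slope))


def harmonic_init(t_hours, values, tau: float = 24.0) -> tuple:
    """Cosinor start values (amplitude, psi) from one day of detrended data.

    Least-squares fit of A1*cos(wt) + A2*sin(wt); the implied start values
    are amplitude sqrt(A1^2 + A2^2) and phase -atan2(A2, A1), so that
    A1 cos + A2 sin == amplitude * cos(wt + psi).
    """
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t_hours and values must be matching 1-D arrays")
    if t.size < 4:
        raise ValueError("harmonic window needs at least 4 samples")
    step = float(np.median(np.diff(t)))
    if (t[-1] - t[0]) + step < tau - 1e-9:
        raise ValueError("harmonic window must span at least one full period")
    w = 2.0 * _PI / tau
    design = np.column_stack([np.cos(w * t), np.sin(w * t)])
    (a1, a2), *_ = np.linalg.lstsq(design, y, rcond=None)
    amplitude = float(math.hypot(a1, a2))
    psi = float(-math.atan2(a2, a1))
    return amplitude, psi


def profile_variances(
    residuals, regime_codes, floor: float = 1e-6
) -> NoiseParams:
    """ML (divisor n) per-regime variances of residuals, floored at ``floor``.

    ``regime_codes`` assigns each residual to day1/day2/night (codes 0/1/2,
    from :meth:`VarianceSchedule.regime_codes` on the sample clock times).
    """
    r = np.asarray(residuals, dtype=float)
    codes = np.asarray(regime_codes)
    if r.shape != codes.shape:
        raise ValueError("residuals and regime_codes must align")
    out = []
    for code, label in enumerate(REGIME_LABELS):
        sub = r[codes == code]
        if sub.size == 0:
            raise ValueError(f"no residuals fall in regime {label!r}")
        out.append(max(float(np.mean(sub ** 2)), floor))
    return NoiseParams(*out)


def negative_log_likelihood(
    series: TemperatureSeries,
    params: FullModelParams,
    schedule: VarianceSchedule | None = None,
) -> float:
    """Gaussian negative log-likelihood with diagonal, regime-wise covariance.

    Equals N/2 log(2 pi) + 1/2 sum_n log sigma^2(n) + 1/2 sum_n r_n^2/sigma^2(n)
    with r_n the residual about the model mean and sigma^2(n) the variance of
    the regime containing sample n — the dense multivariate-normal density
    specialised to a diagonal covariance.
    """
    if schedule is None:
        schedule = VarianceSchedule()
    var = params.noise.as_array()
    if np.any(var <= 0):
        raise ValueError("likelihood requires strictly positive variances")
    r = series.temperature - model_mean(series.time_hours, params)
    v = var[schedule.regime_codes(series.clock_hours)]
    n = series.n
    return float(0.5 * (n * math.log(2.0 * _PI) + np.sum(np.log(v)) + np.sum(r * r / v)))


def compute_bounds(series: TemperatureSeries) -> tuple:
    """(a0_upper, gamma_upper): half the raw span of the first and last day."""
    t = series.time_hours
    total = series.duration_hours
    if total < 24.0 - 1e-9:
        raise ValueError("bounds need at least one full day of data")
    first = series.temperature[t < 24.0]
    last = series.temperature[t >= total - 24.0]
    return float(np.ptp(first) / 2.0), float(np.ptp(last) / 2.0)


def _profiled_nll(r: np.ndarray, codes: np.ndarray, counts: np.ndarray, floor: float) -> float:
    """NLL with variances profiled from the current residuals (vectorised)."""
    ss = np.bincount(codes, weights=r * r, minlength=3)
    v = np.maximum(ss / counts, floor)
    n = r.size
    return float(
        0.5 * (n * math.log(2.0 * _PI) + np.sum(counts * np.log(v)) + np.sum(ss / v))
    )


def _fixed_var_nll(r: np.ndarray, codes: np.ndarray, counts: np.ndarray, var: np.ndarray) -> float:
    ss = np.bincount(codes, weights=r * r, minlength=3)
    n = r.size
    return float(
        0.5 * (n * math.log(2.0 * _PI) + np.sum(counts * np.log(var)) + np.sum(ss / var))
    )


def fit_phase(
    series: TemperatureSeries,
    config: FitConfig | None = None,
    phase_label: str | None = None,
    schedule: VarianceSchedule | None = None,
) -> PhaseFit:
    """Pseudo-ML fit of the full model to one animal-phase series.

    Steps: (1) fix the trend by OLS; (2) fix tau; (3) optimise
    (a0, gamma, eps, psi) by L-BFGS-B within their boxes, profiling the three
    regime variances from the residuals at every objective evaluation;
    (4) report the fit with its NLL, AIC and end-of-phase amplitude a(T).
    Start values come from first/last-day cosinor regressions (a0 forced to
    0.5 when the phase is P1).
    """
    if config is None:
        config = FitConfig()
    if schedule is None:
        schedule = VarianceSchedule()
    if phase_label is None:
        phase_label = series.phase

    trend = fit_trend(series)
    t = series.time_hours
    y_detr = series.temperature - trend_at(t, trend)
    codes = schedule.regime_codes(series.clock_hours)
    counts = np.bincount(codes, minlength=3).astype(float)
    if np.any(counts == 0):
        missing = REGIME_LABELS[int(np.argmin(counts))]
        raise ValueError(f"series has no samples in regime {missing!r}")

    a0_up, gamma_up = compute_bounds(series)
    lo = config.amplitude_lower
    if a0_up <= lo or gamma_up <= lo:
        raise ValueError(
            "degenerate series: first/last-day span gives amplitude upper bound "
            f"({a0_up:.3g}, {gamma_up:.3g}) at or below the lower bound {lo}"
        )

    total = series.duration_hours
    first = t < 24.0
    last = t >= total - 24.0
    a0_h, psi_h = harmonic_init(t[first], y_detr[first], config.tau_fixed)
    gamma_h, _ = harmonic_init(t[last], y_detr[last], config.tau_fixed)

    a0_init = config.a0_init_p1 if phase_label == "P1" else a0_h
    box = [
        (lo, a0_up),
        (lo, gamma_up),
        config.epsilon_bounds,
        config.psi_bounds,
    ]
    x0 = np.array(
        [
            np.clip(a0_init, *box[0]),
            np.clip(gamma_h, *box[1]),
            np.clip(config.epsilon_init, *box[2]),
            np.clip(psi_h, *box[3]),
        ]
    )

    omega = 2.0 * _PI / config.tau_fixed
    coef_t = omega * t

    def residuals_for(theta: np.ndarray) -> np.ndarray:
        a0, gamma, eps, psi = theta
        inv4k = a0 ** -2 - gamma ** -2
        a = (inv4k * np.exp(-eps * omega * t) + gamma ** -2) ** -0.5
        phase_arg = coef_t + psi
        x = a * np.cos(phase_arg) - (eps * a ** 3 / (8.0 * gamma ** 2)) * np.sin(
            3.0 * phase_arg
        )
        return y_detr - x

    def objective(theta: np.ndarray) -> float:
        return _profiled_nll(residuals_for(theta), codes, counts, config.variance_floor)

    options = {"maxiter": config.maxiter, "ftol": config.ftol}
    if config.profile_mode == "per_eval":
        result = minimize(objective, x0, method="L-BFGS-B", bounds=box, options=options)
        theta = result.x
        converged = bool(result.success)
    else:  # outer: alternate fixed-variance optimisation with re-profiling
        theta = x0
        var = np.maximum(
            np.bincount(codes, weights=residuals_for(theta) ** 2, minlength=3) / counts,
            config.variance_floor,
        )
        converged = False
        for _ in range(config.max_outer):
            result = minimize(
                lambda th: _fixed_var_nll(residuals_for(th), codes, counts, var),
                theta,
                method="L-BFGS-B",
                bounds=box,
                options=options,
            )
            theta = result.x
            new_var = np.maximum(
                np.bincount(codes, weights=residuals_for(theta) ** 2, minlength=3)
                / counts,
                config.variance_floor,
            )
            if np.max(np.abs(new_var - var) / var) < 1e-6:
                converged = bool(result.success)
                var = new_var
                break
            var = new_var

    # L-BFGS-B never returns a worse point than its start, but guard anyway.
    if objective(theta) > objective(x0):
        theta = x0
        converged = False

    r = residuals_for(theta)
    noise = profile_variances(r, codes, config.variance_floor)
    vdp = VanDerPolParams(
        a0=float(theta[0]),
        gamma=float(theta[1]),
        epsilon=float(theta[2]),
        psi=float(theta[3]),
        tau=config.tau_fixed,
    )
    params = FullModelParams(vdp=vdp, trend=trend, noise=noise)
    nll = negative_log_likelihood(series, params, schedule)
    return PhaseFit(
        animal_id=series.animal_id,
        group=series.group,
        phase=series.phase,
        params=params,
        negloglik=nll,
        aic=2.0 * config.n_free_params + 2.0 * nll,
        a_at_T=float(amplitude_at(total, vdp)),
        duration_hours=total,
        n_obs=series.n,
        converged=converged,
        bounds={
            "a0": box[0],
            "gamma": box[1],
            "epsilon": box[2],
            "psi": box[3],
        },
        initial={
            "a0": float(x0[0]),
            "gamma": float(x0[1]),
            "epsilon": float(x0[2]),
            "psi": float(x0[3]),
        },
        n_free_params=config.n_free_params,
        residuals=r,
        regime_codes=codes,
    )


def aic(fit: PhaseFit, n_params: int | None = None) -> float:
    """Akaike information criterion 2p - 2 loglik (p defaults to the fit's)."""
    p = fit.n_free_params if n_params is None else n_params
    return 2.0 * p + 2.0 * fit.negloglik


def residual_acf(fit: PhaseFit, max_lag: int, regime: str | None = None) -> np.ndarray:
    """Sample autocorrelations of the fit residuals at lags 1..max_lag.

    ``regime`` restricts to one noise regime's residuals; default pools all
    samples in time order.
    """
    from statsmodels.tsa.stattools import acf as _acf

    if regime is None:
        r = fit.residuals
    else:
        r = fit.residuals_by_regime()[regime]
    if max_lag < 1 or max_lag >= r.size:
        raise ValueError("max_lag must be in [1, n_residuals)")
    if np.std(r) == 0:
        raise ValueError("autocorrelation undefined for constant residuals")
    return _acf(r, nlags=max_lag, fft=True)[1:]


@dataclass
class HarmonicFit:
    """Constant-amplitude cosinor reference fit (for AIC comparison)."""

    coefficients: np.ndarray  # (c0, c1, A1, A2)
    noise: NoiseParams
    negloglik: float
    aic: float
    n_free_params: int
    residuals: np.ndarray


def harmonic_reference_fit(
    series: TemperatureSeries,
    tau: float = 24.0,
    schedule: VarianceSchedule | None = None,
    variance_floor: float = 1e-6,
) -> HarmonicFit:
    """Fit the harmonic-regression alternative y ~ c0 + c1 t + A1 cos + A2 sin.

    Uses the same three-regime variance profiling so its AIC is comparable
    with the oscillator model's: 7 free parameters (4 regression + 3
    variances).  The oscillator model should win whenever the amplitude
    genuinely drifts within a phase.
    """
    if schedule is None:
        schedule = VarianceSchedule()
    t = series.time_hours
    w = 2.0 * _PI / tau
    design = np.column_stack([np.ones_like(t), t, np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, series.temperature, rcond=None)
    r = series.temperature - design @ coef
    codes = schedule.regime_codes(series.clock_hours)
    noise = profile_variances(r, codes, variance_floor)
    v = noise.as_array()[codes]
    nll = float(
        0.5 * (series.n * math.log(2.0 * _PI) + np.sum(np.log(v)) + np.sum(r * r / v))
    )
    p = 7
    return HarmonicFit(
        coefficients=coef,
        noise=noise,
        negloglik=nll,
        aic=2.0 * p + 2.0 * nll,
        n_free_params=p,
        residuals=r,
    )
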