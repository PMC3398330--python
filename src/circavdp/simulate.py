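"""Synthetic telemetry generation and a numerical oscillator oracle.

Emulates the ovariectomized-rat telemetry protocol: 20 animals in two
treatment groups (estradiol reference vs. tibolone test), three consecutive
phases — estrogen reference P1 (6 d), vehicle washout P2 (6 d), treatment
P3 (10 d) — with tail skin temperature sampled every 3 minutes under a
12:12 light-dark cycle (lights on 06:00-18:00) and three daily noise
regimes.  The default scenario draws per-animal parameters around published
group-level means and spreads for this experiment, so simulated studies
have realistic amplitudes (limit cycle collapsing from ~4 deg C to ~1.6 in
washout and recovering to ~2.7-3.3 under treatment), baselines near 30 deg C
and regime variances of 4-15 deg C^2.

A fixed-step RK4 integrator of the underlying van der Pol ODE is included
purely as a validation oracle for the closed-form perturbation solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    FullModelParams,
    NoiseParams,
    TrendParams,
    VanDerPolParams,
    VarianceSchedule,
    circadian_component,
    circadian_derivative,
    model_mean,
)

__all__ = [
    "STUDY_EPOCH",
    "StudyDesign",
    "TemperatureSeries",
    "simulate_phase",
    "simulate_study",
    "default_scenario",
    "integrate_vdp_ode",
    "perturbation_initial_state",
]

#: Arbitrary but fixed calendar anchor for simulated studies (a Monday 06:00,
#: start of the husbandry day).  Only the clock time matters for the model.
STUDY_EPOCH = pd.Timestamp("2010-03-01 06:00:00")


@dataclass(frozen=True)
class StudyDesign:
    """Experimental layout: phases, sampling cadence, light and noise schedule."""

    phases: tuple = (("P1", 6), ("P2", 6), ("P3", 10))
    dt_minutes: float = 3.0
    lights_on: float = 6.0
    lights_off: float = 18.0
    phase_start_hour: float = 6.0
    schedule: VarianceSchedule = field(default_factory=VarianceSchedule)

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("design needs at least one phase")
        for label, days in self.phases:
            if days <= 0:
                raise ValueError(f"phase {label!r} must have positive duration")
        if self.dt_minutes <= 0 or (24 * 60) % self.dt_minutes:
            raise ValueError("dt_minutes must evenly divide 24 h")

    @property
    def phase_labels(self) -> tuple:
        return tuple(label for label, _ in self.phases)

    @property
    def samples_per_day(self) -> int:
        return int(round(24 * 60 / self.dt_minutes))

    def phase_days(self, label: str) -> int:
        for lab, days in self.phases:
            if lab == label:
                return days
        raise KeyError(f"unknown phase {label!r}")

    def phase_start(self, label: str, epoch: pd.Timestamp = STUDY_EPOCH) -> pd.Timestamp:
        """Start timestamp of a phase when phases run back-to-back from epoch."""
        offset = 0
        for lab, days in self.phases:
            if lab == label:
                return epoch + pd.Timedelta(days=offset)
            offset += days
        raise KeyError(f"unknown phase {label!r}")


@dataclass
class TemperatureSeries:
    """One animal-phase telemetry trace: uniform timestamps plus temperatures."""

    animal_id: str
    group: str
    phase: str
    temperature: np.ndarray
    start: pd.Timestamp
    dt_minutes: float = 3.0
    truth: FullModelParams | None = None

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.start = pd.Timestamp(self.start)
        if self.temperature.ndim != 1 or self.temperature.size == 0:
            raise ValueError("temperature must be a nonempty 1-D array")
        if self.dt_minutes <= 0:
            raise ValueError("dt_minutes must be positive")

    @property
    def n(self) -> int:
        return int(self.temperature.size)

    @property
    def time_hours(self) -> np.ndarray:
        """Hours since the first sample (model time origin)."""
        return np.arange(self.n) * (self.dt_minutes / 60.0)

    @property
    def clock_hours(self) -> np.ndarray:
        """Clock time of each sample in [0, 24), derived from timestamps."""
        start_clock = (
            self.start.hour + self.start.minute / 60.0 + self.start.second / 3600.0
        )
        return (start_clock + self.time_hours) % 24.0

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(np.arange(self.n) * self.dt_minutes, unit="m")

    @property
    def duration_hours(self) -> float:
        """Nominal phase length T = n * dt (end of the last sampling interval)."""
        return self.n * self.dt_minutes / 60.0


def simulate_phase(
    params: FullModelParams,
    design: StudyDesign,
    phase: str,
    seed,
    animal_id: str = "sim",
    group: str = "sim",
    start: pd.Timestamp | None = None,
) -> TemperatureSeries:
    """Simulate one animal-phase series under the observation model.

    y_n = x(n dt) + c(n dt) + e_n with e_n independent Gaussian, variance
    selected by the regime of each sample's clock time.  Reproducible for a
    fixed ``seed`` (an int or :class:`numpy.random.SeedSequence`).
    """
    days = design.phase_days(phase)
    n = days * design.samples_per_day
    if start is None:
        start = design.phase_start(phase)
    series = TemperatureSeries(
        animal_id=animal_id,
        group=group,
        phase=phase,
        temperature=np.zeros(n),
        start=start,
        dt_minutes=design.dt_minutes,
        truth=params,
    )
    mean = model_mean(series.time_hours, params)
    codes = design.schedule.regime_codes(series.clock_hours)
    sd = np.sqrt(params.noise.as_array())[codes]
    rng = np.random.default_rng(seed)
    series.temperature = mean + rng.standard_normal(n) * sd
    return series


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-series integer seeds (each < 2^31) from a master seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def simulate_study(
    param_table: Mapping[str, Mapping[str, FullModelParams]],
    design: StudyDesign,
    seed: int,
    groups: Mapping[str, str],
) -> list[TemperatureSeries]:
    """Simulate every (animal, phase) cell of a study.

    ``param_table`` maps animal id -> phase label -> parameters and must
    cover every phase of the design for every animal; gaps are reported in
    the raised error.  Per-series seeds derive deterministically from the
    master seed, so identical seeds give bit-identical studies.
    """
    animals = sorted(param_table)
    missing = [
        (a, ph)
        for a in animals
        for ph in design.phase_labels
        if ph not in param_table[a]
    ]
    if missing:
        raise ValueError(f"param_table is missing cells: {missing}")
    cells = [(a, ph) for a in animals for ph in design.phase_labels]
    seeds = _child_seeds(seed, len(cells))
    out = []
    for (animal, phase), s in zip(cells, seeds):
        out.append(
            simulate_phase(
                param_table[animal][phase],
                design,
                phase,
                s,
                animal_id=animal,
                group=groups.get(animal, "unknown"),
            )
        )
    return out


# Group-level means and between-animal SDs for the emulated experiment:
# (a0, eps, psi, gamma) oscillator rows and (c0, c1, var_day1, var_day2,
# var_night) trend/noise rows, per group and phase.
_SCENARIO = {
    ("E2", "P1"): dict(a0=(0.65, 0.32), eps=(0.52, 0.26), psi=(0.24, 0.19),
                       gamma=(3.97, 1.48), c0=(29.53, 1.68), c1=(0.31e-4, 1.99e-4),
                       v1=(9.87, 3.69), v2=(4.06, 1.28), vn=(10.39, 2.76)),
    ("E2", "P2"): dict(a0=(2.48, 0.98), eps=(0.29, 0.25), psi=(0.40, 0.34),
                       gamma=(1.58, 0.55), c0=(30.35, 1.12), c1=(1.37e-4, 1.39e-4),
                       v1=(9.56, 3.25), v2=(4.91, 3.55), vn=(11.17, 2.40)),
    ("E2", "P3"): dict(a0=(1.43, 0.61), eps=(0.31, 0.26), psi=(0.16, 0.36),
                       gamma=(2.70, 1.00), c0=(30.71, 0.74), c1=(-1.46e-4, 0.62e-4),
                       v1=(10.22, 3.71), v2=(3.55, 0.90), vn=(9.75, 2.07)),
    ("Tibolone", "P1"): dict(a0=(0.57, 0.21), eps=(0.56, 0.34), psi=(0.25, 0.28),
                             gamma=(3.55, 0.75), c0=(30.02, 1.01), c1=(1.14e-4, 2.85e-4),
                             v1=(9.83, 2.78), v2=(5.25, 1.79), vn=(15.07, 5.24)),
    ("Tibolone", "P2"): dict(a0=(3.10, 1.37), eps=(0.36, 0.34), psi=(0.34, 0.37),
                             gamma=(1.61, 0.55), c0=(30.23, 1.86), c1=(1.53e-4, 2.58e-4),
                             v1=(10.78, 2.51), v2=(5.85, 1.33), vn=(11.97, 2.74)),
    ("Tibolone", "P3"): dict(a0=(1.45, 0.67), eps=(0.20, 0.00), psi=(0.05, 0.21),
                             gamma=(3.29, 0.99), c0=(30.86, 1.28), c1=(-3.15e-4, 1.15e-4),
                             v1=(14.77, 3.50), v2=(4.57, 1.34), vn=(11.28, 2.68)),
}

_EPS_BOUNDS = (0.2, 1.0)


def _draw(rng, mean_sd, lo=None, hi=None):
    mean, sd = mean_sd
    x = rng.normal(mean, sd)
    if lo is not None:
        x = max(x, lo)
    if hi is not None:
        x = min(x, hi)
    return x


def default_scenario(
    seed: int = 0, n_per_group: int = 10, design: StudyDesign | None = None
):
    """Per-animal parameter table for the emulated two-group study.

    Draws each animal-phase parameter independently from a normal
    distribution centred at the group mean with the between-animal SD,
    truncated to valid ranges (eps to [0.2, 1], psi to [-pi, pi], amplitudes
    and variances bounded away from zero).  Returns ``(param_table, groups)``
    ready for :func:`simulate_study`.
    """
    if design is None:
        design = StudyDesign()
    rng = np.random.default_rng(seed)
    param_table: dict = {}
    groups: dict = {}
    for group, prefix in (("E2", "E2"), ("Tibolone", "TI")):
        for i in range(1, n_per_group + 1):
            animal = f"{prefix}_{i:02d}"
            groups[animal] = group
            per_phase = {}
            for phase in design.phase_labels:
                row = _SCENARIO[(group, phase)]
                per_phase[phase] = FullModelParams(
                    vdp=VanDerPolParams(
                        a0=_draw(rng, row["a0"], lo=0.1),
                        gamma=_draw(rng, row["gamma"], lo=0.3),
                        epsilon=_draw(rng, row["eps"], *_EPS_BOUNDS),
                        psi=_draw(rng, row["psi"], lo=-math.pi, hi=math.pi),
                    ),
                    trend=TrendParams(c0=_draw(rng, row["c0"], lo=20.0),
                                      c1=_draw(rng, row["c1"])),
                    noise=NoiseParams(
                        var_day1=_draw(rng, row["v1"], lo=0.5),
                        var_day2=_draw(rng, row["v2"], lo=0.5),
                        var_night=_draw(rng, row["vn"], lo=0.5),
                    ),
                )
            param_table[animal] = per_phase
    return param_table, groups


def integrate_vdp_ode(
    params: VanDerPolParams,
    initial_state,
    duration: float,
    step: float = 0.02,
):
    """Fixed-step RK4 trajectory of the van der Pol ODE.

    Integrates x'' + eps*w*(4 x^2/gamma^2 - 1) x' + w^2 x = 0 from
    ``initial_state = (x0, xdot0)`` over ``duration`` hours.  Returns
    ``(t, x, xdot)`` arrays including both endpoints.  This is the
    validation oracle for the perturbation solution, not a simulation path.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if step <= 0:
        raise ValueError("step must be positive")
    w = params.omega
    eps = params.epsilon
    g2 = params.gamma ** 2

    def deriv(state):
        x, v = state
        return np.array([v, -(eps * w * (4.0 * x * x / g2 - 1.0) * v + w * w * x)])

    n_steps = int(round(duration / step))
    h = duration / n_steps
    t = np.linspace(0.0, duration, n_steps + 1)
    traj = np.empty((n_steps + 1, 2))
    state = np.asarray(initial_state, dtype=float)
    traj[0] = state
    for i in range(n_steps):
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * h * k1)
        k3 = deriv(state + 0.5 * h * k2)
        k4 = deriv(state + h * k3)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        traj[i + 1] = state
    return t, traj[:, 0], traj[:, 1]


def perturbation_initial_state(params: VanDerPolParams) -> tuple:
    """(x(0), dx/dt(0)) of the perturbation solution, for matched ODE starts."""
    return (
        float(circadian_component(0.0, params)),
        float(circadian_derivative(0.0, params)),
    )
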