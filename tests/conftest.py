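import numpy as np
import pytest

from circavdp import (
    FullModelParams,
    NoiseParams,
    StudyDesign,
    TrendParams,
    VanDerPolParams,
    simulate_phase,
)


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture
def recovery_params():
    """Realistic single-animal truth at the magnitudes of the emulated study."""
    return FullModelParams(
        vdp=VanDerPolParams(a0=1.4, gamma=2.7, epsilon=0.3, psi=0.15),
        trend=TrendParams(c0=30.7, c1=1e-4),
        noise=NoiseParams(var_day1=10.0, var_day2=3.5, var_night=9.8),
    )


@pytest.fixture
def simulated_series(design, recovery_params):
    """One 6-day phase simulated at realistic noise levels, fixed seed."""
    return simulate_phase(
        recovery_params, design, "P2", seed=42, animal_id="a1", group="E2"
    )


@pytest.fixture
def quiet_series(design):
    """Nearly noiseless growing-amplitude series for parameter-recovery checks."""
    params = FullModelParams(
        vdp=VanDerPolParams(a0=0.5, gamma=3.0, epsilon=0.4, psi=0.0),
        trend=TrendParams(c0=30.0, c1=0.0),
        noise=NoiseParams(0.01, 0.01, 0.01),
    )
    return simulate_phase(params, design, "P2", seed=7, animal_id="q", group="E2")


def rng_param_draws(n, seed=0):
    """Random valid oscillator parameter vectors for property tests."""
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        draws.append(
            VanDerPolParams(
                a0=rng.uniform(0.1, 5.0),
                gamma=rng.uniform(0.1, 5.0),
                epsilon=rng.uniform(0.0, 1.0),
                psi=rng.uniform(-np.pi, np.pi),
                tau=24.0,
            )
        )
    return draws
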