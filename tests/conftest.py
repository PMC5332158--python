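import numpy as np
import pytest

import replispan as rs
from replispan.simulate import cell_rng


@pytest.fixture(scope="session")
def growth():
    return rs.GrowthParams()


@pytest.fixture(scope="session")
def noiseless_growth():
    return rs.GrowthParams(birth_length_sd=0.0, division_length_sd=0.0,
                           doubling_time_sd=0.0, division_asymmetry_sd=0.0)


@pytest.fixture(scope="session")
def wt_mortality():
    """Default wild-type mortality: constant ~2% hazard per generation."""
    return rs.MortalityModel("exponential", alpha=0.02)


@pytest.fixture(scope="session")
def wt_cohort(wt_mortality):
    return rs.sample_lifespans(wt_mortality, 10_000, seed=101)


@pytest.fixture(scope="session")
def small_trajectory(growth):
    traj = rs.simulate_trajectory(growth, 5, "short", cell_rng(31, 0))
    return traj


@pytest.fixture(scope="session")
def rendered_stack(small_trajectory):
    imaging = rs.ImagingParams(max_jitter=3, noise_sd=6.0)
    stack = rs.render_kymograph_stack(small_trajectory, imaging, seed=99)
    return stack, imaging


def sawtooth_trace(period_h=2.05, n_periods=5, dt_h=2.0 / 60.0,
                   low=8.0, high=16.0):
    """Noiseless sawtooth length trace: linear growth, instant reset."""
    times = np.arange(0.0, period_h * n_periods + 0.6 * period_h, dt_h)
    phase = (times % period_h) / period_h
    lengths = low + (high - low) * phase
    return rs.LengthTrace(times=times, lengths=lengths, pole=None,
                          septum=None, pixel_size=1.0)
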