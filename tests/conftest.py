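"""Shared fixtures: noiseless reference sessions and a simulated study cohort."""

import warnings

import numpy as np
import pytest

from wrikit.config import RunConfig
from wrikit.io_model import ImuSeries
from wrikit.pipeline import sessions_to_features
from wrikit.simulate import SimParams, simulate_cohort, simulate_session

COHORT_SEED = 1


@pytest.fixture
def noiseless_params() -> SimParams:
    """The reference rotation: 45 deg at 2 Hz sustained through every block."""
    return SimParams(
        theta_amp=45.0,
        freq=2.0,
        sustain_s=20.0,
        gyro_noise_sd=0.0,
        accel_noise_sd=0.0,
        gyro_bias=0.0,
        seed=0,
    )


@pytest.fixture
def noiseless_session(noiseless_params):
    return simulate_session(noiseless_params)


@pytest.fixture(scope="session")
def study_features():
    """Feature table of a full simulated study cohort (n=108, default presets)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sessions = simulate_cohort(seed=COHORT_SEED)
        table, failures = sessions_to_features(sessions, RunConfig())
    assert not failures
    return table


def make_series(t, gy, rate=50.0, **channels):
    """ImuSeries with gy set and all other channels zero unless given."""
    t = np.asarray(t, dtype=float)
    zeros = np.zeros_like(t)
    kw = {ch: channels.get(ch, zeros) for ch in ("ax", "ay", "az", "gx", "gz")}
    return ImuSeries(t=t, gy=np.asarray(gy, dtype=float), nominal_rate=rate, **kw)
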