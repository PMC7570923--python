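import numpy as np
import pytest

from ffhdetect.imu_core import ImuTrace
from ffhdetect.synthetic import MotionSpec


@pytest.fixture(scope="session")
def noiseless_spec() -> MotionSpec:
    """Generator conditions with every stochastic term switched off."""
    return MotionSpec(
        accel_noise_sd=0.0,
        gyro_noise_sd=0.0,
        gyro_bias_range=0.0,
        timing_jitter=0.0,
        amplitude_jitter=0.0,
    )


@pytest.fixture(scope="session")
def default_spec() -> MotionSpec:
    return MotionSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_static_trace(n: int = 400, fs: float = 100.0) -> ImuTrace:
    """Quiet upright standing: specific force (0, 0, -1) g, zero rates."""
    t = np.arange(n) / fs
    acc = np.tile([0.0, 0.0, -1.0], (n, 1))
    gyro = np.zeros((n, 3))
    return ImuTrace(t=t, acc=acc, gyro=gyro, fs=fs)


@pytest.fixture()
def static_trace() -> ImuTrace:
    return make_static_trace()
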