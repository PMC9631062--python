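import numpy as np
import pytest

from spadvi import camera, workbench


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sensor():
    return workbench.default_sensor()


@pytest.fixture(scope="session")
def footprint(sensor):
    return workbench.default_footprint(sensor)


@pytest.fixture
def small_stack(rng):
    """Random 4x4x3 binary stack."""
    planes = rng.integers(0, 2, size=(3, 4, 4)).astype(np.uint8)
    return camera.BitPlaneStack(planes=planes, frame_rate_Hz=1000.0,
                                metadata={"origin": "test"})


def constant_stack(lam, n_planes, shape=(8, 8), seed=0, rate=10_000.0):
    """Stack of independent Bernoulli planes at constant per-pixel lambda."""
    rates = np.full((n_planes,) + shape, lam)
    return camera.sample_bit_planes(rates, seed, rate)
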