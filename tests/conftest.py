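import numpy as np
import pytest

from qpmap.fitting import FitConfig
from qpmap.model import VoxelParams, default_protocol
from qpmap.phantom import PhantomSpec, make_phantom, noise_sd_for_snr, simulate_acquisition


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_physiologic_voxel(rng, m0=1000.0):
    """One random voxel state in the physiologic envelope."""
    return VoxelParams(
        kw=float(rng.uniform(30, 150)),
        cbf=float(rng.uniform(10, 80)),
        att=float(rng.uniform(0.6, 2.2)),
        r1b=float(rng.uniform(0.6, 1.3)),
        m0=m0,
    )


@pytest.fixture(scope="session")
def small_phantom(protocol):
    """12x12x6 phantom with an SNR-100 noisy acquisition (seeded)."""
    spec = PhantomSpec(dims=(12, 12, 6), seed=11)
    truth = make_phantom(spec)
    sd = noise_sd_for_snr(truth, protocol, 100.0)
    series = simulate_acquisition(truth, protocol, sd, seed=12)
    return truth, series, sd
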