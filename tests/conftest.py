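"""Shared fixtures: small phantoms, desk-scale protocols, EMI worlds and
pre-simulated records (module-scoped where simulation is reused)."""

from __future__ import annotations

import pytest

from ulfmri.acquisition import t2w_fse, simulate_scan
from ulfmri.emi import EMISource, EMIWorld, make_random_coupling
from ulfmri.phantom import make_phantom


@pytest.fixture(scope="session")
def phantom64():
    return make_phantom((64, 64, 1))


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom((32, 32, 1))


def small_world(seed: int = 7, receive_gain: float = 0.05,
                sensor_noise_sigma: float = 0.01, receive_taps: int = 3) -> EMIWorld:
    """Broadband + mains-harmonic world for small test scans."""
    srcs = [EMISource("broadband", amplitude=1.0, band=(2e3, 18e3), seed=seed * 10 + 1),
            EMISource("powerline_harmonics", amplitude=0.6, band=(0.0, 20e3),
                      seed=seed * 10 + 2)]
    coup = make_random_coupling(2, seed=seed * 10 + 3, receive_taps=receive_taps,
                                sensing_taps=1, receive_gain=receive_gain,
                                sensor_noise_sigma=sensor_noise_sigma)
    return EMIWorld(srcs, coup)


@pytest.fixture(scope="session")
def record32(phantom32):
    """Small contaminated FSE record: 32x32, ETL 8, NEX 1, 40 char windows."""
    protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=1, char_count=10,
                       elliptic=False, receiver_noise_sigma=0.005)
    return simulate_scan(phantom32, protocol, small_world(), seed=11)


@pytest.fixture(scope="session")
def shielded_record32(phantom32):
    protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=1, char_count=10,
                       elliptic=False, receiver_noise_sigma=0.005)
    return simulate_scan(phantom32, protocol, None, seed=11)
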