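import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from spinefusi.synthetic_data import (
    PhantomConfig,
    PressureParams,
    ProtocolSpec,
    generate_phantom,
    simulate_bladder_pressure,
)


@pytest.fixture(scope="session")
def tiny_protocol() -> ProtocolSpec:
    """Tenth-scale default timeline (baseline 30 s, ~156 frames total)."""
    return ProtocolSpec.scaled(0.1)


@pytest.fixture(scope="session")
def tiny_trace(tiny_protocol):
    return simulate_bladder_pressure(tiny_protocol, seed=11)


@pytest.fixture(scope="session")
def clean_trace(tiny_protocol):
    """Noise-free pressure trace."""
    return simulate_bladder_pressure(
        tiny_protocol, PressureParams(noise_sd=0.0), seed=0
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_protocol, tiny_trace):
    """Small noisy phantom with planted regions (SNR 2)."""
    cfg = PhantomConfig(shape=(24, 32), noise_snr=2.0)
    return generate_phantom(cfg, tiny_trace, tiny_protocol, seed=5)


@pytest.fixture(scope="session")
def clean_phantom(tiny_protocol, clean_trace):
    """Noise-free, identity-kernel phantom: planted pixels correlate exactly."""
    cfg = PhantomConfig(
        shape=(24, 32), noise_sd=0.0, noise_snr=None, identity_kernel=True
    )
    return generate_phantom(cfg, clean_trace, tiny_protocol, seed=5)


@pytest.fixture
def smooth_image() -> np.ndarray:
    """Static multi-blob image for registration tests."""
    rng = np.random.default_rng(0)
    shape = (91, 128)
    img = np.full(shape, 0.1)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for _ in range(6):
        r, c = rng.uniform(12, shape[0] - 12), rng.uniform(12, shape[1] - 12)
        img += rng.uniform(0.5, 2.0) * np.exp(
            -(((rr - r) / 4.0) ** 2 + ((cc - c) / 6.0) ** 2)
        )
    return img
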