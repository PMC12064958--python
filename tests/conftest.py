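"""Shared fixtures: small phantom artifacts, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from octa3d.phantom import (
    DriftParams,
    PhantomConfig,
    generate_clean_volume,
    simulate_repeat_acquisitions,
)
from octa3d.projection import mip, register_enface


@pytest.fixture(scope="session")
def phantom_config() -> PhantomConfig:
    return PhantomConfig(shape=(32, 128, 128), seed=3)


@pytest.fixture(scope="session")
def clean_volume(phantom_config):
    return generate_clean_volume(phantom_config)


@pytest.fixture(scope="session")
def drifting_repeats(phantom_config, clean_volume):
    clean, _ = clean_volume
    drift = DriftParams(max_shift=3.0, max_rotation=1.5, seed=11)
    return simulate_repeat_acquisitions(clean, 10, drift, phantom_config)


@pytest.fixture(scope="session")
def registered_repeats(drifting_repeats):
    return register_enface([mip(r.volume) for r in drifting_repeats], reference_index=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
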