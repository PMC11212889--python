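import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bundlekit3d import phantoms

settings.register_profile(
    "ci", derandomize=True, max_examples=30, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> phantoms.PhantomConfig:
    """One-row, two-bundle phantom small enough for fast unit tests."""
    return phantoms.PhantomConfig(
        shape=(16, 160, 160),
        row_y=(100.0,),
        bundles_per_row=2,
        x_margin=45.0,
        wing_length_px=30.0,
        stroke_px=5.0,
        depth=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return phantoms.generate_stack(small_cfg)


@pytest.fixture(scope="session")
def four_row_cfg() -> phantoms.PhantomConfig:
    """Four well-separated rows of three bundles each."""
    return phantoms.PhantomConfig(
        shape=(16, 256, 256),
        row_y=(200.0, 150.0, 100.0, 50.0),
        bundles_per_row=3,
        x_margin=40.0,
        wing_length_px=28.0,
        stroke_px=5.0,
        depth=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def four_row_phantom(four_row_cfg):
    return phantoms.generate_stack(four_row_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
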