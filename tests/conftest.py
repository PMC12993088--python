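"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout5():
    """Small 5x5 checkerboard layout at 5 mm pitch (13 chambers)."""
    from doseup import build_layout

    return build_layout(None, n_rows=5, n_cols=5, grid_pitch_mm=5.0)


@pytest.fixture
def layout53():
    """The standard 53x53 array preset."""
    from doseup import build_layout

    return build_layout("OD1500")
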