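import logging

import numpy as np
import pytest

from epitensor.config import PipelineConfig
from epitensor.edf import EegSegment
from epitensor.synthetic import CouplingSpec, generate_catalog

logging.getLogger("epitensor").setLevel(logging.WARNING)


@pytest.fixture
def channel_names():
    return tuple(f"CH{i:02d}" for i in range(1, 24))


@pytest.fixture
def make_segment(channel_names):
    """Factory for simple deterministic 23-channel segments."""

    def _make(data, fs=256.0, label=None):
        return EegSegment(
            data=np.asarray(data, float),
            fs=fs,
            channel_names=channel_names,
            label=label,
        )

    return _make


@pytest.fixture(scope="session")
def tiny_catalog(tmp_path_factory):
    """8 short segments (64 s) with separated classes, for smoke tests."""
    out = tmp_path_factory.mktemp("tiny_catalog")
    inter = CouplingSpec(coupling_strength=0.2, drift_rate=0.0)
    pre = CouplingSpec(coupling_strength=0.8, drift_rate=-5e-4)
    return generate_catalog(4, inter, pre, 64.0, out, master_seed=7)


@pytest.fixture
def smoke_config():
    """Config scaled to the tiny catalog: short streams, small alarm."""
    return PipelineConfig(band="gamma", num=3, L=6, alarm_len=3, seed=7)
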