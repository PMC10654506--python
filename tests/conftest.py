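import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from retinotile import (
    ReceptiveField,
    SimConfig,
    make_checkerboard,
    make_hex_lattice,
    synth_recording,
)


@pytest.fixture
def config():
    return SimConfig()


@pytest.fixture
def hex25():
    """5x5 jittered hexagonal lattice in SC coordinates (~25 cells)."""
    return make_hex_lattice(100.0, 0.1, 5, 5, seed=42)


@pytest.fixture
def hex25_deg():
    return make_hex_lattice(7.2, 0.1, 5, 5, seed=42, unit="deg", space="visual")


@pytest.fixture(scope="session")
def stimulus_10min():
    """10-minute binary checkerboard at the experimental geometry."""
    return make_checkerboard(600.0, seed=11)


@pytest.fixture(scope="session")
def truth_rfs():
    rng = np.random.default_rng(7)
    return [
        ReceptiveField(
            center=(float(rng.uniform(-25, 25)), float(rng.uniform(-12, 12))),
            sd_long=2.4,
            sd_short=2.4,
            peak_latency=100.0,
            roi_id=i,
        )
        for i in range(20)
    ]


@pytest.fixture(scope="session")
def recording_10min(stimulus_10min, truth_rfs):
    """LNP-simulated event traces for 20 ground-truth RFs."""
    return synth_recording(truth_rfs, stimulus_10min, seed=2)
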