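import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from ipadpy import PenaltyConfig, SimulationSpec, simulate


@pytest.fixture
def small_sim():
    """A small complete-data instance with planted structure."""
    spec = SimulationSpec(N=30, K=4, G1=50, G2=8, h1_density=0.4,
                          h2_density=0.0, missing_rate2=0.0, seed=42)
    return simulate(spec)


@pytest.fixture
def masked_sim():
    """A small instance with missing drug-response cells."""
    spec = SimulationSpec(N=40, K=5, G1=60, G2=10, h1_density=0.35,
                          h2_density=0.0, missing_rate2=0.15, seed=7)
    return simulate(spec)


@pytest.fixture
def quick_cfg():
    return PenaltyConfig(lambda1=0.3, lambda2=0.3, seed=1)
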