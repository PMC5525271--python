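import numpy as np
import pytest
from hypothesis import settings

from photosrna.core_io import Transcript
from photosrna.synthetic_data import SimulationConfig, simulate_world

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_world():
    """A tiny deterministic synthetic world shared by read-only tests."""
    cfg = SimulationConfig(
        seed=7,
        n_transcripts=12,
        n_mirnas=6,
        n_phas_loci=2,
        cluster_archetype_sizes={"I": 1, "II": 2, "III": 2},
    )
    return cfg, simulate_world(cfg)


@pytest.fixture
def toy_transcript():
    return Transcript("tx1", "ACGT" * 30)
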