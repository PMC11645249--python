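import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("ci", derandomize=True)
hypothesis_settings.load_profile("ci")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from locusnet import build_transitions
from locusnet.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_sim():
    """A dense little genome: quick to simulate, rich in gene structure."""
    cfg = SimulationConfig(
        genome_length=60_000,
        mean_exon_length=120,
        mean_exons_per_gene=4,
        coding_fraction=0.05,
        intron_fraction=0.20,
        seed=3,
    )
    record, annotation, labels = simulate_genome(cfg)
    return cfg, record, annotation, labels


@pytest.fixture(scope="session")
def toy_params():
    """HMM with short mean lengths, handy for small decodes."""
    return build_transitions({"intergenic": 100, "intron": 40, "coding_exon": 30})


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
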