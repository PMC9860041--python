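import numpy as np
import pytest

from podovirome.seqio import PipelineConfig
from podovirome.synthetic import CladeSpec, simulate_clade_genomes


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()

@pytest.fixture(scope="session")
def four_clade_genomes():
    """Three genomes per clade for the four named clades, 30 kb, seeded."""
    clades = [CladeSpec(c, 3, 0.02, 0.15) for c in ("MPP-A", "MPP-B", "MPP-C", "P-RSP2")]
    return simulate_clade_genomes(clades, 30_000, seed=11)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
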