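import numpy as np
import pytest

from burstdecon.gene_model import GeneModel, synthetic_gap_gene
from burstdecon.noise_model import NoiseModel


@pytest.fixture(scope="session")
def gap_gene() -> GeneModel:
    return synthetic_gap_gene()


@pytest.fixture(scope="session")
def noise() -> NoiseModel:
    return NoiseModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    """Tiny gene whose kernel spans ~3 coarse steps at 10-s sampling."""
    return GeneModel(
        gene_length_bp=100.0,
        loop_ends_bp=np.array([30.0]),
        elongation_rate=0.2,
        name="toy",
    )
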