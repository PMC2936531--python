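import numpy as np
import pytest
from hypothesis import settings

from competence_evo import Cell, Genome, Phenotype, Population, SimulationParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    return SimulationParams(L=4, K=50.0, delta=0.1)


@pytest.fixture
def tri_population(small_params):
    """Three explicit cells at L=4: a tiny hand-checkable population."""
    cells = [
        Cell(Genome.from_bitstring("1100"), Phenotype.VEGETATIVE, lineage=0),
        Cell(Genome.from_bitstring("1111"), Phenotype.COMPETENT, lineage=0),
        Cell(Genome.from_bitstring("0011"), Phenotype.VEGETATIVE, lineage=1),
    ]
    return Population.from_cells(small_params, cells)
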