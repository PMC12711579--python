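import numpy as np
import pytest

from meicos import GenomeMap, Chromosome, call_population, generate_population
from meicos.simulate import SimulationConfig


@pytest.fixture(scope="session")
def toy_genome():
    """Two small chromosomes with hand-placed pericentromeres."""
    return GenomeMap(
        [
            Chromosome("tc1", 1_000_000, 500_000, 400_000, 600_000),
            Chromosome("tc2", 600_000, 200_000, 150_000, 280_000),
        ]
    )


@pytest.fixture(scope="session")
def pop200():
    """Shared Poisson-mode population: 200 individuals, five 30-Mb chromosomes,
    0.85 COs/gamete/chromosome, default marker grid and missingness."""
    cfg = SimulationConfig(
        model="poisson", co_intensity=0.85, n_individuals=200, seed=11
    )
    return generate_population(cfg)


@pytest.fixture(scope="session")
def pop200_called(pop200):
    segments, events = call_population(pop200.genotypes, min_support=3)
    return segments, events


@pytest.fixture(scope="session")
def noiseless_pop():
    """Noiseless (no missing calls) population for caller-fidelity oracles."""
    cfg = SimulationConfig(
        model="poisson", co_intensity=0.85, n_individuals=150,
        missing_rate=0.0, marker_layout="grid", seed=7,
    )
    return generate_population(cfg)
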