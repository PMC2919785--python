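import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py importable

from breedmap.io_formats import GenotypeMatrix, MarkerMap


@pytest.fixture
def tiny_map():
    return MarkerMap(
        marker_id=[f"m{j}" for j in range(4)],
        chromosome=["chr1", "chr1", "chr1", "chr2"],
        position_bp=[1_000, 51_000, 101_000, 10_000],
    )


@pytest.fixture
def tiny_genotypes(tiny_map):
    return GenotypeMatrix(
        genotypes=[[0, 1, 2, 1], [2, 1, 0, 0], [1, 0, 2, 2]],
        individual_ids=["d1", "d2", "d3"],
        breed_labels=["A", "A", "B"],
        map=tiny_map,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with village dogs, reused across tests."""
    from breedmap.simulate import SimConfig, simulate_breed_frequencies, simulate_haplotypes

    cfg = SimConfig(
        n_breeds=8,
        dogs_per_breed=10,
        n_markers=2000,
        n_chromosomes=2,
        village_dogs=15,
        seed=11,
    )
    truth = simulate_breed_frequencies(cfg)
    panel, genotypes = simulate_haplotypes(cfg, truth)
    return cfg, truth, panel, genotypes
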