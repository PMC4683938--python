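import numpy as np
import pytest

from herdvar.genotype_io import MISSING, GenotypeMatrix, MarkerInfo, PopulationPartition
from herdvar.simdata import IslandScenario, balding_nichols


@pytest.fixture
def toy_gm() -> GenotypeMatrix:
    """2 samples x 2 markers, one missing genotype."""
    markers = [
        MarkerInfo("m1", "1", 100, "A", "G"),
        MarkerInfo("m2", "2", 200, "C", "T"),
    ]
    dosages = np.array([[1, 0], [2, MISSING]], dtype=np.int8)
    return GenotypeMatrix(dosages, markers, ["s1", "s2"])


@pytest.fixture
def three_pop():
    """3-population Balding-Nichols fixture with known truth (seeded)."""
    scenario = IslandScenario(
        n_markers=800,
        n_chromosomes=4,
        population_f=(0.01, 0.05, 0.10),
        sample_sizes=(12, 8, 8),
        seed=42,
    )
    return balding_nichols(scenario)


@pytest.fixture
def three_pop_missing():
    scenario = IslandScenario(
        n_markers=400,
        n_chromosomes=4,
        population_f=(0.02, 0.08, 0.15),
        sample_sizes=(10, 6, 6),
        missing_rate=0.03,
        seed=7,
    )
    return balding_nichols(scenario)


def random_gm(rng: np.random.Generator, n_samples: int, n_markers: int,
              missing_rate: float = 0.0, n_chrom: int = 2) -> GenotypeMatrix:
    """Helper for property tests: random valid GenotypeMatrix."""
    p = rng.uniform(0.05, 0.95, n_markers)
    d = rng.binomial(2, p, size=(n_samples, n_markers)).astype(np.int8)
    if missing_rate:
        d[rng.random(d.shape) < missing_rate] = MISSING
    markers = [
        MarkerInfo(f"m{j}", str(j % n_chrom + 1), (j + 1) * 10, "A", "C")
        for j in range(n_markers)
    ]
    return GenotypeMatrix(d, markers, [f"s{i}" for i in range(n_samples)])
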