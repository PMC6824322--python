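import numpy as np
import pytest

from popgwas import gwas, simulate as sim


@pytest.fixture(scope="session")
def small_panel():
    return sim.simulate_panel(120, 80, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_panel):
    spec = sim.PopulationSpec("toy", 60, 12)
    return sim.sample_population(small_panel, spec, seed=5)


@pytest.fixture(scope="session")
def medium_pop():
    panel = sim.simulate_panel(300, 300, seed=21)
    spec = sim.PopulationSpec("med", 300, 40)
    return sim.sample_population(panel, spec, seed=22)


@pytest.fixture(scope="session")
def medium_grm(medium_pop):
    geno = gwas.GenotypeMatrix.from_phased(medium_pop)
    return gwas.compute_grm(geno)


def random_genotype_matrix(rng, n, m):
    """A toy GenotypeMatrix with random dosages (for oracle tests)."""
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    return gwas.GenotypeMatrix(
        dosages=X,
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1) * 100,
        effect_allele=np.array(["A"] * m, dtype=object),
        other_allele=np.array(["G"] * m, dtype=object),
        sample_ids=[f"s{i}" for i in range(n)],
    )
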