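import numpy as np
import pytest

import ydemos as yd


@pytest.fixture(scope="session")
def table():
    return yd.east_asian_clade_table()


@pytest.fixture(scope="session")
def y_mainland(table):
    return yd.frequency_vector(table, "Mainland Japanese")


@pytest.fixture(scope="session")
def z_korean(table):
    return yd.frequency_vector(table, "Korean")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_matrix():
    """A 6-sample, 40-site haploid matrix from a fixed genealogy."""
    rng = np.random.default_rng(7)
    gen = yd.simulate_genealogy(yd.DemographicModel(n0=100.0), 6, rng)
    return yd.drop_mutations(gen, 40, rng)


@pytest.fixture(scope="session")
def clade_structured():
    """Synthetic 7-clade data with deep stems plus its truth labels."""
    cfg = yd.SynthConfig(n_samples=100, n_snps=3000, stem_scale=20.0, seed=11)
    matrix, truth, gen = yd.generate_clade_haplotypes(cfg)
    return matrix, truth, gen
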