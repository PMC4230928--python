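import numpy as np
import pytest

from tigerscape import simdata
from tigerscape.genotypes import MultilocusGenotype


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def two_pop_sample():
    """Two moderately diverged populations (F_ST ~ 0.15), 30 sampled each."""
    cfg = simdata.SimConfig(
        seed=42, n_pops=2, effective_size=150, n_generations=300,
        migration_matrix=simdata.default_migration_matrix(2, 0.004))
    pops, loci, ledger = simdata.gen_metapopulation(cfg)
    rng = np.random.default_rng(7)
    indices = {lab: rng.choice(150, 30, replace=False) for lab in pops}
    inds = simdata.genotype_array_to_individuals(pops, loci, indices)
    return inds, loci, ledger


def make_ind(sample_id, loci, locality=None):
    return MultilocusGenotype(sample_id=sample_id, loci=loci,
                              locality=locality)
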