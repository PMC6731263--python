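import numpy as np
import pytest

from karyoscan import GenomeSpec, generate_reference, simulate_pileup


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def small_genome():
    """A two-chromosome diploid genome, generated once per session."""
    spec = GenomeSpec(chromosome_lengths=[120_000, 80_000], seed=11)
    reference, truth = generate_reference(spec)
    return spec, reference, truth


@pytest.fixture(scope="session")
def small_pileup(small_genome):
    spec, reference, truth = small_genome
    return simulate_pileup(reference, truth, spec)
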