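import numpy as np
import pytest

from polytax.seq_core import NucleotideSequence
from polytax.synthetic import gen_genome, mutate_genome


@pytest.fixture(scope="session")
def random_16s():
    """A random 1.5-kb 16S-like sequence (balanced composition)."""
    rng = np.random.default_rng(1234)
    return NucleotideSequence(
        "iso16S", "".join(rng.choice(list("ACGT"), size=1500)))


@pytest.fixture(scope="session")
def small_genome():
    return gen_genome(20000, 0.5, seed=7, genome_id="G0")


@pytest.fixture(scope="session")
def small_genome_mutated(small_genome):
    mutated, truth = mutate_genome(small_genome, 0.05, seed=8)
    return mutated, truth
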