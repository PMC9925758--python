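import numpy as np
import pytest

from pirnasv.core_model import ChromSizes, GenomicInterval, SmallRNASpecies
from pirnasv.smallrna_quant import Library


@pytest.fixture
def sizes():
    return ChromSizes({"chr1": 10_000_000, "chr2": 5_000_000})


@pytest.fixture
def small_sizes():
    return ChromSizes({"chrA": 100_000})


def make_species(sequence, count, mappings):
    return SmallRNASpecies(sequence, count, list(mappings))


def make_read(chrom, pos, strand, count=1.0, length=26, rng=None):
    """One uniquely-mapping collapsed read with a random sequence."""
    rng = rng or np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return SmallRNASpecies(seq, count, [(chrom, pos, strand)])


@pytest.fixture
def read_factory():
    rng = np.random.default_rng(12345)
    counter = [0]

    def factory(chrom, pos, strand, count=1.0, length=26):
        counter[0] += 1
        return make_read(chrom, pos, strand, count, length, rng)

    return factory


@pytest.fixture
def library_factory(read_factory):
    def factory(reads, mirna_total=1_000_000.0, label="test"):
        return Library(label, list(reads), mirna_total)

    return factory
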