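import numpy as np
import pytest

from mitosat import fixtures
from mitosat.genome_annotation import CircularGenome


@pytest.fixture(scope="session")
def annotation():
    return fixtures.load_annotation()


@pytest.fixture(scope="session")
def allele_rows():
    return fixtures.load_str_alleles()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length, at_fraction=0.5):
    at = at_fraction / 2
    gc = (1 - at_fraction) / 2
    return "".join(rng.choice(list("ATCG"), size=length, p=[at, at, gc, gc]))


@pytest.fixture()
def small_genome():
    # 56-mer with [AT]5 at position 7 and [G]6 at position 23
    seq = "CCGTAC" + "AT" * 5 + "CTTCAT" + "G" * 6 + "TCACTACGTTCAAGCTTACCGATCGATC"
    return CircularGenome(id="mini", sequence=seq)
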