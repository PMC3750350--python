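import numpy as np
import pytest

from aflpsim import EnzymePair
from aflpsim.genome_io import Gene, GeneSet, Genome

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ecomse():
    return EnzymePair.from_names("EcoRI", "MseI")


@pytest.fixture
def sachpa():
    return EnzymePair.from_names("SacI", "HpaII")


@pytest.fixture
def bsmtaq():
    return EnzymePair.from_names("BsmI", "TaqI")


@pytest.fixture
def tiny_genome():
    return Genome([("c1", "ACGTACGTAC"), ("c2", "ACNNNGTTTT")])


@pytest.fixture
def tiny_geneset():
    return GeneSet(
        [
            Gene("gA", "c1", 1, 5, "+"),
            Gene("gB", "c1", 6, 9, "-"),
            Gene("gC", "c2", 0, 4, "."),
        ]
    )
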