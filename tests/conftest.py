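import math
import random

import pytest

import codonfold as cf
from codonfold.codon_model import GENETIC_CODE

AA_ALPHABET = "".join(sorted(set(GENETIC_CODE) - {"*"}))


@pytest.fixture(scope="session")
def human_w():
    return cf.relative_adaptiveness(cf.embedded_human_usage())


@pytest.fixture(scope="session")
def nus():
    return cf.nussinov_model()


@pytest.fixture(scope="session")
def nn():
    return cf.nearest_neighbor_model()


def random_protein(rng: random.Random, lo: int, hi: int, max_cds: int | None = None) -> str:
    """Random protein with an optional cap on its number of synonymous CDSs."""
    while True:
        prot = "".join(rng.choice(AA_ALPHABET) for _ in range(rng.randint(lo, hi)))
        if max_cds is None:
            return prot
        if math.prod(len(GENETIC_CODE[a]) for a in prot) <= max_cds:
            return prot


def random_rna(rng: random.Random, lo: int, hi: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(rng.randint(lo, hi)))
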