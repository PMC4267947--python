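import numpy as np
import pytest

from sefscreen import (
    HERMAPHRODITE,
    MALE,
    CrossSpec,
    Genotype,
    Individual,
    Locus,
    make_locus_map,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def sef_locus():
    return Locus("sef", "II", 10.0, "recessive")


@pytest.fixture
def sef_map(sef_locus):
    return make_locus_map([sef_locus])


def individual(loci, alleles, sex=HERMAPHRODITE, generation=""):
    """Shorthand constructor used throughout the suite."""
    return Individual(sex, Genotype(dict(loci), dict(alleles)), generation)


@pytest.fixture
def sef_het_herm(sef_map):
    return individual(sef_map, {"sef": ("+", "m")})


@pytest.fixture
def sef_het_male(sef_map):
    return individual(sef_map, {"sef": ("m", "+")}, sex=MALE)


@pytest.fixture
def plain_herm(sef_map):
    return individual(sef_map, {"sef": ("+", "+")})
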