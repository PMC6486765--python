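import numpy as np
import pytest

from daisydrive import (
    Allele,
    DriveArchitecture,
    FitnessModel,
    daisy_architecture,
    enumerate_haplotypes,
)

W, D, R = Allele.W, Allele.D, Allele.R


@pytest.fixture
def daisy3():
    return daisy_architecture(3, 0.95)


@pytest.fixture
def neutral_fitness():
    def make(n):
        return FitnessModel(element_costs=(0.0,) * n, cargo_resistance_cost=0.0)

    return make


def random_genotype(rng: np.random.Generator, n: int):
    haps = enumerate_haplotypes(n)
    i, j = rng.integers(0, len(haps), size=2)
    return (haps[i], haps[j])
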