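"""Shared fixtures: small handmade genomes and simulation configs."""

import numpy as np
import pytest

from balancerscan.core_io import ReferenceGenome
from balancerscan.synthetic_data import SimConfig


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160921)


@pytest.fixture
def toy_ref() -> ReferenceGenome:
    """Two tiny linkage groups with distinct, non-repetitive sequence."""
    r = np.random.default_rng(42)
    return ReferenceGenome({
        "chrI": random_dna(r, 3000),
        "chrII": random_dna(r, 2000),
    })


@pytest.fixture
def clean_sim_cfg() -> SimConfig:
    """Error-free, scar-free simulation on a 2 x 10 kb genome."""
    return SimConfig(seed=5, n_linkage_groups=2, lengths=(10_000, 10_000),
                     substitution_rate=0.0, indel_rate=0.0,
                     microindel_prob=0.0, coverage=15.0)
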