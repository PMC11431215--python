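import numpy as np
import pytest

from sterncode import ConstraintProfile


@pytest.fixture
def default_profile_n4():
    return ConstraintProfile(n=4, d=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20240911)


@pytest.fixture
def dna_strings(rng):
    """A pile of random DNA strings of lengths 1..8 for property tests."""
    bases = np.array(list("ACGT"))
    out = []
    for _ in range(120):
        length = int(rng.integers(1, 9))
        out.append("".join(bases[rng.integers(0, 4, size=length)]))
    return out
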