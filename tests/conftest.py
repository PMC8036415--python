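import numpy as np
import pytest

from enhancerkit.seq_io import DnaSequence

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, seq_id: str = "s") -> DnaSequence:
    return DnaSequence(
        id=seq_id, residues="".join(rng.choice(list(BASES), size=length))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_records(rng):
    """50 random 200-nt sequences with distinct ids."""
    return [random_dna(rng, 200, f"seq{i}") for i in range(50)]
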