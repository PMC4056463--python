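import numpy as np
import pytest

from splitmap.genome import ReferenceGenome
from splitmap.index import build_index

_ALPHA = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng, n: int) -> str:
    return _ALPHA[rng.integers(0, 4, n)].tobytes().decode("ascii")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome(rng):
    """A 60 kb two-chromosome random genome used across tests."""
    return ReferenceGenome(
        {"chr1": random_sequence(rng, 40_000), "chr2": random_sequence(rng, 20_000)}
    )


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index(small_genome)
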