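import numpy as np
import pytest

from ppielm import encode

# fully worked 21-residue example: C->7, Y->3, G->1
EXAMPLE_SEQUENCE = "CCYGGGYYCYYYCGGCCYYCG"
EXAMPLE_ENCODED = [7, 7, 3, 1, 1, 1, 3, 3, 7, 3, 3, 3, 7, 1, 1, 7, 7, 3, 3, 7, 1]


@pytest.fixture(scope="session")
def example_symbols() -> np.ndarray:
    return encode(EXAMPLE_SEQUENCE).symbols


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_protein(rng: np.random.Generator, length: int) -> str:
    from ppielm.features import AAC_ALPHABET
    return "".join(np.array(list(AAC_ALPHABET))[rng.integers(0, 20, size=length)])
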