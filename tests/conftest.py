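import numpy as np
import pytest

from t2tcurate.genome_model import Assembly, Scaffold

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)].tobytes().decode("ascii")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_assembly(rng):
    """Ten random scaffolds of assorted lengths."""
    scaffolds = [
        Scaffold(f"s{i}", random_sequence(rng, int(rng.integers(200, 2000))))
        for i in range(10)
    ]
    return Assembly("small", scaffolds)
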