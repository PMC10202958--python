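import numpy as np
import pytest


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


@pytest.fixture
def rnd():
    return random_seq
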