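import numpy as np
import pytest

from omcorrect import Rmap

WORKED_SEQUENCE = "CGCGTCGCGAATATCGCGTTAATAATAACGCGACGCG"
WORKED_SITE = "CGCG"


@pytest.fixture
def worked_sequence():
    return WORKED_SEQUENCE


def random_rmap(rng: np.random.Generator, rid: str = "r", n_min=3, n_max=12,
                f_min=1, f_max=40) -> Rmap:
    n = int(rng.integers(n_min, n_max + 1))
    frags = [int(x) for x in rng.integers(f_min, f_max + 1, size=n)]
    return Rmap(rid, frags)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
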