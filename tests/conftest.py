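import numpy as np
import pytest

from armipop.data import Alignment


@pytest.fixture
def toy_alignment() -> Alignment:
    """4 sequences, 2 sites segregating, two sites (populations)."""
    return Alignment.from_strings(
        ids=["a", "b", "c", "d"],
        sequences=["AAAA", "AAAT", "AATT", "AAAA"],
        pop_labels=["s1", "s1", "s2", "s2"],
        region_labels=["r1", "r1", "r2", "r2"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231109)
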