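import numpy as np
import pytest

from signalchains import Language, Meaning, MEANING_SPACE
from signalchains.core import ALPHABET

#: The four-signal language used throughout as a worked compression example.
WORKED_EXAMPLE = ["0010", "0100", "0011", "0101"]


def random_language(rng, min_len: int = 3, max_len: int = 8) -> Language:
    """Structureless language: 8 distinct uniform-random signals, lengths
    drawn independently of the meanings."""
    sigs: list[str] = []
    while len(sigs) < 8:
        s = "".join(rng.choice(ALPHABET, size=rng.integers(min_len, max_len + 1)))
        if s not in sigs:
            sigs.append(s)
    return Language.from_signals(sigs)


@pytest.fixture
def worked_example() -> list[str]:
    return list(WORKED_EXAMPLE)


@pytest.fixture
def compositional_language() -> Language:
    """Perfectly compositional toy language: each signal is the meaning's
    3-bit feature string."""
    return Language.from_signals(
        ["".join(str(b) for b in m.bits) for m in MEANING_SPACE]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
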