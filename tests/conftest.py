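import numpy as np
import pytest

from rlfscan import InputSequence, SearchParams


@pytest.fixture(scope="session")
def params() -> SearchParams:
    return SearchParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150416)


def random_sequence(rng: np.random.Generator, max_len: int = 600) -> str:
    """G-enriched random DNA (occasionally with N) for scanner stress tests."""
    length = int(rng.integers(40, max_len + 1))
    g_prob = rng.uniform(0.15, 0.5)
    rest = (1 - g_prob) / 3
    probs = np.array([rest, rest, g_prob, rest])
    chars = rng.choice(list("ACGT"), size=length, p=probs / probs.sum())
    if rng.random() < 0.2:
        idx = rng.integers(0, length, size=max(1, length // 50))
        chars[idx] = "N"
    return "".join(chars)


def as_input(residues: str, name: str = "seq") -> InputSequence:
    return InputSequence(name=name, residues=residues)
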