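import numpy as np
import pytest

from fishid import paperdata
from fishid.seq import IUPACSequence

BASES = "ACGT"


def random_bases(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length))


def substitute(bases: str, positions, seed: int = 0) -> str:
    """Substitute each position to a different concrete base."""
    rng = np.random.default_rng(seed)
    out = list(bases)
    for pos in positions:
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


@pytest.fixture(scope="session")
def assays():
    return paperdata.load_assays()


@pytest.fixture()
def seq_pair_7_subs():
    """A 652-bp pair differing at exactly 7 substitution positions."""
    base = random_bases(652, seed=11)
    rng = np.random.default_rng(12)
    positions = rng.choice(652, size=7, replace=False)
    return (
        IUPACSequence(id="target", bases=base),
        IUPACSequence(id="con", bases=substitute(base, positions, seed=13)),
    )
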