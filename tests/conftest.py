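import numpy as np
import pytest

from pairedni import PairedCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_table(rng, n_max=200, with_missing=True, min_complete=2):
    """A random valid count table with at least ``min_complete`` complete
    pairs and at least one discordant pair."""
    while True:
        n = int(rng.integers(min_complete, n_max))
        cells = rng.multinomial(n, [0.35, 0.15, 0.2, 0.3])
        extra = rng.multinomial(int(rng.integers(0, max(n // 3, 1) + 1)),
                                [0.3, 0.3, 0.2, 0.2]) if with_missing else [0] * 4
        t = PairedCountTable(n00=int(cells[0]), n01=int(cells[1]),
                             n10=int(cells[2]), n11=int(cells[3]),
                             n0x=int(extra[0]), n1x=int(extra[1]),
                             nx0=int(extra[2]), nx1=int(extra[3]))
        if t.n_pp >= min_complete and t.n01 + t.n10 > 0:
            return t


@pytest.fixture
def table_factory(rng):
    def factory(**kwargs):
        return random_table(rng, **kwargs)

    return factory
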