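import numpy as np
import pandas as pd
import pytest

from crosspath.geneset_io import GeneSet, GeneSetCollection


@pytest.fixture
def toy_gmt(tmp_path):
    """Two-line GMT file plus its expected content."""
    path = tmp_path / "toy.gmt"
    path.write_text("P1\tdesc one\tg1\tg2\tg3\nP2\thttp://x\tg2\tg4\n")
    return path


@pytest.fixture
def block_dissim():
    """Two well-separated blocks: within-block dissimilarity 0.05, between 0.95."""
    n = 16
    labels = np.array([0] * 8 + [1] * 8)
    d = np.where(labels[:, None] == labels[None, :], 0.05, 0.95)
    np.fill_diagonal(d, 0.0)
    ids = [f"pw{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids), pd.Series(labels, index=ids)


def make_sets(sizes, universe_size=1000, seed=0, prefix="S"):
    """Random gene sets of given sizes over a shared universe."""
    rng = np.random.default_rng(seed)
    universe = [f"G{i:04d}" for i in range(universe_size)]
    sets = tuple(
        GeneSet(id=f"{prefix}{i}", genes=frozenset(rng.choice(universe, s, replace=False)))
        for i, s in enumerate(sizes)
    )
    return GeneSetCollection(sets=sets, universe=frozenset(universe))
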