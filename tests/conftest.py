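import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from splitomics import GeneSetCollection, build_network

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def toy_collection():
    """10-gene universe with one 4-gene term (the worked enrichment toy)."""
    return GeneSetCollection({"T1": {"g1", "g2", "g3", "g4"}})


@pytest.fixture
def toy_background():
    return {f"g{i}" for i in range(1, 11)}


@pytest.fixture
def chain_network():
    """6-node directed chain a->b->c->d plus isolated pair e->f."""
    return build_network(
        [
            ("a", "activation", "b"),
            ("b", "inhibition", "c"),
            ("c", "unspecified", "d"),
            ("e", "activation", "f"),
        ]
    )


@pytest.fixture
def small_expression():
    """4-gene, 6-sample log2 matrix with one clear up and one clear down gene."""
    rng = np.random.default_rng(7)
    base = rng.uniform(6, 12, size=4)
    data = np.tile(base[:, None], (1, 6)) + rng.normal(0, 0.05, size=(4, 6))
    data[0, 3:] += 2.0  # up in group B
    data[1, 3:] -= 2.0  # down in group B
    expr = pd.DataFrame(
        data, index=["up1", "down1", "null1", "null2"],
        columns=["A1", "A2", "A3", "B1", "B2", "B3"],
    )
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=expr.columns)
    return expr, groups
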