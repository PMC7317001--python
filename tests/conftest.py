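import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from modminer.io import OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def path_graph():
    """a - b - c - d - e."""
    g = nx.Graph()
    nx.add_path(g, list("abcde"))
    return g


def make_matrix(layer, values, features=None, samples=None) -> OmicsMatrix:
    values = np.asarray(values)
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return OmicsMatrix(layer, pd.DataFrame(values, index=features, columns=samples))
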