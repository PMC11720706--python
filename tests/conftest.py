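import networkx as nx
import numpy as np
import pytest

from nbt.io import ClinicalTable, ExpressionMatrix

import pandas as pd


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"G{i:02d}" for i in range(10)]
    samples = [f"S{i}" for i in range(6)]
    return ExpressionMatrix(genes, samples, rng.uniform(0, 10, (10, 6)), "log2")


@pytest.fixture
def small_clinical() -> ClinicalTable:
    return ClinicalTable(pd.DataFrame({
        "sample": ["S0", "S1", "S2", "S3"],
        "time": [2.0, 5.0, 3.5, 8.0],
        "event": [1, 0, 1, 1],
        "response": ["CR", "PR", "SD", "PD"],
    }))


@pytest.fixture
def two_cliques() -> tuple[nx.Graph, list[str], list[str]]:
    """Two 10-cliques joined by a single bridge edge."""
    g = nx.Graph()
    c1 = [f"A{i}" for i in range(10)]
    c2 = [f"B{i}" for i in range(10)]
    for clique in (c1, c2):
        for i in range(10):
            for j in range(i + 1, 10):
                g.add_edge(clique[i], clique[j])
    g.add_edge(c1[0], c2[0])
    return g, c1, c2
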