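import numpy as np
import pandas as pd
import pytest

from coexdriver.io import ExpressionMatrix, GenePanel
from coexdriver.semsim import GoDag


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, 2 control + 2 case."""
    values = pd.DataFrame(
        np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [5.0, 5.0, 6.0, 6.0]]),
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    cond = {"s1": "control", "s2": "control", "s3": "case", "s4": "case"}
    return ExpressionMatrix(values=values, condition_of=cond)


@pytest.fixture
def toy_dag() -> GoDag:
    """Root R with children A (is_a) and C (part_of); B under A and C.

    B reaches R through A with weight 0.8*0.8 = 0.64 and through C with
    weight 0.8*0.6 = 0.48, so the max rule matters.
    """
    return GoDag(
        parents_of={
            "R": {},
            "A": {"R": "is_a"},
            "C": {"R": "part_of"},
            "B": {"A": "is_a", "C": "is_a"},
        },
        namespace_of={t: "molecular_function" for t in "RACB"},
    )


@pytest.fixture
def small_panel() -> GenePanel:
    return GenePanel(
        name="p",
        members={"S1", "S2", "N1"},
        category_of={"S1": "seed", "S2": "seed", "N1": "nkpf"},
    )


def random_simple_graph(rng: np.random.Generator, max_nodes: int = 25):
    """Erdős–Rényi-style random simple graph for oracle comparisons."""
    import networkx as nx

    n = int(rng.integers(3, max_nodes + 1))
    p = float(rng.uniform(0.1, 0.5))
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_edge(i, j)
    return graph
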