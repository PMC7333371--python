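import dendropy
import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def example_tree() -> dendropy.Tree:
    """The hand-checkable three-tip tree ((A:1,B:1):1,C:2)."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def two_block_corr() -> pd.DataFrame:
    """Two 3-gene blocks: within-block r = 0.9, between-block r = 0.2."""
    genes = ["a1", "a2", "a3", "b1", "b2", "b3"]
    corr = np.full((6, 6), 0.2)
    corr[:3, :3] = 0.9
    corr[3:, 3:] = 0.9
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=genes, columns=genes)


@pytest.fixture
def star5() -> nx.Graph:
    return nx.star_graph(["c", "l1", "l2", "l3", "l4"])


@pytest.fixture
def path3() -> nx.Graph:
    return nx.path_graph(["a", "m", "b"])


def z_table(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Tidy mean-Z frame from {sirna: {marker: z}} (missing markers -> 0)."""
    from senonet.screen import MARKERS

    rows = []
    for sirna, zmap in values.items():
        for marker in MARKERS:
            rows.append((sirna, marker, zmap.get(marker, 0.0), 2))
    return pd.DataFrame(rows, columns=["sirna", "marker", "z", "n_experiments"])
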