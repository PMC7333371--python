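"""Seed-gene network construction.

Two network classes: co-expression networks thresholded on the Pearson
correlation matrix, with the threshold chosen to minimize network density
(the proportion of realized edges among nodes that retain at least one
edge — lower density trades more nodes against fewer, stronger edges); and
interaction subnetworks induced by a seed set plus its first-order
neighborhood, keeping all edges among the included nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ThresholdScan",
    "pearson_matrix",
    "scan_thresholds",
    "select_threshold",
    "coexpression_network",
    "first_order_subnetwork",
    "components",
]


@dataclass
class ThresholdScan:
    """Per-threshold node/edge/density profile of a correlation matrix.

    ``table`` has columns threshold, n_nodes, n_edges, density; density is
    NaN where a threshold keeps no edge, and such rows are excluded from
    threshold selection.
    """

    table: pd.DataFrame
    absolute: bool = False


def pearson_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation matrix from a genes x samples frame.

    Genes with zero sample variance are excluded (they have no defined
    correlation and must not contribute edges downstream).
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    values = expr.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 genes with nonzero variance")
    corr = np.corrcoef(values[keep])
    np.fill_diagonal(corr, 1.0)
    genes = expr.index[keep]
    return pd.DataFrame(corr, index=genes, columns=genes)


def _edges_at(corr: pd.DataFrame, threshold: float, absolute: bool) -> list[tuple[str, str]]:
    vals = corr.to_numpy()
    if absolute:
        vals = np.abs(vals)
    iu, ju = np.triu_indices(len(corr), k=1)
    mask = vals[iu, ju] >= threshold
    genes = corr.index.to_numpy()
    return list(zip(genes[iu[mask]], genes[ju[mask]]))


def scan_thresholds(
    corr: pd.DataFrame, grid: list[float], absolute: bool = False
) -> ThresholdScan:
    """Node count, edge count and density at each correlation threshold.

    At threshold ``t`` the network keeps pairs with correlation >= t (signed
    by default, on |r| with ``absolute``); only nodes incident to a kept edge
    are counted, and density = E / (N * (N - 1) / 2).
    """
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    grid = list(grid)
    if any(not 0 <= t < 1 for t in grid) or any(
        b <= a for a, b in zip(grid, grid[1:])
    ):
        raise ValueError("grid must be strictly increasing within [0, 1)")
    rows = []
    for t in grid:
        edges = _edges_at(corr, t, absolute)
        nodes = {u for e in edges for u in e}
        n, e = len(nodes), len(edges)
        density = e / (n * (n - 1) / 2) if e else np.nan
        rows.append((t, n, e, density))
    return ThresholdScan(
        table=pd.DataFrame(rows, columns=["threshold", "n_nodes", "n_edges", "density"]),
        absolute=absolute,
    )


def select_threshold(scan: ThresholdScan) -> float:
    """Threshold with minimum network density; ties go to the lowest threshold.

    The lowest tied threshold keeps the most seed genes in the network
    (maximal inclusion) at the same density.
    """
    defined = scan.table.dropna(subset=["density"])
    if defined.empty:
        raise ValueError("no threshold yields a defined density")
    best = defined.loc[defined["density"].idxmin()]
    # idxmin already takes the first (lowest) threshold on ties because the
    # grid is strictly increasing
    return float(best["threshold"])


def coexpression_network(
    corr: pd.DataFrame,
    threshold: float,
    seeds: set[str],
    absolute: bool = False,
) -> nx.Graph:
    """First-order co-expression network around the seed genes.

    Nodes are the seeds present in the matrix plus their super-threshold
    partners; edges are all super-threshold pairs among the included nodes
    (partner-partner edges kept, partners-of-partners excluded) — the same
    neighborhood rule as :func:`first_order_subnetwork` applied to the
    thresholded correlation graph.
    """
    present = sorted(set(seeds) & set(corr.index))
    if not present:
        raise ValueError("no seed gene present in the correlation matrix")
    edges = _edges_at(corr, threshold, absolute)
    seedset = set(present)
    nodes = set(present) | {
        v for u, v in edges if u in seedset
    } | {u for u, v in edges if v in seedset}
    kept = [(u, v) for u, v in edges if u in nodes and v in nodes]
    if not kept:
        raise ValueError("no super-threshold edge touches the node set")
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(kept)
    g.remove_edges_from(nx.selfloop_edges(g))
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0 and n not in seedset])
    return g


def first_order_subnetwork(edges, seeds: set[str]) -> nx.Graph:
    """Seed-plus-first-order-neighbor subnetwork of an interaction edge list.

    Nodes = seeds appearing in the edge list (or isolated seeds given as
    endpoints) plus direct neighbors of seeds; edges = all input edges with
    both endpoints in that node set, including edges between two first-order
    partners. Self-loops and duplicate edges are removed first.
    """
    base: nx.Graph = nx.Graph()
    cleaned = [(str(u).strip(), str(v).strip()) for u, v in edges]
    base.add_edges_from((u, v) for u, v in cleaned if u != v)
    if base.number_of_edges() == 0:
        raise ValueError("edge list is empty after cleaning")
    present = set(seeds) & set(base.nodes)
    if not present:
        raise ValueError("no seed appears in the edge list")
    nodes = set(present)
    for s in present:
        nodes.update(base.neighbors(s))
    return nx.Graph(base.subgraph(nodes))


def components(net: nx.Graph) -> list[list[str]]:
    """Connected components, largest first; ties by smallest node label."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [sorted(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps
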