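"""Topological analysis of seed-gene networks.

Four per-node parameters drive candidate discovery: degree (hubs),
normalized betweenness centrality (bottlenecks), closeness centrality
(reciprocal of the mean shortest-path distance to reachable nodes, so higher
means more central), and "increased connectivity" (IC) — the hypergeometric
significance of how many of a node's neighbors fall in the seed set compared
to chance. Candidate regulators are nodes ranking in the top percentile of
several parameters, or carrying a significant IC alongside one top-percentile
membership. Also here: network density, the log-log least-squares power-law
fit used to check scale-free structure, and an edge-clustering-value (ECV)
agglomeration for module detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from senonet.overlap import bh_adjust

__all__ = [
    "PowerLawFit",
    "ModulePartition",
    "compute_topology",
    "network_density",
    "fit_power_law",
    "ic_pvalues",
    "rank_candidates",
    "detect_modules",
]


@dataclass
class PowerLawFit:
    """Least-squares fit of log(frequency) = log(a) + b * log(degree)."""

    coefficient: float
    exponent: float
    corr_loglog: float
    r_squared: float


@dataclass
class ModulePartition:
    """Node-to-module assignment from agglomerative clustering."""

    module_of: dict[str, int]
    sizes: dict[int, int] = field(default_factory=dict)
    unassigned: set = field(default_factory=set)


def _percentile_rank(values: pd.Series) -> pd.Series:
    """Weak-CDF percentile rank in [0, 100]: share of nodes with value <= v."""
    n = len(values)
    ranks = values.rank(method="max")
    return 100.0 * ranks / n


def compute_topology(net: nx.Graph, seeds: set[str]) -> pd.DataFrame:
    """Per-node degree, betweenness, closeness, local clustering and IC.

    Betweenness is pair-normalized within each connected component (a node's
    score is the fraction of shortest paths between pairs of its component
    that pass through it); closeness is 1 / mean distance to reachable
    nodes; local clustering is the realized fraction of neighbor-neighbor
    edges (0 for degree < 2). IC p-values are computed by
    :func:`ic_pvalues` with the component as sampling universe and BH
    adjustment across all nodes. Percentile ranks (weak-CDF, 0-100) are
    reported for degree, betweenness and closeness.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    bc: dict[str, float] = {}
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        bc.update(nx.betweenness_centrality(sub, normalized=len(comp) > 2))
    cc = nx.closeness_centrality(net, wf_improved=False)
    local = nx.clustering(net)
    ic = ic_pvalues(net, seeds) if seeds else None
    nodes = sorted(net.nodes)
    report = pd.DataFrame(
        {
            "degree": [net.degree(v) for v in nodes],
            "bc": [bc[v] for v in nodes],
            "cc": [cc[v] for v in nodes],
            "local_cc": [local[v] for v in nodes],
            "is_seed": [v in seeds for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    if ic is not None:
        report["ic_p"] = ic.loc[nodes, "ic_p"]
        report["ic_p_adj"] = ic.loc[nodes, "ic_p_adj"]
    for col in ("degree", "bc", "cc"):
        report[f"{col}_pct"] = _percentile_rank(report[col])
    return report


def network_density(net: nx.Graph) -> float:
    """Realized fraction of all possible edges: 2E / (N (N - 1))."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density needs >= 2 nodes")
    return 2.0 * net.number_of_edges() / (n * (n - 1))


def fit_power_law(net: nx.Graph) -> PowerLawFit:
    """Log-log least-squares fit of the degree-frequency distribution.

    Fits log(frequency) against log(degree) over degrees >= 1 with nonzero
    frequency; a good negative-slope fit indicates scale-free structure.
    Follows the network-analyzer convention (least squares on log-log
    points) rather than maximum-likelihood tail estimation.
    """
    degrees = [d for _, d in net.degree() if d >= 1]
    ks, freqs = np.unique(degrees, return_counts=True)
    if len(ks) < 3:
        raise ValueError("power-law fit needs >= 3 distinct degrees")
    x, y = np.log(ks), np.log(freqs)
    res = stats.linregress(x, y)
    return PowerLawFit(
        coefficient=math.exp(res.intercept),
        exponent=float(res.slope),
        corr_loglog=float(res.rvalue),
        r_squared=float(res.rvalue**2),
    )


def ic_pvalues(net: nx.Graph, seeds: set[str]) -> pd.DataFrame:
    """Increased-connectivity p-values: seed overrepresentation among neighbors.

    For node v with k neighbors of which x are seeds, the one-sided upper
    tail P(X >= x) of a hypergeometric draw of k nodes from the v-excluded
    component universe (N - 1 nodes, K of them seeds, not counting v itself)
    measures whether v touches more seeds than chance allows. BH adjustment
    runs across all nodes of the network.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("empty seed set")
    if not seeds <= set(net.nodes):
        raise ValueError("seeds must be a subset of the network nodes")
    nodes, pvals = [], []
    for comp in nx.connected_components(net):
        n_comp = len(comp)
        k_seeds = len(comp & seeds)
        for v in comp:
            neigh = set(net.neighbors(v))
            x = len(neigh & seeds)
            big_k = k_seeds - (1 if v in seeds else 0)
            # P(X >= x) drawing |neigh| from N-1 nodes containing big_k seeds
            p = float(stats.hypergeom.sf(x - 1, n_comp - 1, big_k, len(neigh)))
            nodes.append(v)
            pvals.append(min(1.0, p))
    adj = bh_adjust(pvals)
    return pd.DataFrame(
        {"ic_p": pvals, "ic_p_adj": adj}, index=pd.Index(nodes, name="node")
    ).sort_index()


def _top_set(values: pd.Series, tier: float) -> set:
    """Nodes among the top ``tier`` percent (ties at the cut included)."""
    n = len(values)
    k = max(1, math.ceil(tier / 100.0 * n))
    cut = values.sort_values(ascending=False).iloc[k - 1]
    return set(values.index[values >= cut])


def rank_candidates(
    report: pd.DataFrame,
    top_tier: float = 1.0,
    second_tier: float = 5.0,
    alpha: float = 0.05,
    novel_only: bool = False,
) -> pd.DataFrame:
    """Candidate regulators from topological rankings.

    A node qualifies when it sits in the top ``top_tier`` percent of at
    least two of degree / betweenness / closeness, or carries a significant
    adjusted IC together with at least one membership in the top
    ``second_tier`` percent of those parameters. Seeds are flagged but kept
    unless ``novel_only``. Output is ordered by the number of qualifying
    criteria, then betweenness descending, then node label.
    """
    for tier in (top_tier, second_tier):
        if not 0 < tier < 100:
            raise ValueError("percentile tiers must lie in (0, 100)")
    metrics = ("degree", "bc", "cc")
    top1 = {m: _top_set(report[m], top_tier) for m in metrics}
    top2 = {m: _top_set(report[m], second_tier) for m in metrics}
    rows = []
    for node in report.index:
        n_top1 = sum(node in top1[m] for m in metrics)
        n_top2 = sum(node in top2[m] for m in metrics)
        sig_ic = (
            "ic_p_adj" in report.columns and report.at[node, "ic_p_adj"] < alpha
        )
        qualifies = n_top1 >= 2 or (sig_ic and n_top2 >= 1)
        if not qualifies:
            continue
        if novel_only and bool(report.at[node, "is_seed"]):
            continue
        rows.append(
            {
                "node": node,
                "n_criteria": n_top1 + int(bool(sig_ic)),
                "top_tier_memberships": n_top1,
                "significant_ic": bool(sig_ic),
                "bc": report.at[node, "bc"],
                "is_seed": bool(report.at[node, "is_seed"]),
            }
        )
    out = pd.DataFrame(
        rows, columns=["node", "n_criteria", "top_tier_memberships",
                       "significant_ic", "bc", "is_seed"]
    )
    if len(out):
        out = out.sort_values(
            ["n_criteria", "bc", "node"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return out


def _ecv(net: nx.Graph, u: str, v: str) -> float:
    nu = set(net.neighbors(u)) - {v}
    nv = set(net.neighbors(v)) - {u}
    if not nu or not nv:
        return 0.0
    common = len(set(net.neighbors(u)) & set(net.neighbors(v)))
    return common**2 / (len(nu) * len(nv))


def detect_modules(
    net: nx.Graph, lam: float = 2.0, min_size_fraction: float = 0.01
) -> ModulePartition:
    """Agglomerative module detection ordered by edge clustering value.

    Each edge (u, v) scores ECV = |N(u) ∩ N(v)|^2 / (|N(u)\\{v}| |N(v)\\{u}|);
    edges are processed in descending ECV (ties by lexicographic endpoints),
    growing a cluster whenever an endpoint is unassigned, and merging two
    clusters only when the merged cluster keeps total internal degree
    > (lam / 2) x total external degree (at the default lam = 2 this is the
    weak-community condition). Edges with ECV = 0 carry no cohesion evidence
    (no shared neighbor) and never trigger a merge, so bridges between
    modules are left uncut-across. Clusters smaller than
    ``min_size_fraction x N`` are discarded to the unassigned set.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    n = net.number_of_nodes()
    scored = []
    for u, v in net.edges:
        a, b = sorted((u, v))
        scored.append((-_ecv(net, a, b), a, b))
    scored.sort()
    cluster_of: dict[str, int] = {}
    members: dict[int, set] = {}
    next_id = 0
    for neg_ecv, u, v in scored:
        if neg_ecv == 0.0:
            continue  # ECV = 0: no shared-neighbor evidence of cohesion
        cu, cv = cluster_of.get(u), cluster_of.get(v)
        if cu is None and cv is None:
            members[next_id] = {u, v}
            cluster_of[u] = cluster_of[v] = next_id
            next_id += 1
        elif cu is None or cv is None:
            cid = cv if cu is None else cu
            node = u if cu is None else v
            members[cid].add(node)
            cluster_of[node] = cid
        elif cu != cv:
            merged = members[cu] | members[cv]
            internal = 2 * sum(
                1 for a, b in net.edges(merged) if a in merged and b in merged
            )
            external = sum(
                1 for a, b in net.edges(merged) if (a in merged) != (b in merged)
            )
            if internal > (lam / 2.0) * external:
                for node in members[cv]:
                    cluster_of[node] = cu
                members[cu] = merged
                del members[cv]
    min_size = min_size_fraction * n
    module_of: dict[str, int] = {}
    sizes: dict[int, int] = {}
    keep = sorted(
        (cid for cid, m in members.items() if len(m) >= max(min_size, 1)),
        key=lambda cid: (-len(members[cid]), min(members[cid])),
    )
    for new_id, cid in enumerate(keep, start=1):
        for node in members[cid]:
            module_of[node] = new_id
        sizes[new_id] = len(members[cid])
    unassigned = set(net.nodes) - set(module_of)
    return ModulePartition(module_of=module_of, sizes=sizes, unassigned=unassigned)
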