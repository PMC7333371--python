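"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Each generator emulates one class of study input: latent-factor expression
matrices with planted co-expressed modules, preferential-attachment
interaction graphs with a designated seed subset (optionally a planted
high-connectivity node), per-tissue differential-expression tables with
planted multi-tissue genes, pure-birth trees, and high-content screen plates
with designed hits. All generators are deterministic given their seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from senonet.screen import MARKERS, SENESCENCE_DIRECTION

__all__ = [
    "SyntheticExpression",
    "SyntheticScreenTruth",
    "gen_expression",
    "gen_scalefree_graph",
    "gen_deg_tables",
    "gen_screen",
    "gen_tree",
]


@dataclass
class SyntheticExpression:
    """Expression matrix with known module membership.

    ``matrix`` is genes x samples; ``module_of`` maps every gene to its
    module id or ``"noise"``.
    """

    matrix: pd.DataFrame
    module_of: dict[str, str]
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticScreenTruth:
    """Ground truth for a designed siRNA screen.

    ``designed_hit`` maps an siRNA label to the set of markers shifted in the
    senescence-associated direction; ``shift_sd_units`` is the shift size in
    units of the control SD (per marker, with ``default_shift`` as fallback);
    ``control_mean``/``control_sd`` parameterize the negative-control
    distribution per marker.
    """

    designed_hit: dict[str, frozenset]
    shift_sd_units: dict[str, float] = field(default_factory=dict)
    default_shift: float = 3.0
    control_mean: dict[str, float] = field(default_factory=dict)
    control_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.default_shift < 0:
            raise ValueError("shift_sd_units must be >= 0")
        for marker, s in self.shift_sd_units.items():
            if s < 0:
                raise ValueError(f"shift_sd_units must be >= 0 (marker {marker})")
        for m in MARKERS:
            self.control_mean.setdefault(m, 100.0)
            self.control_sd.setdefault(m, 10.0)

    def shift_for(self, marker: str) -> float:
        return self.shift_sd_units.get(marker, self.default_shift)


def gen_expression(
    n_modules: int,
    genes_per_module: int,
    n_noise: int,
    n_samples: int,
    within_r: float,
    seed: int,
) -> SyntheticExpression:
    """Latent-factor expression matrix with planted correlated modules.

    Genes within a module share a standard-normal latent factor:
    ``gene = sqrt(within_r) * factor + sqrt(1 - within_r) * noise``, so the
    expected pairwise Pearson correlation within a module is ``within_r``
    exactly; noise genes are i.i.d. standard normal.
    """
    if not 0 <= within_r < 1:
        raise ValueError("within_r must lie in [0, 1)")
    if min(n_modules, genes_per_module, n_samples) < 1 or n_noise < 0:
        raise ValueError("counts must be positive (n_noise >= 0)")
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    genes: list[str] = []
    module_of: dict[str, str] = {}
    a, b = math.sqrt(within_r), math.sqrt(1.0 - within_r)
    for m in range(n_modules):
        mid = f"M{m + 1}"
        factor = rng.standard_normal(n_samples)
        for g in range(genes_per_module):
            name = f"{mid}_g{g + 1}"
            rows.append(a * factor + b * rng.standard_normal(n_samples))
            genes.append(name)
            module_of[name] = mid
    for g in range(n_noise):
        name = f"noise_g{g + 1}"
        rows.append(rng.standard_normal(n_samples))
        genes.append(name)
        module_of[name] = "noise"
    matrix = pd.DataFrame(
        np.vstack(rows), index=genes, columns=[f"s{i + 1}" for i in range(n_samples)]
    )
    params = dict(
        n_modules=n_modules,
        genes_per_module=genes_per_module,
        n_noise=n_noise,
        n_samples=n_samples,
        within_r=within_r,
        seed=seed,
    )
    return SyntheticExpression(matrix=matrix, module_of=module_of, params=params)


def gen_scalefree_graph(
    n_nodes: int,
    m_attach: int,
    seed_fraction: float,
    plant_seed_hub: bool,
    seed: int,
) -> tuple[nx.Graph, set[str]]:
    """Preferential-attachment graph plus a designated seed subset.

    Growth starts from an ``m_attach``-clique; every subsequent node attaches
    ``m_attach`` edges to distinct existing nodes with probability
    proportional to degree, giving exactly
    ``C(m_attach, 2) + m_attach * (n_nodes - m_attach)`` edges. A random
    ``seed_fraction`` of nodes is marked as seeds. With ``plant_seed_hub`` an
    extra non-seed node is wired to 75% (ceiling) of the seeds — a designed
    high-connectivity-to-seeds node that candidate discovery should surface.
    """
    if not 0 < seed_fraction < 1:
        raise ValueError("seed_fraction must lie in (0, 1)")
    if m_attach >= n_nodes:
        raise ValueError("m_attach must be < n_nodes")
    rng = np.random.default_rng(seed)
    names = [f"g{i + 1:04d}" for i in range(n_nodes)]
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(names[:m_attach])
    graph.add_edges_from(itertools.combinations(names[:m_attach], 2))
    for name in names[m_attach:]:
        existing = list(graph.nodes)
        deg = np.array([graph.degree(u) for u in existing], dtype=float)
        # the clique start guarantees every existing node has degree >= 1
        targets = rng.choice(existing, size=m_attach, replace=False, p=deg / deg.sum())
        graph.add_node(name)
        graph.add_edges_from((name, t) for t in targets)
    n_seeds = max(1, round(seed_fraction * n_nodes))
    seeds = set(rng.choice(names, size=n_seeds, replace=False))
    if plant_seed_hub:
        hub = "planted_hub"
        wired = rng.choice(sorted(seeds), size=math.ceil(0.75 * len(seeds)), replace=False)
        graph.add_node(hub)
        graph.add_edges_from((hub, s) for s in wired)
    return graph, seeds


def gen_deg_tables(
    n_genes: int,
    tissue_sig_up: dict[str, int],
    tissue_sig_down: dict[str, int],
    planted: dict[str, tuple[list[str], str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-tissue differential-expression table with planted multi-tissue genes.

    Every tissue gets exactly ``tissue_sig_up[t]`` genes with
    (p_adj < 0.05, effect > log2(1.5)) and ``tissue_sig_down[t]`` with
    (p_adj < 0.05, effect < -log2(1.5)); planted genes occupy significant
    slots in their stated tissues and directions; all remaining genes draw
    p_adj uniform on (0.05, 1] and effect uniform in (-log2(1.5), log2(1.5)).
    Effects are on the 50-year scale used downstream.
    """
    planted = planted or {}
    tissues = list(tissue_sig_up)
    if set(tissue_sig_down) != set(tissues):
        raise ValueError("tissue_sig_up and tissue_sig_down must cover the same tissues")
    for t in tissues:
        if tissue_sig_up[t] + tissue_sig_down[t] > n_genes:
            raise ValueError(f"significant counts exceed n_genes in tissue {t}")
    for gene, (gts, direction) in planted.items():
        if direction not in {"up", "down"}:
            raise ValueError("planted direction must be 'up' or 'down'")
        unknown = set(gts) - set(tissues)
        if unknown or len(gts) > len(tissues):
            raise ValueError(f"planted gene {gene} assigned to unknown or too many tissues")
    genes = list(planted)
    genes += [f"g{i + 1:05d}" for i in range(n_genes - len(genes))]
    if len(genes) != n_genes or len(set(genes)) != n_genes:
        raise ValueError("planted genes must fit within n_genes and be unique")
    rng = np.random.default_rng(seed)
    fc_min = math.log2(1.5)
    rows = []
    for t in tissues:
        up_planted = [g for g, (gts, d) in planted.items() if d == "up" and t in gts]
        down_planted = [g for g, (gts, d) in planted.items() if d == "down" and t in gts]
        if len(up_planted) > tissue_sig_up[t] or len(down_planted) > tissue_sig_down[t]:
            raise ValueError(f"planted genes exceed significant slots in tissue {t}")
        # planted genes are significant exactly where stated, never by fill
        pool = [g for g in genes if g not in planted]
        pool = list(rng.permutation(pool))
        n_fill_up = tissue_sig_up[t] - len(up_planted)
        n_fill_down = tissue_sig_down[t] - len(down_planted)
        up = up_planted + pool[:n_fill_up]
        down = down_planted + pool[n_fill_up : n_fill_up + n_fill_down]
        sig = set(up) | set(down)
        for g in genes:
            if g in sig:
                p = rng.uniform(1e-6, 0.05 - 1e-6)
                eff = fc_min + rng.uniform(0.05, 2.0)
                if g in set(down):
                    eff = -eff
            else:
                p = rng.uniform(0.05 + 1e-9, 1.0)
                eff = rng.uniform(-fc_min + 1e-9, fc_min - 1e-9)
            rows.append((t, g, p, eff))
    return pd.DataFrame(rows, columns=["tissue", "gene", "p_adj", "log2fc50"])


def gen_screen(
    n_targets: int,
    truth: SyntheticScreenTruth,
    n_experiments: int,
    wells_per_condition: int,
    seed: int,
) -> pd.DataFrame:
    """High-content screen measurement table with designed hits.

    Negative-control wells draw from Normal(control mean, control sd) per
    marker per experiment; target wells draw from the same distribution
    except that markers in a target's ``designed_hit`` set are shifted by
    ``shift_sd_units x sd`` in the senescence-associated direction (down for
    cell number and Ki67, up for the rest). Target labels are
    ``target_001``.. unless named in ``truth.designed_hit``.
    """
    if n_experiments < 2:
        raise ValueError("n_experiments must be >= 2")
    if wells_per_condition < 3:
        raise ValueError("wells_per_condition must be >= 3")
    rng = np.random.default_rng(seed)
    named = list(truth.designed_hit)
    if len(named) > n_targets:
        raise ValueError("more designed hits than targets")
    targets = named + [f"target_{i + 1:03d}" for i in range(n_targets - len(named))]
    rows = []
    for e in range(1, n_experiments + 1):
        exp = f"exp{e}"
        for w in range(1, wells_per_condition + 1):
            vals = {
                m: rng.normal(truth.control_mean[m], truth.control_sd[m]) for m in MARKERS
            }
            rows.append({"experiment": exp, "well": f"NC_{w}", "sirna": "cyclophilinB",
                         "role": "neg_control", **vals})
        for sirna in targets:
            hit = truth.designed_hit.get(sirna, frozenset())
            for w in range(1, wells_per_condition + 1):
                vals = {}
                for m in MARKERS:
                    mu = truth.control_mean[m]
                    if m in hit:
                        mu += SENESCENCE_DIRECTION[m] * truth.shift_for(m) * truth.control_sd[m]
                    vals[m] = rng.normal(mu, truth.control_sd[m])
                rows.append({"experiment": exp, "well": f"{sirna}_{w}", "sirna": sirna,
                             "role": "target", **vals})
    return pd.DataFrame(rows, columns=["experiment", "well", "sirna", "role", *MARKERS])


def gen_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times, unit birth rate.

    Lineages split at exponential waiting times (rate = number of extant
    lineages); the lineage to split is chosen uniformly. The result is an
    ultrametric rooted tree with strictly positive branch lengths and unique
    tip labels ``t1``..``tN``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active leaves with their birth times
    t = 0.0
    first, second = dendropy.Node(), dendropy.Node()
    tree.seed_node.add_child(first)
    tree.seed_node.add_child(second)
    active: list[tuple[dendropy.Node, float]] = [(first, 0.0), (second, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / len(active))
    for k, (node, born) in enumerate(active):
        node.edge.length = t_end - born
    tree.seed_node.edge.length = None
    for k, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.require_taxon(label=f"t{k + 1}")
    return tree
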