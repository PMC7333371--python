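"""Conservation statistics: proportion z-tests and Faith's phylogenetic diversity.

Faith's PD for a tip subset is the branch-length sum of the minimal spanning
subtree, by default including the path from the subtree's most recent common
ancestor up to the root (the convention of the R phylodiversity ecosystem).
Its expectation under binomial tip sampling — each tip kept independently
with probability p — has the closed form sum over branches of
``L_b * (1 - (1 - p)^{n_b})`` with ``n_b`` the tips descending from the
branch. Orthologue-conservation comparisons use the pooled two-proportion
z-test with a two-tailed normal p-value.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np
from scipy import stats

__all__ = ["two_proportion_ztest", "faith_pd", "expected_pd", "total_tree_length"]


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test; returns (z, two-tailed p).

    z = (p1 - p2) / sqrt(p_pool (1 - p_pool) (1/n1 + 1/n2)). With a pooled
    proportion of exactly 0 or 1 the proportions are equal and z = 0.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pool * (1.0 - pool) * (1.0 / n1 + 1.0 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return z, min(1.0, p)


def _check_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels must be unique")


def total_tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (missing lengths count 0)."""
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def faith_pd(tree: dendropy.Tree, tips, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a tip subset.

    Sum of branch lengths on the paths from the sampled tips to their most
    recent common ancestor, plus the MRCA-to-root path when ``include_root``
    (default, matching the convention under which a single tip's PD is its
    full root path).
    """
    tips = set(tips)
    if not tips:
        raise ValueError("tip set is empty")
    _check_tree(tree)
    by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    unknown = tips - set(by_label)
    if unknown:
        raise ValueError(f"unknown tip labels: {sorted(unknown)}")
    # mark every edge on a tip-to-root path
    marked = set()
    for label in tips:
        node = by_label[label]
        while node is not None:
            marked.add(node)
            node = node.parent_node
    if include_root:
        # sum in preorder for run-to-run bitwise reproducibility
        return sum(
            (n.edge.length or 0.0)
            for n in tree.preorder_node_iter()
            if n in marked and n.parent_node is not None
        )
    # exclude the root path: the MRCA is the deepest node whose marked
    # subtree covers all sampled tips — walk down from the root while
    # exactly one child is marked
    mrca = tree.seed_node
    while True:
        marked_children = [ch for ch in mrca.child_nodes() if ch in marked]
        if len(marked_children) == 1:
            mrca = marked_children[0]
        else:
            break
    below = set()
    stack = [mrca]
    while stack:
        n = stack.pop()
        for ch in n.child_nodes():
            if ch in marked:
                below.add(ch)
                stack.append(ch)
    return sum(
        (n.edge.length or 0.0) for n in tree.preorder_node_iter() if n in below
    )


def expected_pd(tree: dendropy.Tree, sampling_p: float) -> float:
    """Closed-form expected Faith's PD under binomial tip sampling.

    Each tip is sampled independently with probability ``sampling_p``; a
    branch contributes its length whenever at least one descendant tip is
    sampled: E[PD] = sum_b L_b (1 - (1 - p)^{n_b}), the root-inclusive
    convention matching :func:`faith_pd` with ``include_root=True`` (an
    empty sample contributes PD 0).
    """
    if not 0 <= sampling_p <= 1:
        raise ValueError("sampling_p must lie in [0, 1]")
    _check_tree(tree)
    q = 1.0 - sampling_p
    total = 0.0
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        n_tips = sum(1 for _ in node.leaf_iter())
        total += (node.edge.length or 0.0) * (1.0 - q**n_tips)
    return total
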