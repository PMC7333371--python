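"""Permutation null for multi-tissue differential expression of catalog genes.

The observed statistic is, per catalog gene, the number of tissues where it
passes the significance filter (adjusted p < alpha and |effect| above a
fold-change floor, directionally). The null scrambles each tissue's
(p, effect) pairs uniformly across that tissue's genes — pairs are never
split, tissues are scrambled independently — and re-applies the filter, so
a catalog gene is significant-up in tissue t with probability
m_t / G_t (significant-up count over genes present). The number of tissues
a gene clears by chance is then Poisson-binomial, which provides an
analytic oracle for the simulation estimate. The call threshold k* is the
smallest k with P(count > k) < 0.05 under the null; observed genes
exceeding k* in a direction are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NullTissueDistribution",
    "scramble_tissue",
    "significant_sets",
    "tissue_counts",
    "null_distribution",
    "poisson_binomial_tail",
    "call_multitissue",
]

FC_MIN_DEFAULT = math.log2(1.5)

REQUIRED_COLUMNS = ("tissue", "gene", "p_adj", "log2fc50")


def _validate(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    if table.duplicated(["tissue", "gene"]).any():
        raise ValueError("duplicate (tissue, gene) rows in DEG table")


@dataclass
class NullTissueDistribution:
    """Null tail probabilities of the per-gene multi-tissue count.

    ``tail_up[k]`` estimates P(a catalog gene is significant-up in MORE THAN
    k tissues by chance); ``k_star_up`` is the smallest k with that
    probability < 0.05 (analogously down).
    """

    tail_up: np.ndarray
    tail_down: np.ndarray
    k_star_up: int | None
    k_star_down: int | None
    n_sim: int
    seed: int
    tissues: tuple[str, ...] = field(default_factory=tuple)
    alpha: float = 0.05
    effect_min: float = FC_MIN_DEFAULT


def scramble_tissue(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Permute (p_adj, effect) pairs across genes within each tissue.

    Pairs stay intact; each tissue is permuted independently; the per-tissue
    multiset of pairs (and hence every pair-level filter count) is
    preserved exactly.
    """
    _validate(table)
    out = table.copy()
    for _, idx in out.groupby("tissue", sort=False).indices.items():
        perm = rng.permutation(len(idx))
        out.iloc[idx, out.columns.get_loc("p_adj")] = (
            table["p_adj"].to_numpy()[idx][perm]
        )
        out.iloc[idx, out.columns.get_loc("log2fc50")] = (
            table["log2fc50"].to_numpy()[idx][perm]
        )
    return out


def significant_sets(
    table: pd.DataFrame,
    alpha: float = 0.05,
    effect_min: float = FC_MIN_DEFAULT,
) -> dict[str, dict[str, set]]:
    """Per-tissue up/down significant gene sets.

    up = {p_adj < alpha and effect > effect_min};
    down = {p_adj < alpha and effect < -effect_min}.
    Input p-values are taken as already multiple-testing adjusted per tissue.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if effect_min <= 0:
        raise ValueError("effect_min must be > 0")
    _validate(table)
    sets: dict[str, dict[str, set]] = {}
    sig = table[table["p_adj"] < alpha]
    for tissue, block in table.groupby("tissue", sort=True):
        b = sig[sig["tissue"] == tissue]
        sets[tissue] = {
            "up": set(b.loc[b["log2fc50"] > effect_min, "gene"]),
            "down": set(b.loc[b["log2fc50"] < -effect_min, "gene"]),
        }
    return sets


def tissue_counts(
    sets: dict[str, dict[str, set]], genes: list[str]
) -> pd.DataFrame:
    """Per-gene number of tissues carrying it in the up / down set."""
    rows = [
        (
            g,
            sum(g in s["up"] for s in sets.values()),
            sum(g in s["down"] for s in sets.values()),
        )
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene", "n_up", "n_down"]).set_index("gene")


def null_distribution(
    table: pd.DataFrame,
    genes: list[str],
    n_sim: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    effect_min: float = FC_MIN_DEFAULT,
) -> NullTissueDistribution:
    """Scrambling null for the per-gene multi-tissue significance count.

    Each simulation permutes every tissue's (p, effect) pairs, re-applies
    the significance filter and records each catalog gene's (n_up, n_down);
    P(count > k) is the fraction of (simulation x gene) observations
    exceeding k, pooled across the catalog genes' tissue-presence patterns
    (a gene absent from a tissue's table cannot be significant there).
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not genes:
        raise ValueError("gene list is empty")
    _validate(table)
    rng = np.random.default_rng(seed)
    tissues = sorted(table["tissue"].unique())
    n_t = len(tissues)
    n_g = len(genes)
    # per tissue: boolean pass vectors over that tissue's rows, and the row
    # slot each catalog gene occupies (-1 when absent)
    per_tissue = []
    for t in tissues:
        block = table[table["tissue"] == t]
        pv = block["p_adj"].to_numpy()
        ev = block["log2fc50"].to_numpy()
        sig = pv < alpha
        up = sig & (ev > effect_min)
        down = sig & (ev < -effect_min)
        pos = {g: i for i, g in enumerate(block["gene"].to_numpy())}
        slots = np.array([pos.get(g, -1) for g in genes])
        per_tissue.append((up, down, slots, len(block)))
    counts_up = np.zeros((n_sim, n_g), dtype=np.int32)
    counts_down = np.zeros((n_sim, n_g), dtype=np.int32)
    for s in range(n_sim):
        for up, down, slots, size in per_tissue:
            perm = rng.permutation(size)
            present = slots >= 0
            assigned = perm[slots[present]]
            counts_up[s, present] += up[assigned]
            counts_down[s, present] += down[assigned]
    ks = np.arange(n_t + 1)
    tail_up = np.array([(counts_up > k).mean() for k in ks])
    tail_down = np.array([(counts_down > k).mean() for k in ks])
    k_star_up = next((int(k) for k in ks if tail_up[k] < 0.05), None)
    k_star_down = next((int(k) for k in ks if tail_down[k] < 0.05), None)
    return NullTissueDistribution(
        tail_up=tail_up,
        tail_down=tail_down,
        k_star_up=k_star_up,
        k_star_down=k_star_down,
        n_sim=n_sim,
        seed=seed,
        tissues=tuple(tissues),
        alpha=alpha,
        effect_min=effect_min,
    )


def poisson_binomial_tail(per_tissue_probs, k: int) -> float:
    """Exact P(count > k) for independent non-identical Bernoulli trials.

    Dynamic programming over tissues: after each tissue the vector holds the
    distribution of the running significant-tissue count.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    probs = np.asarray(list(per_tissue_probs), dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    dist = np.array([1.0])
    for p in probs:
        new = np.zeros(dist.size + 1)
        new[:-1] += dist * (1.0 - p)
        new[1:] += dist * p
        dist = new
    return float(dist[k + 1 :].sum()) if k + 1 < dist.size else 0.0


def call_multitissue(
    observed: pd.DataFrame, null: NullTissueDistribution
) -> pd.DataFrame:
    """Flag genes significant in more tissues than the null allows.

    ``observed`` is the frame from :func:`tissue_counts`. A gene is flagged
    up when n_up > k_star_up (strict), down when n_down > k_star_down; with
    an undefined k* (chance alone clears every k at >= 5%) nothing is
    flagged in that direction.
    """
    if observed[["n_up", "n_down"]].to_numpy().max(initial=0) > len(null.tissues):
        raise ValueError("observed counts exceed the null's tissue panel")
    out = observed.copy()
    out["flag_up"] = (
        observed["n_up"] > null.k_star_up if null.k_star_up is not None else False
    )
    out["flag_down"] = (
        observed["n_down"] > null.k_star_down
        if null.k_star_down is not None
        else False
    )
    return out
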