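"""Directional gene-set overlap statistics.

Fisher's exact / hypergeometric overlap tests with Benjamini-Hochberg
correction, the dual-direction background adjustment (a gene differentially
expressed in both directions across tissues is counted once in each
directional list and once extra in the universe), signed -log2(p) heat
values for enrichment/depletion matrices, and Wilcoxon rank-sum tests for
fold-change distribution shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapResult",
    "fisher_overlap",
    "bh_adjust",
    "dual_direction_background",
    "directional_heat",
    "fc_shift_test",
]


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_overlap: int
    universe: int
    odds_ratio: float
    p: float
    p_adj: float | None
    direction: str  # "enriched" or "depleted"
    alternative: str


def fisher_overlap(
    set_a: set, set_b: set, universe: set, alternative: str = "greater"
) -> OverlapResult:
    """Fisher's exact test on the 2x2 overlap table of two gene sets.

    The table counts (in both / in a only / in b only / in neither) over the
    universe. ``direction`` is "enriched" when the observed overlap exceeds
    the chance expectation a*b/N. The sample odds ratio uses the convention
    inf for a zero denominator cell and 0 for an empty ``set_a``.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    if alternative not in {"greater", "less", "two-sided"}:
        raise ValueError("alternative must be greater, less or two-sided")
    big_n = len(universe)
    a, b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    table = [[k, a - k], [b - k, big_n - a - b + k]]
    if a == 0 or b == 0:
        p, odds = 1.0, 0.0
    else:
        _, p = stats.fisher_exact(table, alternative=alternative)
        num = k * (big_n - a - b + k)
        den = (a - k) * (b - k)
        odds = np.inf if den == 0 and num > 0 else (0.0 if den == 0 else num / den)
    expected = a * b / big_n if big_n else 0.0
    return OverlapResult(
        n_a=a, n_b=b, n_overlap=k, universe=big_n,
        odds_ratio=float(odds), p=float(min(1.0, p)), p_adj=None,
        direction="enriched" if k > expected else "depleted",
        alternative=alternative,
    )


def bh_adjust(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dual_direction_background(
    up_sets: dict[str, set], down_sets: dict[str, set], genome: set
) -> dict:
    """Background adjustment for genes differentially expressed both ways.

    A gene that appears in an up set of one tissue and a down set of another
    would be double-counted when pooling directional lists; it is kept once
    in each pooled directional list and the universe size grows by one per
    such gene to compensate. Returns the pooled directional sets, the set of
    dual-direction genes, and the inflated universe size for
    :func:`fisher_overlap`-style counting.
    """
    up_all = set().union(*up_sets.values()) if up_sets else set()
    down_all = set().union(*down_sets.values()) if down_sets else set()
    if not (up_all <= genome and down_all <= genome):
        raise ValueError("directional sets must be subsets of the genome")
    dual = up_all & down_all
    return {
        "up": up_all,
        "down": down_all,
        "dual": dual,
        "universe_size": len(genome) + len(dual),
    }


def _one_sided_ps(k: int, a: int, b: int, big_n: int) -> tuple[float, float]:
    """(enrichment, depletion) hypergeometric tails for overlap k."""
    p_enr = float(stats.hypergeom.sf(k - 1, big_n, a, b))
    p_dep = float(stats.hypergeom.cdf(k, big_n, a, b))
    return min(1.0, p_enr), min(1.0, p_dep)


def directional_heat(
    cs_sets: dict[str, set],
    tissue_sets: dict[str, set],
    universe: set,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Signed -log2(p) heat matrix of per-tissue overlap enrichment.

    For each (gene set, tissue) cell: heat = -log2(p_enriched) when the
    observed overlap exceeds its expectation, +log2(p_depleted) when below,
    0 at the expectation. Positive heat therefore means more overlap than
    chance. Stars mark cells whose (direction-chosen) p survives BH
    correction across the whole matrix at ``alpha``. Cells with an empty
    tissue set are undefined (NaN).
    """
    universe = set(universe)
    big_n = len(universe)
    names, tissues = list(cs_sets), list(tissue_sets)
    heat = pd.DataFrame(np.nan, index=names, columns=tissues)
    pmat = pd.DataFrame(np.nan, index=names, columns=tissues)
    for name in names:
        sa = set(cs_sets[name])
        if not sa <= universe:
            raise ValueError(f"gene set {name} not within universe")
        for t in tissues:
            sb = set(tissue_sets[t])
            if not sb:
                continue
            if not sb <= universe:
                raise ValueError(f"tissue set {t} not within universe")
            k = len(sa & sb)
            p_enr, p_dep = _one_sided_ps(k, len(sa), len(sb), big_n)
            expected = len(sa) * len(sb) / big_n
            if k > expected:
                heat.at[name, t] = -np.log2(p_enr)
                pmat.at[name, t] = p_enr
            elif k < expected:
                heat.at[name, t] = np.log2(p_dep)
                pmat.at[name, t] = p_dep
            else:
                heat.at[name, t] = 0.0
                pmat.at[name, t] = 1.0
    flat = pmat.to_numpy().ravel()
    defined = np.isfinite(flat)
    adj = np.full(flat.shape, np.nan)
    if defined.any():
        adj[defined] = bh_adjust(flat[defined])
    p_adj = pd.DataFrame(adj.reshape(pmat.shape), index=names, columns=tissues)
    return {"heat": heat, "p": pmat, "p_adj": p_adj, "significant": p_adj < alpha}


def fc_shift_test(values_subset, values_genome) -> dict:
    """Two-sided Wilcoxon rank-sum test for a fold-change distribution shift.

    Exact null distribution when the combined sample size is <= 20 and there
    are no ties; normal approximation with continuity correction otherwise.
    Also reports the sign of (subset median - genome median).
    """
    x = np.asarray(list(values_subset), dtype=float)
    y = np.asarray(list(values_genome), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    med_diff = float(np.median(x) - np.median(y))
    return {
        "p": float(res.pvalue),
        "median_diff_sign": int(np.sign(med_diff)),
        "median_diff": med_diff,
        "method": method,
    }
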