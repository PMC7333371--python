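"""Directional overlap enrichment of gene sets against tissue DEG lists.

Tests whether a gene set overlaps per-tissue differentially expressed
genes more (or less) than chance, reporting signed -log2(p) heat values:
positive = enriched, negative = depleted, stars after BH correction.
"""

from senonet.overlap import directional_heat, fisher_overlap
from senonet.synthetic import gen_deg_tables
from senonet.tissue_perm import significant_sets

tissues = {"adipose": 30, "artery": 30, "lung": 5}
deg = gen_deg_tables(300, tissues, {t: 10 for t in tissues}, seed=8)
sets = significant_sets(deg)
universe = set(deg["gene"].unique())

# a gene set overlapping adipose's up-genes heavily, lung's not at all
cs = {"cs_like": set(list(sets["adipose"]["up"])[:20]) | set(list(universe)[:30])}
heat = directional_heat(cs, {t: s["up"] for t, s in sets.items()}, universe)
print("heat (signed -log2 p):")
print(heat["heat"].round(2).to_string())
print("significant after BH:")
print(heat["significant"].to_string())

res = fisher_overlap(cs["cs_like"], sets["adipose"]["up"], universe)
print(f"adipose overlap: {res.n_overlap}/{res.n_b} genes, "
      f"odds ratio {res.odds_ratio:.1f}, p {res.p:.2e} ({res.direction})")
print("Positive heat marks tissues where the set is over-represented among "
      "age-regulated genes.")
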