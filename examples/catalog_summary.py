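"""Summarize a senescence gene catalog by effect class.

Builds a catalog with the published class sizes (153 inducers, 121
inhibitors, 5 context-dependent genes) and prints the share of each class.
"""

from senonet.catalog import catalog_from_counts, catalog_summary

summary = catalog_summary(catalog_from_counts(153, 121, 5))
print(f"total genes: {summary['total']}")
for effect, pct in summary["pct_effect"].items():
    print(f"  {effect:9s}: {summary['by_effect'][effect]:4d} ({pct}%)")
print("Most catalog genes induce senescence; a small minority do either "
      "depending on cellular context.")
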