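"""The curated senescence gene catalog: reading, validation and summaries."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from senonet.screen import round1

__all__ = ["GeneCatalog", "read_catalog", "catalog_summary", "catalog_from_counts"]

EFFECTS = ("induces", "inhibits", "unclear")
SENESCENCE_TYPES = ("replicative", "stress", "oncogene")


@dataclass
class GeneCatalog:
    """Annotated seed-gene records.

    Each record carries the gene's effect on senescence (induces / inhibits /
    unclear — unclear genes do both depending on context), the senescence
    types it affects (a gene may carry several), and cell-line annotations.
    """

    table: pd.DataFrame
    source: str = ""

    def __len__(self) -> int:
        return len(self.table)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def effect_genes(self, effect: str) -> set[str]:
        if effect not in EFFECTS:
            raise ValueError(f"unknown effect {effect!r}")
        return set(self.table.loc[self.table["effect"] == effect, "gene"])


def _parse_types(raw: str) -> tuple[str, ...]:
    parts = tuple(
        t.strip().lower() for t in str(raw).split(";") if t.strip()
    )
    unknown = set(parts) - set(SENESCENCE_TYPES)
    if unknown:
        raise ValueError(f"unknown senescence type(s): {sorted(unknown)}")
    if not parts:
        raise ValueError("each record needs >= 1 senescence type")
    return parts


def read_catalog(path) -> GeneCatalog:
    """Read and validate a catalog CSV.

    Required columns: gene, effect, senescence_types (semicolon-separated
    subset of replicative/stress/oncogene); optional: fibroblast_only,
    cell_lines. Effects are normalized case-insensitively; duplicate symbols
    are rejected with their row numbers.
    """
    raw = pd.read_csv(path, dtype=str).fillna("")
    missing = {"gene", "effect", "senescence_types"} - set(raw.columns)
    if missing:
        raise ValueError(f"catalog missing columns: {sorted(missing)}")
    genes = raw["gene"].str.strip()
    dup = genes[genes.duplicated(keep=False)]
    if len(dup):
        rows = [str(i + 2) for i in dup.index]  # header is line 1
        raise ValueError(
            f"duplicated gene symbol(s) {sorted(set(dup))} at csv lines {', '.join(rows)}"
        )
    effects = raw["effect"].str.strip().str.lower()
    bad = ~effects.isin(EFFECTS)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise ValueError(
            f"unknown effect {raw['effect'][bad.idxmax()]!r} at csv line {row}"
        )
    table = pd.DataFrame(
        {
            "gene": genes,
            "effect": effects,
            "senescence_types": [_parse_types(v) for v in raw["senescence_types"]],
        }
    )
    if "fibroblast_only" in raw.columns:
        table["fibroblast_only"] = (
            raw["fibroblast_only"].str.strip().str.lower().isin({"true", "1", "yes"})
        )
    else:
        table["fibroblast_only"] = False
    table["cell_lines"] = raw.get("cell_lines", pd.Series([""] * len(raw))).fillna("")
    return GeneCatalog(table=table, source=str(path))


def catalog_summary(catalog: GeneCatalog) -> dict:
    """Counts and one-decimal percentages by effect and senescence type.

    Percentages are 100 x count / total, rounded half-up to one decimal.
    Senescence-type counts may overlap (a gene can carry several types), so
    they can sum to more than the catalog size.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    total = len(catalog)
    by_effect = {e: int((catalog.table["effect"] == e).sum()) for e in EFFECTS}
    by_type = {
        t: int(catalog.table["senescence_types"].apply(lambda ts: t in ts).sum())
        for t in SENESCENCE_TYPES
    }
    return {
        "total": total,
        "by_effect": by_effect,
        "pct_effect": {e: round1(100.0 * c / total) for e, c in by_effect.items()},
        "by_type": by_type,
        "pct_type": {t: round1(100.0 * c / total) for t, c in by_type.items()},
    }


def catalog_from_counts(
    n_induces: int, n_inhibits: int, n_unclear: int, seed: int = 0
) -> GeneCatalog:
    """Synthetic catalog with the given effect-class sizes.

    Stand-in for a curated catalog when only the class counts matter (e.g.
    summary statistics); gene symbols are placeholders, every record is
    tagged replicative.
    """
    rows = []
    idx = 0
    for effect, n in (
        ("induces", n_induces),
        ("inhibits", n_inhibits),
        ("unclear", n_unclear),
    ):
        for _ in range(n):
            idx += 1
            rows.append((f"CSG{idx:04d}", effect, ("replicative",), False, ""))
    table = pd.DataFrame(
        rows,
        columns=["gene", "effect", "senescence_types", "fibroblast_only", "cell_lines"],
    )
    return GeneCatalog(table=table, source=f"synthetic(seed={seed})")
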