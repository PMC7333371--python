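"""Readers and writers for the plain-text formats the pipeline exchanges.

Multi-column tables are comma-separated with a header; interaction edge
lists are tab-separated (the convention of network tooling) or SIF
(``nodeA pp nodeB``). Every writer round-trips losslessly through its
reader.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_sif",
    "write_sif",
    "read_expression",
    "write_expression",
    "read_deg_table",
    "write_deg_table",
    "read_gene_set",
    "write_gene_set",
    "read_screen",
    "write_screen",
    "read_tree",
    "write_tree",
]


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column tab-separated edge list (no header)."""
    edges = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected two tab-separated columns")
        edges.append((parts[0].strip(), parts[1].strip()))
    return edges


def write_edge_list(edges, path) -> None:
    Path(path).write_text("".join(f"{u}\t{v}\n" for u, v in edges))


def read_sif(path) -> list[tuple[str, str]]:
    """SIF interaction lines ``nodeA <relation> nodeB``."""
    edges = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 'nodeA relation nodeB'")
        edges.append((parts[0], parts[2]))
    return edges


def write_sif(edges, path, relation: str = "pp") -> None:
    Path(path).write_text("".join(f"{u} {relation} {v}\n" for u, v in edges))


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_deg_table(path) -> pd.DataFrame:
    """Per-tissue differential-expression CSV (tissue,gene,p_adj,log2fc50)."""
    table = pd.read_csv(path)
    missing = {"tissue", "gene", "p_adj", "log2fc50"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: DEG table missing columns {sorted(missing)}")
    return table


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_gene_set(path) -> set[str]:
    """One gene symbol per line (blank lines ignored)."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def write_gene_set(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_screen(path) -> pd.DataFrame:
    """Screen measurement CSV (experiment,well,sirna,role,<markers...>)."""
    table = pd.read_csv(path)
    missing = {"experiment", "well", "sirna", "role"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: screen table missing columns {sorted(missing)}")
    return table


def write_screen(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_tree(path) -> dendropy.Tree:
    """Rooted newick tree with branch lengths."""
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))
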