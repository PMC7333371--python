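"""Catalog parsing/summary, file round-trips, CLI smoke, pipeline determinism."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from senonet import io as snio
from senonet.catalog import catalog_from_counts, catalog_summary, read_catalog
from senonet.cli import main
from senonet.pipeline import RunConfig, run_pipeline
from senonet.synthetic import gen_deg_tables, gen_expression, gen_tree


def write_catalog_csv(path, rows):
    lines = ["gene,effect,senescence_types,fibroblast_only,cell_lines"]
    lines += [",".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestCatalog:
    def test_published_counts_summary(self, tmp_path):
        # 153 inducers, 121 inhibitors, 5 unclear -> 279 total
        cat = catalog_from_counts(153, 121, 5)
        summary = catalog_summary(cat)
        assert summary["total"] == 279
        assert summary["pct_effect"]["induces"] == 54.8
        assert summary["pct_effect"]["inhibits"] == 43.4
        assert summary["pct_effect"]["unclear"] == 1.8

    def test_read_normalizes_effect_case(self, tmp_path):
        p = tmp_path / "cat.csv"
        write_catalog_csv(p, [("TP53", "Induces", "replicative;stress", "false", "HFF")])
        cat = read_catalog(p)
        assert cat.table.at[0, "effect"] == "induces"
        assert cat.table.at[0, "senescence_types"] == ("replicative", "stress")

    def test_duplicate_symbol_names_rows(self, tmp_path):
        p = tmp_path / "cat.csv"
        write_catalog_csv(
            p,
            [("TP53", "induces", "replicative", "false", ""),
             ("CDK4", "inhibits", "replicative", "false", ""),
             ("TP53", "inhibits", "stress", "false", "")],
        )
        with pytest.raises(ValueError, match="TP53.*lines 2, 4"):
            read_catalog(p)

    def test_unknown_effect_rejected_with_location(self, tmp_path):
        p = tmp_path / "cat.csv"
        write_catalog_csv(p, [("TP53", "activates", "replicative", "false", "")])
        with pytest.raises(ValueError, match="line 2"):
            read_catalog(p)

    def test_type_counts_can_overlap(self):
        cat = catalog_from_counts(2, 1, 0)
        cat.table.at[0, "senescence_types"] = ("replicative", "stress")
        summary = catalog_summary(cat)
        assert summary["by_type"]["replicative"] == 3
        assert summary["by_type"]["stress"] == 1

    def test_empty_effect_class_is_zero(self):
        summary = catalog_summary(catalog_from_counts(3, 2, 0))
        assert summary["pct_effect"]["unclear"] == 0.0


class TestRoundTrips:
    def test_edge_list(self, tmp_path):
        edges = [("a", "b"), ("b", "c")]
        p = tmp_path / "e.tsv"
        snio.write_edge_list(edges, p)
        assert snio.read_edge_list(p) == edges

    def test_sif(self, tmp_path):
        edges = [("a", "b"), ("b", "c")]
        p = tmp_path / "e.sif"
        snio.write_sif(edges, p)
        assert snio.read_sif(p) == edges

    def test_expression_tsv(self, tmp_path):
        expr = gen_expression(2, 3, 1, 5, 0.5, seed=0).matrix
        p = tmp_path / "x.tsv"
        snio.write_expression(expr, p)
        pd.testing.assert_frame_equal(snio.read_expression(p), expr)

    def test_deg_csv(self, tmp_path):
        deg = gen_deg_tables(20, {"t1": 3}, {"t1": 2}, seed=0)
        p = tmp_path / "deg.csv"
        snio.write_deg_table(deg, p)
        pd.testing.assert_frame_equal(snio.read_deg_table(p), deg)

    def test_gene_set(self, tmp_path):
        genes = {"TP53", "CDKN2A", "RB1"}
        p = tmp_path / "genes.txt"
        snio.write_gene_set(genes, p)
        assert snio.read_gene_set(p) == genes

    def test_tree_newick(self, tmp_path):
        tree = gen_tree(6, seed=0)
        p = tmp_path / "t.nwk"
        snio.write_tree(tree, p)
        back = snio.read_tree(p)
        assert {l.taxon.label for l in back.leaf_node_iter()} == {
            l.taxon.label for l in tree.leaf_node_iter()
        }


class TestCLI:
    def test_simulate_and_build_net(self, tmp_path):
        runner = CliRunner()
        edges, seeds, out = tmp_path / "e.tsv", tmp_path / "s.txt", tmp_path / "net.tsv"
        r = runner.invoke(main, [
            "simulate", "graph", "--n-nodes", "60", "--m-attach", "2",
            "--seed-fraction", "0.2", "--seed", "1",
            "--out", str(edges), "--seeds-out", str(seeds),
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "build-net", "--mode", "ppi", "--edges", str(edges),
            "--seeds", str(seeds), "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        assert out.exists() and "nodes=" in r.output

    def test_pd_commands(self, tmp_path):
        runner = CliRunner()
        tree, tips = tmp_path / "t.nwk", tmp_path / "tips.txt"
        tree.write_text("((A:1,B:1):1,C:2);\n")
        tips.write_text("A\nB\n")
        r = runner.invoke(main, ["pd", "--tree", str(tree), "--tips", str(tips)])
        assert r.exit_code == 0 and float(r.output) == pytest.approx(3.0)
        r = runner.invoke(main, ["pd-expected", "--tree", str(tree), "--p", "0.5"])
        assert r.exit_code == 0 and float(r.output) == pytest.approx(2.75)

    def test_input_error_exit_code(self, tmp_path):
        runner = CliRunner()
        tree, tips = tmp_path / "t.nwk", tmp_path / "tips.txt"
        tree.write_text("((A:1,B:1):1,C:2);\n")
        tips.write_text("NOT_A_TIP\n")
        r = runner.invoke(main, ["pd", "--tree", str(tree), "--tips", str(tips)])
        assert r.exit_code == 1

    def test_screen_command(self, tmp_path):
        from senonet.synthetic import SyntheticScreenTruth, gen_screen

        runner = CliRunner()
        screen = tmp_path / "screen.csv"
        truth = SyntheticScreenTruth(
            designed_hit={"hit": frozenset({"ki67", "cell_number", "cell_area"})},
            default_shift=4.0,
        )
        snio.write_screen(gen_screen(4, truth, 2, 5, seed=0), screen)
        z_out, hits_out = tmp_path / "z.csv", tmp_path / "hits.json"
        r = runner.invoke(main, [
            "screen", "--measurements", str(screen),
            "--z-out", str(z_out), "--hits-out", str(hits_out),
        ])
        assert r.exit_code == 0, r.output
        hits = json.loads(hits_out.read_text())
        assert "hit" in hits["top_hits"]


class TestPipeline:
    def test_smoke_and_determinism(self, tmp_path):
        cfg = dict(
            seed=5, n_modules=2, genes_per_module=5, n_noise=10, n_samples=40,
            ppi_nodes=80, n_genes=120, n_tissues=4, sig_per_tissue=10,
            n_sim=50, n_targets=5, wells_per_condition=4, n_tips=8,
        )
        m1 = run_pipeline(RunConfig(out_dir=str(tmp_path / "r1"), **cfg))
        m2 = run_pipeline(RunConfig(out_dir=str(tmp_path / "r2"), **cfg))
        assert m1["report"] == m2["report"]
        assert m1["inputs"] == m2["inputs"]  # byte-identical input files
        for name in ("manifest.json", "topology.csv", "screen_hits.json"):
            assert (tmp_path / "r1" / name).exists()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=3, n_tips=11)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert RunConfig.from_yaml(p) == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError):
            RunConfig.from_yaml(p)
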