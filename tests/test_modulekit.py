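"""Homolog-module construction and the non-redundant collection filter."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from smap.modulekit import (Module, ProteinAlignment, build_homolog_collection,
                            build_homolog_modules, expand_singletons,
                            filter_redundant, load_functional_modules,
                            read_blast_tabular, reduce_alignments, size_class)


def pairs_frame(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "e_value", "coverage"])


class TestReduceAlignments:
    MAP = {"p1": "a", "p2": "b", "p3": "g1", "p4": "g1", "p5": "g1", "p6": "g2"}

    def test_most_significant_alignment_wins(self):
        alns = [ProteinAlignment("p1", "p2", 1e-80, 0.9),
                ProteinAlignment("p1", "p2", 1e-60, 0.95)]
        df = reduce_alignments(alns, self.MAP)
        assert len(df) == 1
        assert df.loc[0, "e_value"] == 1e-80 and df.loc[0, "coverage"] == 0.9

    def test_evalue_tie_broken_by_coverage(self):
        alns = [ProteinAlignment("p1", "p2", 1e-80, 0.6),
                ProteinAlignment("p2", "p1", 1e-80, 0.8)]
        df = reduce_alignments(alns, self.MAP)
        assert df.loc[0, "coverage"] == 0.8

    def test_self_gene_pairs_removed(self):
        # three proteins of gene g1 aligning among themselves -> nothing
        alns = [ProteinAlignment("p3", "p4", 0.0, 1.0),
                ProteinAlignment("p4", "p5", 1e-200, 1.0)]
        assert reduce_alignments(alns, self.MAP).empty

    def test_multiple_proteins_collapse_to_one_gene_pair(self):
        # 3 proteins of g1 each hitting g2 -> one (g1, g2) record, min e-value
        alns = [ProteinAlignment("p3", "p6", 1e-40, 0.7),
                ProteinAlignment("p4", "p6", 1e-90, 0.6),
                ProteinAlignment("p5", "p6", 1e-50, 0.9)]
        df = reduce_alignments(alns, self.MAP)
        assert len(df) == 1
        assert (df.loc[0, "gene_a"], df.loc[0, "gene_b"]) == ("g1", "g2")
        assert df.loc[0, "e_value"] == 1e-90

    def test_unmapped_protein_skipped_and_counted(self):
        alns = [ProteinAlignment("p1", "nope", 1e-90, 0.9),
                ProteinAlignment("p1", "p2", 1e-90, 0.9)]
        df = reduce_alignments(alns, self.MAP)
        assert len(df) == 1 and df.attrs["n_skipped"] == 1


class TestBuildHomologModules:
    def test_transitive_components(self):
        df = pairs_frame([("a", "b", 1e-80, 0.9), ("b", "c", 1e-75, 0.8)])
        modules, singles = build_homolog_modules(df)
        assert [set(m.genes) for m in modules] == [{"a", "b", "c"}]
        assert singles == set()

    def test_strict_thresholds(self):
        # e-value and coverage thresholds are strict
        df = pairs_frame([("a", "b", 1e-50, 0.9), ("c", "d", 1e-90, 0.5)])
        modules, singles = build_homolog_modules(df)
        assert modules == [] and singles == {"a", "b", "c", "d"}

    def test_two_components(self):
        df = pairs_frame([("a", "b", 1e-80, 0.9), ("c", "d", 1e-80, 0.9)])
        modules, _ = build_homolog_modules(df)
        assert sorted([sorted(m.genes) for m in modules]) == [["a", "b"], ["c", "d"]]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        # random graphs on <= 20 nodes vs a brute-force closure oracle
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(rng.integers(5, 20))]
        seen_pairs = set()
        rows = []
        keep_edges = []
        for _ in range(rng.integers(5, 30)):
            a, b = sorted(rng.choice(genes, 2, replace=False))
            if (a, b) in seen_pairs:
                continue
            seen_pairs.add((a, b))
            passing = rng.random() < 0.5
            rows.append((a, b, 1e-80 if passing else 1e-20, 0.9))
            if passing:
                keep_edges.append((a, b))
        df = pairs_frame(rows)
        modules, singles = build_homolog_modules(df, genes)
        oracle = nx.Graph()
        oracle.add_nodes_from(genes)
        oracle.add_edges_from(keep_edges)
        oracle_comps = sorted(sorted(c) for c in nx.connected_components(oracle)
                              if len(c) > 1)
        got = sorted(sorted(m.genes) for m in modules)
        assert got == oracle_comps
        # partition invariant: modules + singletons tile the universe
        covered = set().union(*(m.genes for m in modules)) if modules else set()
        assert covered | singles == set(genes) | set(df["gene_a"]) | set(df["gene_b"])
        assert not covered & singles


class TestExpandSingletons:
    def test_simple_absorption(self):
        mods = [Module("HOM:a", frozenset("ab"))]
        pairs = pairs_frame([("a", "s", 1e-20, 0.6)])
        out, left = expand_singletons(mods, {"s"}, pairs)
        assert set(out[0].genes) == {"a", "b", "s"} and left == set()

    def test_relaxed_cutoff_is_still_a_cutoff(self):
        mods = [Module("HOM:a", frozenset("ab"))]
        pairs = pairs_frame([("a", "s", 1e-5, 0.9)])
        out, left = expand_singletons(mods, {"s"}, pairs)
        assert left == {"s"}

    def test_two_iteration_fixed_point(self):
        # s2 joins module A through its only in-module hit in sweep one;
        # s1's best partner is s2, so s1 follows in sweep two
        mods = [Module("HOM:a", frozenset("ab"))]
        pairs = pairs_frame([("s1", "s2", 1e-15, 0.6), ("a", "s2", 1e-12, 0.7)])
        out, left = expand_singletons(mods, {"s1", "s2"}, pairs)
        assert set(out[0].genes) == {"a", "b", "s1", "s2"} and left == set()

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_growth_and_termination(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(12)]
        rows = [(min(a, b), max(a, b), 10.0 ** -rng.integers(5, 40), 0.6)
                for a, b in (rng.choice(genes, 2, replace=False) for _ in range(20))]
        df = pairs_frame(rows).drop_duplicates(["gene_a", "gene_b"])
        modules, singles = build_homolog_modules(df, genes)
        expanded, left = expand_singletons(modules, singles, df)
        for before, after in zip(modules, expanded):
            assert before.genes <= after.genes
        assert left <= singles


class TestFunctionalModules:
    def test_gmt_loading_and_disambiguation(self, tmp_path):
        (tmp_path / "go.gmt").write_text("wnt\tdesc\tg1\tg2\tg3\ncellcycle\t.\tg4\tg5\n")
        (tmp_path / "kegg.gmt").write_text("cellcycle\t.\tg5\tg6\nempty\t.\n")
        mods = load_functional_modules(
            [tmp_path / "go.gmt", tmp_path / "kegg.gmt"], ["GO", "KEGG"])
        ids = sorted(m.id for m in mods)
        assert ids == ["GO:cellcycle", "KEGG:cellcycle", "wnt"]
        assert next(m for m in mods if m.id == "wnt").genes == {"g1", "g2", "g3"}

    def test_redundancy_filter_boundaries(self):
        r = Module("r", frozenset(["g1", "g2", "g3", "g4"]), "GO")
        # 2/8 = 25% overlap with the smaller retained module -> excluded
        m = Module("m", frozenset(["g1", "g2", "x1", "x2", "x3", "x4", "x5", "x6"]), "GO")
        coll = filter_redundant([r, m], [])
        assert [x.id for x in coll.modules] == ["r"]
        assert coll.redundancy_log[0][:2] == ("m", "functional_overlap")

    def test_homolog_overlap_rule_is_strict(self):
        genes10 = [f"g{i}" for i in range(10)]
        m = Module("m", frozenset(genes10), "GO")
        h5 = Module("h5", frozenset(genes10[:5] + ["h1", "h2"]), "homolog")
        h6 = Module("h6", frozenset(genes10[:6] + ["h1"]), "homolog")
        # 5/10 = 50% is not "over half" -> retained
        assert len(filter_redundant([m], [h5]).modules) == 1
        # 6/10 = 60% -> excluded
        assert len(filter_redundant([m], [h6]).modules) == 0

    def test_order_invariance_among_equal_sizes(self):
        a = Module("a", frozenset(["g1", "g2"]), "GO")
        b = Module("b", frozenset(["g1", "g3"]), "GO")
        keep1 = [m.id for m in filter_redundant([a, b], []).modules]
        keep2 = [m.id for m in filter_redundant([b, a], []).modules]
        assert keep1 == keep2 == ["a"]


def test_size_classes():
    assert [size_class(n) for n in (1, 2, 3, 4, 5, 10, 11, 100)] == \
        ["1", "2", "3", "4", "5-10", "5-10", ">10", ">10"]
    with pytest.raises(ValueError):
        size_class(0)


def test_blast_tabular_parsing(tmp_path):
    path = tmp_path / "hits.tsv"
    base = "90.0\t100\t5\t1\t1\t100\t1\t100"
    path.write_text(
        f"p1\tp2\t{base}\t1e-80\t300\t100\t200\n"    # cov = min(1.0, 0.5)
        f"p1\tp1\t{base}\t0.0\t500\t100\t100\n")
    alns = read_blast_tabular(path)
    assert alns[0].coverage == pytest.approx(0.5)
    bad = tmp_path / "bad.tsv"
    bad.write_text("p1\tp2\tnot-enough-columns\n")
    with pytest.raises(ValueError, match="bad.tsv:1"):
        read_blast_tabular(bad)


def test_full_homolog_collection_partitions_genes():
    df = pairs_frame([("a", "b", 1e-80, 0.9), ("b", "s", 1e-20, 0.6),
                      ("x", "y", 1e-15, 0.7)])
    coll = build_homolog_collection(df, genes=["a", "b", "s", "x", "y", "z"])
    seen = {}
    for m in coll:
        for g in m.genes:
            assert g not in seen, "homolog modules must be disjoint"
            seen[g] = m.id
    assert set(seen) == {"a", "b", "s", "x", "y", "z"}
    assert set(next(m for m in coll if "a" in m.genes).genes) == {"a", "b", "s"}
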