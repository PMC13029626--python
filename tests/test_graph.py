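import numpy as np
import pytest

from krdqn.errors import GraphParseError, GraphValidationError, UnknownNodeError
from krdqn.graph import (
    DemonstrationPath,
    EntityType,
    KGEdge,
    KGNode,
    KnowledgeGraph,
    count_template_paths,
    extract_demonstration_paths,
    load_graph,
    neighbors,
    prune_graph,
)

from conftest import chain_edges, make_graph, random_layered_graph


class TestLoadGraph:
    def test_two_edge_toy(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("D1\tT1\n")
        (tmp_path / "ga.tsv").write_text("G1\tA1\n")
        g = load_graph({"drug_target": tmp_path / "dt.tsv", "gene_adr": tmp_path / "ga.tsv"})
        assert g.n_nodes == 4 and g.n_edges == 2
        assert g.entity_type("T1") is EntityType.TARGET
        assert g.entity_type("A1") is EntityType.ADR

    def test_empty_edge_files_give_empty_graph(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("")
        g = load_graph({"drug_target": tmp_path / "dt.tsv"})
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_duplicate_line_deduplicated(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("D1\tT1\nD1\tT1\n")
        g = load_graph({"drug_target": tmp_path / "dt.tsv"})
        assert g.n_edges == 1

    def test_header_and_comments_skipped(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("source\ttarget\n# comment\nD1\tT1\n")
        g = load_graph({"drug_target": tmp_path / "dt.tsv"})
        assert g.n_edges == 1

    def test_malformed_line_names_file_and_lineno(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("D1\tT1\nonly_one_column\n")
        with pytest.raises(GraphParseError, match=r"dt\.tsv:2"):
            load_graph({"drug_target": tmp_path / "dt.tsv"})

    def test_confidence_column_parsed(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("D1\tT1\t0.9\n")
        g = load_graph({"drug_target": tmp_path / "dt.tsv"})
        assert g.edges[0].confidence == pytest.approx(0.9)

    def test_type_conflict_rejected(self, tmp_path):
        # T1 used both as a target and as a pathway->gene source (pathway)
        (tmp_path / "dt.tsv").write_text("D1\tT1\n")
        (tmp_path / "pg.tsv").write_text("T1\tG1\n")
        with pytest.raises(GraphValidationError, match="T1"):
            load_graph({"drug_target": tmp_path / "dt.tsv", "pathway_gene": tmp_path / "pg.tsv"})

    def test_attribute_files_attached_and_optional(self, tmp_path):
        (tmp_path / "dt.tsv").write_text("D1\tT1\nD2\tT1\n")
        (tmp_path / "drugs.tsv").write_text("D1\tCCO\n")
        (tmp_path / "targets.fasta").write_text(">T1\nMKV\n")
        g = load_graph(
            {"drug_target": tmp_path / "dt.tsv"},
            {EntityType.DRUG: tmp_path / "drugs.tsv", EntityType.TARGET: tmp_path / "targets.fasta"},
        )
        assert g.nodes["D1"].raw_attribute == "CCO"
        assert g.nodes["T1"].raw_attribute == "MKV"
        assert g.nodes["D2"].raw_attribute is None


class TestPruneGraph:
    def test_isolated_node_removed(self):
        g = make_graph(chain_edges("D1", "T1", "P1", "G1", "A1"), extra_nodes=["T2"])
        pruned = prune_graph(g)
        assert set(pruned.nodes) == {"D1", "T1", "P1", "G1", "A1"}

    def test_low_confidence_edge_cascades(self):
        # cutting T1->P1 at confidence 0.2 orphans everything but nothing remains
        g = make_graph(
            chain_edges("D1", "T1", "P1", "G1", "A1"),
            confidences={("T1", "P1"): 0.2},
        )
        pruned = prune_graph(g, min_confidence=0.5)
        assert pruned.n_nodes == 0 and pruned.n_edges == 0

    def test_confidence_cascade_keeps_surviving_chain(self):
        edges = chain_edges("D1", "T1", "P1", "G1", "A1") + chain_edges(
            "D1", "T2", "P2", "G2", "A1"
        )
        g = make_graph(edges, confidences={("T2", "P2"): 0.1})
        pruned = prune_graph(g, min_confidence=0.5)
        assert set(pruned.nodes) == {"D1", "T1", "P1", "G1", "A1"}
        # brute-force oracle: nodes on a complete chain after edge filtering
        surviving = [e for e in g.edges if e.confidence is None or e.confidence >= 0.5]
        on_chain = set()
        for d, t in [(e.source, e.target) for e in surviving if e.relation == "drug_target"]:
            for t2, p in [(e.source, e.target) for e in surviving if e.relation == "target_pathway"]:
                if t2 != t:
                    continue
                for p2, gn in [(e.source, e.target) for e in surviving if e.relation == "pathway_gene"]:
                    if p2 != p:
                        continue
                    for g2, a in [(e.source, e.target) for e in surviving if e.relation == "gene_adr"]:
                        if g2 == gn:
                            on_chain.update([d, t, p, gn, a])
        assert set(pruned.nodes) == on_chain

    def test_unscored_edges_kept(self, chain_graph):
        assert prune_graph(chain_graph, min_confidence=0.99) == chain_graph

    def test_idempotent_on_random_graphs(self, rng):
        for _ in range(20):
            g = random_layered_graph(rng, p=rng.uniform(0.1, 0.6))
            once = prune_graph(g)
            assert prune_graph(once) == once

    def test_never_adds_nodes_or_edges(self, rng):
        for _ in range(20):
            g = random_layered_graph(rng, p=0.3)
            pruned = prune_graph(g)
            assert set(pruned.nodes) <= set(g.nodes)
            assert set(pruned.edges) <= set(g.edges)


class TestDemonstrationPaths:
    def test_single_chain(self, chain_graph):
        assert extract_demonstration_paths(chain_graph) == [
            DemonstrationPath(("D1", "T1", "P1", "G1", "A1"))
        ]

    def test_fanout_product(self):
        # 2 targets x 2 pathways each x 1 gene x 1 adr = 4 paths
        edges = [("D1", "T1"), ("D1", "T2")]
        for t in ("T1", "T2"):
            edges += [(t, "P1"), (t, "P2")]
        edges += [("P1", "G1"), ("P2", "G1"), ("G1", "A1")]
        paths = extract_demonstration_paths(make_graph(edges))
        assert len(paths) == 4

    def test_no_terminal_layer_gives_empty(self):
        g = make_graph(chain_edges("D1", "T1", "P1", "G1"))
        assert extract_demonstration_paths(g) == []

    def test_limit_truncates(self, two_chain_graph):
        assert len(extract_demonstration_paths(two_chain_graph, limit=1)) == 1

    def test_lexicographic_order_and_soundness(self, rng):
        for _ in range(10):
            g = random_layered_graph(rng, p=0.5)
            paths = extract_demonstration_paths(g)
            assert paths == sorted(paths, key=lambda p: p.node_ids)
            edge_set = {(e.source, e.target) for e in g.edges}
            for p in paths:
                types = [g.entity_type(n) for n in p.node_ids]
                assert types == list(EntityType)
                assert all(
                    (p.node_ids[i], p.node_ids[i + 1]) in edge_set for i in range(4)
                )

    def test_count_matches_bruteforce_nested_loops(self, rng):
        for _ in range(10):
            g = random_layered_graph(rng, sizes=(3, 5, 4, 5, 3), p=0.4)
            dt = [(e.source, e.target) for e in g.edges if e.relation == "drug_target"]
            tp = [(e.source, e.target) for e in g.edges if e.relation == "target_pathway"]
            pg = [(e.source, e.target) for e in g.edges if e.relation == "pathway_gene"]
            ga = [(e.source, e.target) for e in g.edges if e.relation == "gene_adr"]
            brute = sum(
                1
                for d, t in dt
                for t2, p in tp
                if t2 == t
                for p2, gn in pg
                if p2 == p
                for g2, a in ga
                if g2 == gn
            )
            assert len(extract_demonstration_paths(g)) == brute
            assert count_template_paths(g) == brute


class TestNeighbors:
    def test_ordered(self):
        g = make_graph([("D1", "T2"), ("D1", "T1")])
        assert neighbors(g, "D1") == ["T1", "T2"]

    def test_sink_is_empty(self, chain_graph):
        assert neighbors(chain_graph, "A1") == []

    def test_unknown_node_raises(self, chain_graph):
        with pytest.raises(UnknownNodeError):
            neighbors(chain_graph, "D999")

    def test_recomputed_after_prune(self):
        g = make_graph(
            chain_edges("D1", "T1", "P1", "G1", "A1") + [("D1", "T2")]
        )
        assert neighbors(g, "D1") == ["T1", "T2"]
        assert neighbors(prune_graph(g), "D1") == ["T1"]


def test_duplicate_node_rejected():
    with pytest.raises(GraphValidationError):
        KnowledgeGraph([KGNode("D1", EntityType.DRUG), KGNode("D1", EntityType.DRUG)])


def test_edge_type_mismatch_rejected():
    nodes = [KGNode("D1", EntityType.DRUG), KGNode("G1", EntityType.GENE)]
    with pytest.raises(GraphValidationError):
        KnowledgeGraph(nodes, [KGEdge("D1", "G1", "drug_target")])
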