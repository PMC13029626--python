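import numpy as np
import pytest

from krdqn.graph import EntityType, KGEdge, KGNode, KnowledgeGraph

LAYER_PREFIX = {
    EntityType.DRUG: "D",
    EntityType.TARGET: "T",
    EntityType.PATHWAY: "P",
    EntityType.GENE: "G",
    EntityType.ADR: "A",
}

RELATION_OF = {
    (EntityType.DRUG, EntityType.TARGET): "drug_target",
    (EntityType.TARGET, EntityType.PATHWAY): "target_pathway",
    (EntityType.PATHWAY, EntityType.GENE): "pathway_gene",
    (EntityType.GENE, EntityType.ADR): "gene_adr",
}


def make_graph(edge_pairs, extra_nodes=(), confidences=None):
    """Build a KnowledgeGraph from (src, dst) id pairs; entity types are
    inferred from the D/T/P/G/A id prefix."""
    type_of = {p: t for t, p in LAYER_PREFIX.items()}
    node_ids = set(extra_nodes)
    for s, t in edge_pairs:
        node_ids.update((s, t))
    nodes = [KGNode(nid, type_of[nid[0]]) for nid in sorted(node_ids)]
    confidences = confidences or {}
    edges = [
        KGEdge(s, t, RELATION_OF[(type_of[s[0]], type_of[t[0]])], confidences.get((s, t)))
        for s, t in edge_pairs
    ]
    return KnowledgeGraph(nodes, edges)


def chain_edges(*node_ids):
    return list(zip(node_ids[:-1], node_ids[1:]))


def random_layered_graph(rng, sizes=(3, 4, 3, 4, 3), p=0.5):
    """Random hierarchy-respecting graph for property tests."""
    layers = [
        [f"{LAYER_PREFIX[t]}{i}" for i in range(n)]
        for t, n in zip(EntityType, sizes)
    ]
    edges = []
    for src_layer, dst_layer in zip(layers[:-1], layers[1:]):
        for s in src_layer:
            for t in dst_layer:
                if rng.random() < p:
                    edges.append((s, t))
    all_nodes = [n for layer in layers for n in layer]
    return make_graph(edges, extra_nodes=all_nodes)


@pytest.fixture
def chain_graph():
    """The minimal single-chain instance D1-T1-P1-G1-A1."""
    return make_graph(chain_edges("D1", "T1", "P1", "G1", "A1"))


@pytest.fixture
def two_chain_graph():
    """One drug, two disjoint chains: one ends at A1, the other at A2."""
    return make_graph(
        chain_edges("D1", "T1", "P1", "G1", "A1")
        + chain_edges("D1", "T2", "P2", "G2", "A2")
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
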