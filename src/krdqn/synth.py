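"""Self-contained synthetic benchmark instances.

Generates a layered knowledge graph with planted drug -> target -> pathway
-> gene -> ADR mechanism chains, hierarchy-respecting noise edges, and
realistic node attributes: valid approved-drug SMILES from a built-in list,
random protein sequences (100-400 residues), random transcripts (300-900
nt), and pathway member-token strings drawn from each pathway's actual
neighbors. Everything is reproducible from a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._scales import AMINO_ACIDS
from ._smiles import DRUG_SMILES
from .errors import GenerationError
from .evaluate import sample_negatives
from .graph import EntityType, KGEdge, KGNode, KnowledgeGraph

_RELATION_LAYERS = {
    "drug_target": (EntityType.DRUG, EntityType.TARGET),
    "target_pathway": (EntityType.TARGET, EntityType.PATHWAY),
    "pathway_gene": (EntityType.PATHWAY, EntityType.GENE),
    "gene_adr": (EntityType.GENE, EntityType.ADR),
}


@dataclass
class SyntheticSpec:
    n_drugs: int = 40
    n_targets: int = 60
    n_pathways: int = 30
    n_genes: int = 50
    n_adrs: int = 20
    edges_per_node: float = 2.0
    planted_pairs: int = 80
    noise_edge_fraction: float = 0.2
    mechanism_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_targets", "n_pathways", "n_genes", "n_adrs"):
            if getattr(self, name) < 1:
                raise GenerationError(f"{name} must be >= 1")
        if not 0 <= self.noise_edge_fraction < 1:
            raise GenerationError("noise_edge_fraction must lie in [0, 1)")
        if self.planted_pairs > self.n_drugs * self.n_adrs:
            raise GenerationError(
                f"{self.planted_pairs} planted pairs exceed "
                f"{self.n_drugs} x {self.n_adrs} drug-ADR combinations"
            )


@dataclass(frozen=True)
class PlantedPair:
    drug: str
    adr: str
    chain: tuple[str, str, str, str, str]


def _node_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(n)]


def _random_seq(alphabet: str, length: int, rng: np.random.Generator) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


def generate_kg(spec: SyntheticSpec) -> tuple[KnowledgeGraph, list[PlantedPair]]:
    """Build the synthetic graph and its ground-truth positive pair list.

    Planted pairs are spread round-robin over drugs so every drug carries
    roughly ``planted_pairs / n_drugs`` true ADR associations. With
    probability ``mechanism_overlap`` a new pair for an already-planted ADR
    reuses an existing (target, pathway, gene) chain, so drugs sharing an
    ADR tend to share mechanism — the signal the concordance analysis
    looks for. Noise edges respect the layer hierarchy: each candidate
    (u, v) pair becomes an edge independently with probability
    ``noise_edge_fraction * edges_per_node / n_destinations``.
    """
    rng = np.random.default_rng(spec.seed)
    ids = {
        EntityType.DRUG: _node_ids("D", spec.n_drugs),
        EntityType.TARGET: _node_ids("T", spec.n_targets),
        EntityType.PATHWAY: _node_ids("P", spec.n_pathways),
        EntityType.GENE: _node_ids("G", spec.n_genes),
        EntityType.ADR: _node_ids("A", spec.n_adrs),
    }

    # -- planted mechanisms -------------------------------------------------
    planted: list[PlantedPair] = []
    used: set[tuple[str, str]] = set()
    chains_by_adr: dict[str, list[tuple[str, str, str]]] = {}
    edges: set[tuple[str, str, str]] = set()
    drug_cycle = 0
    while len(planted) < spec.planted_pairs:
        drug = ids[EntityType.DRUG][drug_cycle % spec.n_drugs]
        drug_cycle += 1
        free = [a for a in ids[EntityType.ADR] if (drug, a) not in used]
        if not free:
            continue
        adr = free[rng.integers(len(free))]
        used.add((drug, adr))
        pool = chains_by_adr.get(adr, [])
        if pool and rng.random() < spec.mechanism_overlap:
            t, p, gn = pool[rng.integers(len(pool))]
        else:
            t = ids[EntityType.TARGET][rng.integers(spec.n_targets)]
            p = ids[EntityType.PATHWAY][rng.integers(spec.n_pathways)]
            gn = ids[EntityType.GENE][rng.integers(spec.n_genes)]
            chains_by_adr.setdefault(adr, []).append((t, p, gn))
        edges.update(
            [
                (drug, t, "drug_target"),
                (t, p, "target_pathway"),
                (p, gn, "pathway_gene"),
                (gn, adr, "gene_adr"),
            ]
        )
        planted.append(PlantedPair(drug, adr, (drug, t, p, gn, adr)))

    # -- hierarchy-respecting noise edges ------------------------------------
    if spec.noise_edge_fraction > 0:
        for relation, (src_t, dst_t) in _RELATION_LAYERS.items():
            srcs, dsts = ids[src_t], ids[dst_t]
            p_edge = min(1.0, spec.noise_edge_fraction * spec.edges_per_node / len(dsts))
            mask = rng.random((len(srcs), len(dsts))) < p_edge
            for i, j in zip(*np.nonzero(mask)):
                edges.add((srcs[i], dsts[j], relation))

    # -- node attributes -----------------------------------------------------
    nodes: list[KGNode] = []
    smiles_order = rng.permutation(len(DRUG_SMILES))
    for i, nid in enumerate(ids[EntityType.DRUG]):
        nodes.append(
            KGNode(nid, EntityType.DRUG, DRUG_SMILES[smiles_order[i % len(DRUG_SMILES)]])
        )
    for nid in ids[EntityType.TARGET]:
        nodes.append(
            KGNode(nid, EntityType.TARGET,
                   _random_seq(AMINO_ACIDS, int(rng.integers(100, 401)), rng))
        )
    for nid in ids[EntityType.GENE]:
        nodes.append(
            KGNode(nid, EntityType.GENE,
                   _random_seq("ACGT", int(rng.integers(300, 901)), rng))
        )
    members: dict[str, set[str]] = {nid: set() for nid in ids[EntityType.PATHWAY]}
    for src, dst, rel in edges:
        if rel == "target_pathway":
            members[dst].add(src)
        elif rel == "pathway_gene":
            members[src].add(dst)
    for nid in ids[EntityType.PATHWAY]:
        nodes.append(
            KGNode(nid, EntityType.PATHWAY,
                   " ".join(sorted(members[nid])) if members[nid] else None)
        )
    nodes.extend(KGNode(nid, EntityType.ADR) for nid in ids[EntityType.ADR])

    g = KnowledgeGraph(nodes, [KGEdge(s, t, r) for s, t, r in sorted(edges)])
    return g, planted


def generate_eval_pairs(
    ground_truth: Sequence[PlantedPair],
    all_adrs: Sequence[str],
    rng: np.random.Generator,
) -> list[tuple[str, str, int]]:
    """Balanced labelled pair table: every planted positive plus one sampled
    negative per positive."""
    if not ground_truth:
        raise GenerationError("ground truth is empty")
    positives = [(p.drug, p.adr) for p in ground_truth]
    table = [(d, a, 1) for d, a in positives]
    table.extend(sample_negatives(positives, all_adrs, rng))
    return table


# ---------------------------------------------------------------------------
# on-disk dialects (round-trip through graph.load_graph)


def write_dataset(
    g: KnowledgeGraph,
    out_dir: str | Path,
    pairs: Sequence[tuple[str, str, int]] | None = None,
) -> dict[str, Path]:
    """Write edge TSVs, FASTA, SMILES/pathway TSVs (and optionally a pairs
    TSV) in the package's interchange dialects. Deterministic output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    by_rel: dict[str, list[KGEdge]] = {r: [] for r in _RELATION_LAYERS}
    for e in g.edges:
        by_rel[e.relation].append(e)
    for rel, rel_edges in by_rel.items():
        path = out / f"{rel}.tsv"
        lines = []
        for e in sorted(rel_edges, key=lambda e: (e.source, e.target)):
            conf = "" if e.confidence is None else f"\t{e.confidence}"
            lines.append(f"{e.source}\t{e.target}{conf}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        files[rel] = path

    def _attr(etype: EntityType) -> list[tuple[str, str]]:
        return [
            (nid, g.nodes[nid].raw_attribute)
            for nid in g.nodes_of_type(etype)
            if g.nodes[nid].raw_attribute
        ]

    fasta_t = out / "targets.fasta"
    fasta_t.write_text("".join(f">{nid}\n{seq}\n" for nid, seq in _attr(EntityType.TARGET)))
    files["target_fasta"] = fasta_t
    fasta_g = out / "genes.fasta"
    fasta_g.write_text("".join(f">{nid}\n{seq}\n" for nid, seq in _attr(EntityType.GENE)))
    files["gene_fasta"] = fasta_g
    drugs = out / "drugs.tsv"
    drugs.write_text("".join(f"{nid}\t{s}\n" for nid, s in _attr(EntityType.DRUG)))
    files["drug_smiles"] = drugs
    pathways = out / "pathways.tsv"
    pathways.write_text("".join(f"{nid}\t{m}\n" for nid, m in _attr(EntityType.PATHWAY)))
    files["pathway_members"] = pathways

    if pairs is not None:
        pairs_path = out / "pairs.tsv"
        pairs_path.write_text("".join(f"{d}\t{a}\t{l}\n" for d, a, l in pairs))
        files["pairs"] = pairs_path
    return files
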