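"""Layered biomedical knowledge graph: construction, pruning, and path queries.

The graph has five node layers — drug, target (protein), pathway, gene, ADR —
and four directed relation types that each connect one layer to the next.
All reasoning in the package (demonstration paths, the MDP, beam search)
navigates this graph strictly along the layer hierarchy.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import GraphParseError, GraphValidationError, UnknownNodeError


class EntityType(enum.Enum):
    """The five entity layers, ordered along the causal hierarchy."""

    DRUG = "drug"
    TARGET = "target"
    PATHWAY = "pathway"
    GENE = "gene"
    ADR = "adr"

    @property
    def layer(self) -> int:
        return _LAYER[self]

    def __lt__(self, other: "EntityType") -> bool:
        return self.layer < other.layer


_LAYER = {
    EntityType.DRUG: 0,
    EntityType.TARGET: 1,
    EntityType.PATHWAY: 2,
    EntityType.GENE: 3,
    EntityType.ADR: 4,
}

LAYER_ORDER: tuple[EntityType, ...] = (
    EntityType.DRUG,
    EntityType.TARGET,
    EntityType.PATHWAY,
    EntityType.GENE,
    EntityType.ADR,
)

#: relation name -> (source entity type, target entity type)
RELATIONS: dict[str, tuple[EntityType, EntityType]] = {
    "drug_target": (EntityType.DRUG, EntityType.TARGET),
    "target_pathway": (EntityType.TARGET, EntityType.PATHWAY),
    "pathway_gene": (EntityType.PATHWAY, EntityType.GENE),
    "gene_adr": (EntityType.GENE, EntityType.ADR),
}


@dataclass
class KGNode:
    node_id: str
    entity_type: EntityType
    raw_attribute: str | None = None


@dataclass(frozen=True)
class KGEdge:
    source: str
    target: str
    relation: str
    confidence: float | None = None


@dataclass(frozen=True)
class DemonstrationPath:
    """A complete drug -> target -> pathway -> gene -> ADR chain."""

    node_ids: tuple[str, str, str, str, str]

    def __iter__(self):
        return iter(self.node_ids)

    @property
    def drug(self) -> str:
        return self.node_ids[0]

    @property
    def adr(self) -> str:
        return self.node_ids[-1]


class KnowledgeGraph:
    """Typed directed graph with deterministic (lexicographic) adjacency.

    Parameters
    ----------
    nodes : iterable of KGNode
    edges : iterable of KGEdge
        Endpoint types must be consistent with each edge's relation.
    """

    def __init__(self, nodes: Iterable[KGNode] = (), edges: Iterable[KGEdge] = ()):
        self.nodes: dict[str, KGNode] = {}
        for n in nodes:
            if n.node_id in self.nodes:
                raise GraphValidationError(f"duplicate node id {n.node_id!r}")
            self.nodes[n.node_id] = n
        self.edges: list[KGEdge] = []
        seen: set[tuple[str, str, str]] = set()
        for e in edges:
            key = (e.source, e.target, e.relation)
            if key in seen:
                continue
            seen.add(key)
            self._validate_edge(e)
            self.edges.append(e)
        self._build_adjacency()

    def _validate_edge(self, e: KGEdge) -> None:
        if e.relation not in RELATIONS:
            raise GraphValidationError(f"unknown relation {e.relation!r}")
        src_t, dst_t = RELATIONS[e.relation]
        for nid, want in ((e.source, src_t), (e.target, dst_t)):
            if nid not in self.nodes:
                raise GraphValidationError(f"edge endpoint {nid!r} is not a node")
            have = self.nodes[nid].entity_type
            if have is not want:
                raise GraphValidationError(
                    f"edge {e.source}->{e.target} ({e.relation}): node {nid!r} "
                    f"is {have.value}, expected {want.value}"
                )

    def _build_adjacency(self) -> None:
        adj: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for e in self.edges:
            adj[e.source].append(e.target)
        # lexicographic ordering makes enumeration and greedy rollouts reproducible
        self.adjacency: dict[str, list[str]] = {k: sorted(set(v)) for k, v in adj.items()}

    # -- queries ------------------------------------------------------------

    def neighbors(self, node_id: str) -> list[str]:
        """Out-neighbors of ``node_id`` in deterministic lexicographic order."""
        if node_id not in self.nodes:
            raise UnknownNodeError(f"unknown node {node_id!r}")
        return list(self.adjacency[node_id])

    def entity_type(self, node_id: str) -> EntityType:
        if node_id not in self.nodes:
            raise UnknownNodeError(f"unknown node {node_id!r}")
        return self.nodes[node_id].entity_type

    def nodes_of_type(self, entity_type: EntityType) -> list[str]:
        return sorted(n.node_id for n in self.nodes.values() if n.entity_type is entity_type)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def copy(self) -> "KnowledgeGraph":
        return KnowledgeGraph(
            [KGNode(n.node_id, n.entity_type, n.raw_attribute) for n in self.nodes.values()],
            list(self.edges),
        )

    def without_node(self, node_id: str) -> "KnowledgeGraph":
        """A copy of the graph with ``node_id`` and its incident edges removed."""
        if node_id not in self.nodes:
            raise UnknownNodeError(f"unknown node {node_id!r}")
        nodes = [
            KGNode(n.node_id, n.entity_type, n.raw_attribute)
            for n in self.nodes.values()
            if n.node_id != node_id
        ]
        edges = [e for e in self.edges if node_id not in (e.source, e.target)]
        return KnowledgeGraph(nodes, edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            {k: (v.entity_type, v.raw_attribute) for k, v in self.nodes.items()}
            == {k: (v.entity_type, v.raw_attribute) for k, v in other.nodes.items()}
            and set(self.edges) == set(other.edges)
        )


# ---------------------------------------------------------------------------
# loading


def _parse_edge_file(path: Path, relation: str) -> list[KGEdge]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("source", "source_id"):
                continue
            if len(parts) not in (2, 3) or not parts[0] or not parts[1]:
                raise GraphParseError(f"{path}:{lineno}: malformed edge line {line!r}")
            conf = None
            if len(parts) == 3 and parts[2] != "":
                try:
                    conf = float(parts[2])
                except ValueError as exc:
                    raise GraphParseError(
                        f"{path}:{lineno}: bad confidence {parts[2]!r}"
                    ) from exc
            edges.append(KGEdge(parts[0], parts[1], relation, conf))
    return edges


def _parse_two_column(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2 or not parts[0]:
                raise GraphParseError(f"{path}:{lineno}: malformed attribute line {line!r}")
            out[parts[0]] = parts[1]
    return out


def _parse_fasta(path: Path) -> dict[str, str]:
    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    except (ValueError, FileNotFoundError) as exc:
        raise GraphParseError(f"{path}: {exc}") from exc


def load_graph(
    edge_files: Mapping[str, str | Path],
    node_attribute_files: Mapping[EntityType | str, str | Path] | None = None,
) -> KnowledgeGraph:
    """Assemble a :class:`KnowledgeGraph` from tab-separated edge lists.

    Parameters
    ----------
    edge_files : mapping relation name -> path
        Each file holds ``source<TAB>target[<TAB>confidence]`` lines; ``#``
        comment lines and an optional ``source``/``source_id`` header are
        skipped. Node entity types are inferred from the relation schema.
    node_attribute_files : mapping entity type -> path, optional
        FASTA for targets and genes, two-column TSV for drugs (SMILES) and
        pathways (member token list). Nodes without an attribute entry get
        ``raw_attribute=None``.
    """
    node_types: dict[str, EntityType] = {}
    all_edges: list[KGEdge] = []
    for relation, path in sorted(edge_files.items()):
        if relation not in RELATIONS:
            raise GraphValidationError(f"unknown relation {relation!r}")
        src_t, dst_t = RELATIONS[relation]
        for e in _parse_edge_file(Path(path), relation):
            for nid, want in ((e.source, src_t), (e.target, dst_t)):
                prev = node_types.setdefault(nid, want)
                if prev is not want:
                    raise GraphValidationError(
                        f"node {nid!r} used as {prev.value} and {want.value}"
                    )
            all_edges.append(e)

    attrs: dict[EntityType, dict[str, str]] = {}
    if node_attribute_files:
        for etype, path in node_attribute_files.items():
            etype = EntityType(etype) if not isinstance(etype, EntityType) else etype
            path = Path(path)
            if etype in (EntityType.TARGET, EntityType.GENE):
                attrs[etype] = _parse_fasta(path)
            elif etype in (EntityType.DRUG, EntityType.PATHWAY):
                attrs[etype] = _parse_two_column(path)
            else:
                raise GraphValidationError(f"no attribute file format for {etype.value}")

    nodes = [
        KGNode(nid, etype, attrs.get(etype, {}).get(nid))
        for nid, etype in sorted(node_types.items())
    ]
    return KnowledgeGraph(nodes, all_edges)


# ---------------------------------------------------------------------------
# pruning


def prune_graph(g: KnowledgeGraph, min_confidence: float = 0.0) -> KnowledgeGraph:
    """Apply the three curation criteria.

    1. Remove edges whose confidence is below ``min_confidence`` (edges that
       carry no confidence are always kept).
    2. Remove duplicate (source, target, relation) triples (already enforced
       by graph construction).
    3. Remove orphaned nodes: every surviving node must lie on at least one
       complete drug -> target -> pathway -> gene -> ADR chain. For a drug
       that means an outgoing chain to some ADR; for an ADR an incoming chain
       from some drug; intermediate nodes need both.
    """
    edges = [e for e in g.edges if e.confidence is None or e.confidence >= min_confidence]

    out_adj: dict[str, list[str]] = {nid: [] for nid in g.nodes}
    in_adj: dict[str, list[str]] = {nid: [] for nid in g.nodes}
    for e in edges:
        out_adj[e.source].append(e.target)
        in_adj[e.target].append(e.source)

    # can_reach_adr: computed back from the ADR layer
    can_reach = {nid: g.nodes[nid].entity_type is EntityType.ADR for nid in g.nodes}
    for etype in (EntityType.GENE, EntityType.PATHWAY, EntityType.TARGET, EntityType.DRUG):
        for n in g.nodes.values():
            if n.entity_type is etype:
                can_reach[n.node_id] = any(can_reach[m] for m in out_adj[n.node_id])

    # reachable_from_drug: computed forward from the drug layer
    from_drug = {nid: g.nodes[nid].entity_type is EntityType.DRUG for nid in g.nodes}
    for etype in (EntityType.TARGET, EntityType.PATHWAY, EntityType.GENE, EntityType.ADR):
        for n in g.nodes.values():
            if n.entity_type is etype:
                from_drug[n.node_id] = any(from_drug[m] for m in in_adj[n.node_id])

    keep = {nid for nid in g.nodes if can_reach[nid] and from_drug[nid]}
    nodes = [
        KGNode(n.node_id, n.entity_type, n.raw_attribute)
        for n in g.nodes.values()
        if n.node_id in keep
    ]
    # between two kept nodes every hierarchy edge lies on a complete chain
    kept_edges = [e for e in edges if e.source in keep and e.target in keep]
    return KnowledgeGraph(nodes, kept_edges)


# ---------------------------------------------------------------------------
# demonstration paths


def extract_demonstration_paths(
    g: KnowledgeGraph, limit: int | None = None
) -> list[DemonstrationPath]:
    """Enumerate every drug->target->pathway->gene->ADR chain.

    Depth-first over the lexicographically ordered adjacency, so the output
    order is lexicographic by node-id tuple. ``limit`` truncates the list.
    """
    paths: list[DemonstrationPath] = []
    type_of = {nid: n.entity_type for nid, n in g.nodes.items()}

    def _next(nid: str, want: EntityType) -> list[str]:
        return [m for m in g.adjacency[nid] if type_of[m] is want]

    for d in g.nodes_of_type(EntityType.DRUG):
        for t in _next(d, EntityType.TARGET):
            for p in _next(t, EntityType.PATHWAY):
                for gn in _next(p, EntityType.GENE):
                    for a in _next(gn, EntityType.ADR):
                        paths.append(DemonstrationPath((d, t, p, gn, a)))
                        if limit is not None and len(paths) >= limit:
                            return paths
    return paths


def count_template_paths(g: KnowledgeGraph) -> int:
    """Number of complete template chains, by layer-wise dynamic programming."""
    type_of = {nid: n.entity_type for nid, n in g.nodes.items()}
    count = {nid: 1 for nid in g.nodes if type_of[nid] is EntityType.ADR}
    for etype in (EntityType.GENE, EntityType.PATHWAY, EntityType.TARGET, EntityType.DRUG):
        nxt = LAYER_ORDER[etype.layer + 1]
        for nid in g.nodes_of_type(etype):
            count[nid] = sum(
                count.get(m, 0) for m in g.adjacency[nid] if type_of[m] is nxt
            )
    return sum(count.get(d, 0) for d in g.nodes_of_type(EntityType.DRUG))


def neighbors(g: KnowledgeGraph, node_id: str) -> list[str]:
    """Thin functional wrapper over :meth:`KnowledgeGraph.neighbors`."""
    return g.neighbors(node_id)
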