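"""Q-guided path search shared by scoring and explanation ranking."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env import admissible_actions, State
from .graph import EntityType, KnowledgeGraph
from .network import QNetwork


@dataclass(frozen=True)
class ScoredPath:
    """A complete template chain with its per-transition Q-values."""

    nodes: tuple[str, ...]
    step_qs: tuple[float, ...]

    @property
    def terminal_q(self) -> float:
        return self.step_qs[-1]

    @property
    def total_q(self) -> float:
        return float(sum(self.step_qs))

    @property
    def adr(self) -> str:
        return self.nodes[-1]


def beam_complete_paths(
    net: QNetwork,
    g: KnowledgeGraph,
    drug: str,
    target_adr: str,
    beam_width: int = 10,
) -> list[ScoredPath]:
    """Level-wise beam search from a drug conditioned on a target ADR.

    Partial paths are expanded layer by layer and pruned to ``beam_width``
    by the Q-value of their most recent transition; every surviving path
    that enters an ADR node (any ADR) is returned.
    """
    beams: list[tuple[tuple[str, ...], tuple[float, ...]]] = [((drug,), ())]
    complete: list[ScoredPath] = []
    for hop in range(4):
        expansions: list[tuple[tuple[str, ...], tuple[float, ...]]] = []
        for nodes, qs in beams:
            state = State(nodes[-1], hop, target_adr)
            actions = admissible_actions(g, state)
            if not actions:
                continue
            q = net.q_values(actions, [hop] * len(actions), [target_adr] * len(actions))
            for a, qa in zip(actions, q):
                expansions.append((nodes + (a,), qs + (float(qa),)))
        if not expansions:
            break
        expansions.sort(key=lambda e: (-e[1][-1], e[0]))
        beams = expansions[:beam_width]
        if hop == 3:
            complete = [
                ScoredPath(nodes, qs)
                for nodes, qs in beams
                if g.entity_type(nodes[-1]) is EntityType.ADR
            ]
    return complete


def enumerate_paths_to_adr(
    g: KnowledgeGraph, drug: str, adr: str
) -> list[tuple[str, ...]]:
    """All template chains from ``drug`` ending exactly at ``adr``,
    lexicographic order."""
    type_of = {nid: n.entity_type for nid, n in g.nodes.items()}

    def nxt(nid: str, want: EntityType) -> list[str]:
        return [m for m in g.adjacency[nid] if type_of[m] is want]

    out = []
    for t in nxt(drug, EntityType.TARGET):
        for p in nxt(t, EntityType.PATHWAY):
            for gn in nxt(p, EntityType.GENE):
                if adr in g.adjacency[gn]:
                    out.append((drug, t, p, gn, adr))
    return out


def count_paths_to_adr(g: KnowledgeGraph, drug: str, adr: str) -> int:
    type_of = {nid: n.entity_type for nid, n in g.nodes.items()}
    total = 0
    for t in g.adjacency[drug]:
        if type_of[t] is not EntityType.TARGET:
            continue
        for p in g.adjacency[t]:
            if type_of[p] is not EntityType.PATHWAY:
                continue
            total += sum(
                1
                for gn in g.adjacency[p]
                if type_of[gn] is EntityType.GENE and adr in g.adjacency[gn]
            )
    return total


def score_paths(
    net: QNetwork,
    g: KnowledgeGraph,
    paths: list[tuple[str, ...]],
    target_adr: str,
) -> list[ScoredPath]:
    """Attach per-transition Q-values (conditioned on ``target_adr``) to paths."""
    if not paths:
        return []
    flat_actions = [n for path in paths for n in path[1:]]
    flat_steps = [k for _ in paths for k in range(4)]
    flat_adrs = [target_adr] * len(flat_actions)
    q = net.q_values(flat_actions, flat_steps, flat_adrs)
    out = []
    for i, path in enumerate(paths):
        out.append(ScoredPath(path, tuple(float(x) for x in q[4 * i : 4 * i + 4])))
    return out
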