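"""Markov decision process over the knowledge graph.

An episode starts at a drug node with a designated target ADR, moves
strictly down the layer hierarchy (drug -> target -> pathway -> gene -> ADR),
and terminates when an ADR node is entered, when a dead end is hit, or after
four transitions. Rewards come from a three-valued alphabet:

* ``+5`` — the target ADR was reached,
* ``+1`` — an on-structure intermediate hop,
* ``-5`` — a wrong ADR was entered, or the walk dead-ended.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .errors import AgentEnvironmentError
from .graph import LAYER_ORDER, EntityType, KnowledgeGraph

MAX_HOPS = 4

REWARD_TARGET = 5.0
REWARD_STEP = 1.0
REWARD_PENALTY = -5.0


@dataclass(frozen=True)
class State:
    """(current node, completed hops k in {0..3}, target ADR)."""

    current_node: str
    hop_count: int
    target_adr: str


@dataclass(frozen=True)
class StepOutcome:
    next_state: State | None  # None marks a terminal transition
    reward: float
    done: bool


@dataclass(frozen=True)
class RewardScheme:
    target: float = REWARD_TARGET
    step: float = REWARD_STEP
    penalty: float = REWARD_PENALTY
    dead_end: float = REWARD_PENALTY


def reset(g: KnowledgeGraph, drug: str, target_adr: str) -> State:
    if g.entity_type(drug) is not EntityType.DRUG:
        raise AgentEnvironmentError(f"{drug!r} is not a drug node")
    if g.entity_type(target_adr) is not EntityType.ADR:
        raise AgentEnvironmentError(f"{target_adr!r} is not an ADR node")
    return State(drug, 0, target_adr)


def admissible_actions(g: KnowledgeGraph, s: State) -> list[str]:
    """Out-neighbors of the current node that sit on the next layer."""
    cur_type = g.entity_type(s.current_node)
    if cur_type is EntityType.ADR:
        return []
    nxt = LAYER_ORDER[cur_type.layer + 1]
    return [m for m in g.neighbors(s.current_node) if g.entity_type(m) is nxt]


def step(
    g: KnowledgeGraph,
    s: State,
    action: str,
    rewards: RewardScheme = RewardScheme(),
) -> StepOutcome:
    if action not in admissible_actions(g, s):
        raise AgentEnvironmentError(
            f"action {action!r} is not admissible from {s.current_node!r}"
        )
    if g.entity_type(action) is EntityType.ADR:
        hit = action == s.target_adr
        return StepOutcome(None, rewards.target if hit else rewards.penalty, True)
    next_state = State(action, s.hop_count + 1, s.target_adr)
    if not admissible_actions(g, next_state):
        # dead end one layer short of the ADR sink: terminal penalty
        return StepOutcome(None, rewards.dead_end, True)
    return StepOutcome(next_state, rewards.step, False)


def rollout(
    g: KnowledgeGraph,
    s0: State,
    policy: Callable[[State], str | None],
    max_hops: int = MAX_HOPS,
    rewards: RewardScheme = RewardScheme(),
) -> tuple[list[str], float, bool]:
    """Drive one episode; ``policy`` returns an admissible action or ``None`` to stop.

    Returns the visited node path (<= 5 nodes), the summed reward, and
    whether the target ADR was reached.
    """
    path = [s0.current_node]
    total = 0.0
    state: State | None = s0
    reached = False
    for _ in range(max_hops):
        assert state is not None
        action = policy(state)
        if action is None:
            break
        outcome = step(g, state, action, rewards)
        total += outcome.reward
        if outcome.done:
            if g.entity_type(action) is EntityType.ADR or outcome.next_state is None:
                path.append(action)
            reached = action == s0.target_adr
            break
        path.append(action)
        state = outcome.next_state
    return path, total, reached
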