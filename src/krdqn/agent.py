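"""Deep Q-learning over the knowledge-graph MDP.

Training follows the classic DQN recipe: a uniform experience-replay buffer
pre-filled with demonstration-path transitions, epsilon-greedy rollouts from
(drug, target-ADR) training pairs, one-step temporal-difference targets from
a periodically synchronized target network, mean-squared Bellman error
minimized with Adam, exponential epsilon annealing, and a per-episode
learning-rate schedule.
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .env import (
    MAX_HOPS,
    RewardScheme,
    State,
    admissible_actions,
    reset,
    step,
)
from .errors import TrainingError
from .graph import DemonstrationPath, EntityType, KnowledgeGraph
from .network import QNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Experience:
    state: State
    action: str
    reward: float
    next_state: State | None
    done: bool
    target_adr: str


class ReplayBuffer:
    """Bounded FIFO of transitions with uniform without-replacement batches."""

    def __init__(self, capacity: int = 10 ** 6):
        self.capacity = capacity
        self._storage: deque[Experience] = deque(maxlen=capacity)

    def push(self, exp: Experience) -> None:
        self._storage.append(exp)

    def extend(self, exps: Iterable[Experience]) -> None:
        self._storage.extend(exps)

    def __len__(self) -> int:
        return len(self._storage)

    def __getitem__(self, i: int) -> Experience:
        return self._storage[i]

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Experience]:
        if len(self._storage) < batch_size:
            raise ValueError(
                f"buffer holds {len(self._storage)} < batch size {batch_size}"
            )
        idx = rng.choice(len(self._storage), size=batch_size, replace=False)
        return [self._storage[i] for i in idx]


@dataclass
class TrainingConfig:
    """Hyperparameters; defaults are the published configuration."""

    learning_rate: float = 0.0008
    gamma: float = 0.946
    batch_size: int = 173
    epsilon_start: float = 1.0
    epsilon_decay: float = 0.987
    epsilon_min: float = 0.066
    dropout: float = 0.3
    embed_dim: int = 32
    episodes: int = 2000
    target_sync_interval: int = 25
    lr_decay: float = 0.999
    hidden_sizes: tuple[int, ...] = (128, 64)
    buffer_capacity: int = 10 ** 6
    demo_fraction: float = 0.8
    seed: int = 0
    rewards: RewardScheme = field(default_factory=RewardScheme)

    def __post_init__(self):
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0 < self.epsilon_min <= self.epsilon_start <= 1:
            raise ValueError("need 0 < epsilon_min <= epsilon_start <= 1")
        for name in ("learning_rate", "batch_size", "target_sync_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.episodes < 0:
            raise ValueError("episodes must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d


# ---------------------------------------------------------------------------
# core operations


def encode_state_action(net: QNetwork, s: State, action: str) -> float:
    """Scalar Q for one (state, action) pair in evaluation mode."""
    return net.q_value(action, s.hop_count, s.target_adr)


def select_action(
    net: QNetwork,
    g: KnowledgeGraph,
    s: State,
    epsilon: float,
    rng: np.random.Generator,
) -> str | None:
    """Epsilon-greedy over admissible actions; Q-ties break lexicographically.

    Returns ``None`` when no action is admissible (dead end for the caller).
    """
    actions = admissible_actions(g, s)
    if not actions:
        return None
    if rng.random() < epsilon:
        return actions[rng.integers(len(actions))]
    q = net.q_values(actions, [s.hop_count] * len(actions), [s.target_adr] * len(actions))
    best = np.flatnonzero(q == q.max())
    # adjacency is lexicographically sorted, so the first maximizer is the tie-break
    return actions[best[0]]


def td_target(
    target_net: QNetwork,
    g: KnowledgeGraph,
    exp: Experience,
    gamma: float,
) -> float:
    """One-step TD target R + gamma * max_a' Q_target(s', a') * (1 - done)."""
    if exp.done or exp.next_state is None:
        return exp.reward
    actions = admissible_actions(g, exp.next_state)
    if not actions:
        return exp.reward
    q = target_net.q_values(
        actions,
        [exp.next_state.hop_count] * len(actions),
        [exp.next_state.target_adr] * len(actions),
    )
    return exp.reward + gamma * float(q.max())


def _batch_td_targets(
    target_net: QNetwork,
    g: KnowledgeGraph,
    batch: Sequence[Experience],
    gamma: float,
) -> np.ndarray:
    """Vectorized TD targets: one flattened Q evaluation for the whole batch."""
    targets = np.array([e.reward for e in batch], dtype=float)
    flat_actions: list[str] = []
    flat_steps: list[int] = []
    flat_adrs: list[str] = []
    owners: list[int] = []
    for i, e in enumerate(batch):
        if e.done or e.next_state is None:
            continue
        acts = admissible_actions(g, e.next_state)
        flat_actions.extend(acts)
        flat_steps.extend([e.next_state.hop_count] * len(acts))
        flat_adrs.extend([e.next_state.target_adr] * len(acts))
        owners.extend([i] * len(acts))
    if flat_actions:
        q = target_net.q_values(flat_actions, flat_steps, flat_adrs)
        owners_arr = np.array(owners)
        for i in np.unique(owners_arr):
            targets[i] += gamma * q[owners_arr == i].max()
    return targets


def train_step(
    policy_net: QNetwork,
    target_net: QNetwork,
    buffer: ReplayBuffer,
    g: KnowledgeGraph,
    config: TrainingConfig,
    rng: np.random.Generator,
    lr: float | None = None,
) -> float | None:
    """One Adam update on a uniform batch; returns the batch loss.

    Skips (returning ``None``) while the buffer holds fewer than
    ``batch_size`` transitions.
    """
    if len(buffer) < config.batch_size:
        logger.info(
            "buffer underfull (%d < %d); skipping update", len(buffer), config.batch_size
        )
        return None
    batch = buffer.sample(config.batch_size, rng)
    targets = _batch_td_targets(target_net, g, batch, config.gamma)
    loss, grads = policy_net.loss_and_grads(
        [e.action for e in batch],
        [e.state.hop_count for e in batch],
        [e.target_adr for e in batch],
        targets,
        rng,
    )
    policy_net.adam_step(grads, lr if lr is not None else config.learning_rate)
    return loss


def anneal_epsilon(epsilon: float, config: TrainingConfig) -> float:
    """epsilon' = max(epsilon_min, epsilon * epsilon_decay)."""
    return max(config.epsilon_min, epsilon * config.epsilon_decay)


def demonstrations_to_experiences(
    g: KnowledgeGraph,
    paths: Iterable[DemonstrationPath],
    rewards: RewardScheme = RewardScheme(),
) -> list[Experience]:
    """Decompose each demonstration chain into its four reward-labelled transitions."""
    out: list[Experience] = []
    for path in paths:
        nodes = path.node_ids
        adr = nodes[-1]
        for k in range(4):
            s = State(nodes[k], k, adr)
            action = nodes[k + 1]
            if k == 3:
                out.append(Experience(s, action, rewards.target, None, True, adr))
            else:
                out.append(
                    Experience(s, action, rewards.step, State(action, k + 1, adr), False, adr)
                )
    return out


@dataclass
class EpisodeRecord:
    episode: int
    total_reward: float
    epsilon: float
    loss: float | None
    lr: float
    reached: bool


def train(
    g: KnowledgeGraph,
    demonstration_paths: Sequence[DemonstrationPath],
    pairs: Sequence[tuple[str, str]],
    config: TrainingConfig,
    features: Mapping[str, np.ndarray] | None = None,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 0,
) -> tuple[QNetwork, list[EpisodeRecord]]:
    """Full training loop.

    The buffer is pre-filled with a ``demo_fraction`` subsample of the
    demonstration-path transitions, each stored relative to the path's own
    endpoint ADR; each episode then samples a training (drug, ADR)
    positive, rolls out epsilon-greedily, appends the collected
    transitions, performs one replay update, anneals epsilon, decays the
    learning rate, and periodically synchronizes the target network.
    """
    if not pairs:
        raise TrainingError("no training pairs")
    pair_drugs = {d for d, _ in pairs}
    if not any(p.drug in pair_drugs for p in demonstration_paths):
        raise TrainingError(
            "no demonstration path exists for any training pair (degenerate task)"
        )
    rng = np.random.default_rng(config.seed)
    policy_net = QNetwork(
        sorted(g.nodes),
        embed_dim=config.embed_dim,
        hidden_sizes=config.hidden_sizes,
        dropout=config.dropout,
        init_features=features,
        rng=rng,
    )
    target_net = policy_net.clone()

    buffer = ReplayBuffer(config.buffer_capacity)
    demos = list(demonstration_paths)
    if config.demo_fraction < 1.0 and demos:
        keep = max(1, int(round(config.demo_fraction * len(demos))))
        idx = rng.choice(len(demos), size=keep, replace=False)
        demos = [demos[i] for i in sorted(idx)]
    buffer.extend(demonstrations_to_experiences(g, demos, config.rewards))

    log: list[EpisodeRecord] = []
    epsilon = config.epsilon_start
    lr = config.learning_rate
    pair_list = list(pairs)
    for ep in range(1, config.episodes + 1):
        drug, adr = pair_list[rng.integers(len(pair_list))]
        state: State | None = reset(g, drug, adr)
        total = 0.0
        reached = False
        for _ in range(MAX_HOPS):
            assert state is not None
            action = select_action(policy_net, g, state, epsilon, rng)
            if action is None:
                break
            outcome = step(g, state, action, config.rewards)
            buffer.push(
                Experience(state, action, outcome.reward, outcome.next_state,
                           outcome.done, adr)
            )
            total += outcome.reward
            if outcome.done:
                reached = action == adr
                break
            state = outcome.next_state

        loss = train_step(policy_net, target_net, buffer, g, config, rng, lr=lr)
        epsilon = anneal_epsilon(epsilon, config)
        lr *= config.lr_decay
        if ep % config.target_sync_interval == 0:
            target_net.copy_weights_from(policy_net)
        if checkpoint_path and checkpoint_every and ep % checkpoint_every == 0:
            policy_net.save(checkpoint_path)
        log.append(EpisodeRecord(ep, total, epsilon, loss, lr, reached))

    if checkpoint_path:
        policy_net.save(checkpoint_path)
    return policy_net, log
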