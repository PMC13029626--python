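"""scikit-learn style estimator facade over the knowledge-graph DQN.

`KRDQNClassifier` treats (drug, ADR) identifier pairs as samples: ``fit``
trains the Q-network by reinforcement learning on the positive pairs,
``predict_proba`` turns beam-searched Q-values into association
probabilities, and ``explain`` returns the ranked mechanism chains behind
a prediction. The estimator composes with sklearn model selection because
it implements the standard ``get_params``/``set_params``/``fit``/
``predict`` contract.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import agent
from .env import RewardScheme
from .errors import KrdqnError
from .evaluate import score_pair
from .features import compute_all_features
from .graph import KnowledgeGraph, extract_demonstration_paths, prune_graph
from .interpret import ExplanationPath, top_k_paths


def _as_pairs(X) -> list[tuple[str, str]]:
    if isinstance(X, pd.DataFrame):
        cols = ["drug", "adr"] if {"drug", "adr"} <= set(X.columns) else list(X.columns[:2])
        return list(map(tuple, X[cols].astype(str).itertuples(index=False, name=None)))
    arr = np.asarray(X, dtype=object)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise KrdqnError("X must be an (n, 2) array-like of (drug, adr) pairs")
    return [(str(d), str(a)) for d, a in arr[:, :2]]


class KRDQNClassifier(ClassifierMixin, BaseEstimator):
    """Drug-ADR association classifier backed by deep Q-learning.

    Parameters
    ----------
    graph : KnowledgeGraph
        The five-layer biomedical graph to navigate (pruned internally).
    features : mapping node_id -> 32-dim vector, "auto", or None
        Attribute features used to initialize node embeddings. "auto"
        computes them from the graph's raw attributes.
    Remaining parameters mirror :class:`krdqn.agent.TrainingConfig`;
    defaults are the published configuration.

    Attributes
    ----------
    q_network_ : trained :class:`krdqn.network.QNetwork`
    graph_ : pruned navigation graph
    history_ : per-episode training log
    classes_ : ndarray [0, 1]
    """

    def __init__(
        self,
        graph: KnowledgeGraph | None = None,
        features: Mapping[str, np.ndarray] | str | None = "auto",
        learning_rate: float = 0.0008,
        gamma: float = 0.946,
        batch_size: int = 173,
        epsilon_start: float = 1.0,
        epsilon_decay: float = 0.987,
        epsilon_min: float = 0.066,
        dropout: float = 0.3,
        embed_dim: int = 32,
        episodes: int = 2000,
        target_sync_interval: int = 25,
        lr_decay: float = 0.999,
        hidden_sizes: tuple[int, ...] = (128, 64),
        demo_fraction: float = 0.8,
        beam_width: int = 10,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.graph = graph
        self.features = features
        self.learning_rate = learning_rate
        self.gamma = gamma
        self.batch_size = batch_size
        self.epsilon_start = epsilon_start
        self.epsilon_decay = epsilon_decay
        self.epsilon_min = epsilon_min
        self.dropout = dropout
        self.embed_dim = embed_dim
        self.episodes = episodes
        self.target_sync_interval = target_sync_interval
        self.lr_decay = lr_decay
        self.hidden_sizes = hidden_sizes
        self.demo_fraction = demo_fraction
        self.beam_width = beam_width
        self.threshold = threshold
        self.random_state = random_state

    def _config(self) -> agent.TrainingConfig:
        return agent.TrainingConfig(
            learning_rate=self.learning_rate,
            gamma=self.gamma,
            batch_size=self.batch_size,
            epsilon_start=self.epsilon_start,
            epsilon_decay=self.epsilon_decay,
            epsilon_min=self.epsilon_min,
            dropout=self.dropout,
            embed_dim=self.embed_dim,
            episodes=self.episodes,
            target_sync_interval=self.target_sync_interval,
            lr_decay=self.lr_decay,
            hidden_sizes=tuple(self.hidden_sizes),
            demo_fraction=self.demo_fraction,
            seed=self.random_state,
            rewards=RewardScheme(),
        )

    def fit(self, X, y=None):
        """Train on positive (drug, ADR) pairs.

        ``y`` may carry 0/1 labels, in which case only label-1 pairs drive
        the reinforcement episodes; with ``y=None`` all pairs are treated
        as positives.
        """
        if self.graph is None:
            raise KrdqnError("a KnowledgeGraph must be supplied via `graph`")
        pairs = _as_pairs(X)
        if y is not None:
            labels = np.asarray(y).astype(int)
            pairs = [p for p, lab in zip(pairs, labels) if lab == 1]
        self.graph_ = prune_graph(self.graph)
        if self.features == "auto":
            feats = compute_all_features(self.graph_, seed=self.random_state)
        else:
            feats = self.features
        self.demonstration_paths_ = extract_demonstration_paths(self.graph_)
        train_pairs = [
            (d, a) for d, a in pairs if d in self.graph_.nodes and a in self.graph_.nodes
        ]
        self.q_network_, self.history_ = agent.train(
            self.graph_, self.demonstration_paths_, train_pairs, self._config(),
            features=feats,
        )
        self.classes_ = np.array([0, 1])
        return self

    def decision_scores(self, X) -> np.ndarray:
        check_is_fitted(self, "q_network_")
        scores = np.empty(len(_as_pairs(X)))
        for i, (d, a) in enumerate(_as_pairs(X)):
            scores[i], _ = score_pair(self.q_network_, self.graph_, d, a, self.beam_width)
        return scores

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.decision_scores(X)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def explain(self, drug: str, adr: str, k: int = 10) -> list[ExplanationPath]:
        """Ranked mechanism chains for one (drug, ADR) query."""
        check_is_fitted(self, "q_network_")
        return top_k_paths(self.q_network_, self.graph_, drug, adr, k)
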