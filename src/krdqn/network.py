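"""Q-network: embedding tables plus a ReLU MLP, in plain NumPy.

The state-action encoding concatenates three 32-dim embeddings — the action
node, the current hop index, and the target ADR node — into a 96-dim input,
which a small fully connected stack with ReLU activations and dropout maps
to a scalar Q-value. Gradients are computed by hand-written backprop and
applied with Adam; node-embedding rows can be initialized from the
attribute feature vectors so chemistry/sequence information seeds the
otherwise learnable tables.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import KrdqnError

N_STEPS = 4  # hop indices 0..3


class QNetwork:
    """MLP Q(s, a) = W_out * relu-stack([e_action; e_step; e_adr]) + b_out.

    Parameters
    ----------
    node_ids : ordered node vocabulary (embedding-table rows)
    embed_dim : per-entity embedding width (default 32)
    hidden_sizes : widths of the hidden ReLU layers
    dropout : dropout probability between hidden layers (training mode only)
    init_features : optional node_id -> vector map; rows are scaled to unit
        norm and written into the node table before training
    """

    def __init__(
        self,
        node_ids: Sequence[str],
        embed_dim: int = 32,
        hidden_sizes: Sequence[int] = (128, 64),
        dropout: float = 0.3,
        init_features: Mapping[str, np.ndarray] | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.node_ids = list(node_ids)
        self.node_index = {n: i for i, n in enumerate(self.node_ids)}
        self.embed_dim = embed_dim
        self.hidden_sizes = tuple(hidden_sizes)
        self.dropout = dropout

        params: dict[str, np.ndarray] = {}
        params["node_emb"] = rng.normal(0.0, 0.1, (len(self.node_ids), embed_dim))
        if init_features:
            for nid, vec in init_features.items():
                if nid in self.node_index:
                    v = np.asarray(vec, dtype=float)
                    norm = np.linalg.norm(v)
                    if norm > 0:
                        params["node_emb"][self.node_index[nid]] = v / norm
        params["step_emb"] = rng.normal(0.0, 0.1, (N_STEPS, embed_dim))
        sizes = [3 * embed_dim, *hidden_sizes, 1]
        for l in range(len(sizes) - 1):
            fan_in = sizes[l]
            params[f"W{l}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, sizes[l + 1]))
            params[f"b{l}"] = np.zeros(sizes[l + 1])
        self.params = params
        self.n_layers = len(sizes) - 1
        self._adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        self._adam_t = 0

    # -- encoding -----------------------------------------------------------

    def _ids(self, nodes: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.node_index[n] for n in nodes], dtype=np.int64)
        except KeyError as exc:
            raise KrdqnError(f"no embedding for node {exc.args[0]!r}") from None

    def _forward(
        self,
        action_idx: np.ndarray,
        step_idx: np.ndarray,
        adr_idx: np.ndarray,
        training: bool,
        rng: np.random.Generator | None,
    ):
        x = np.concatenate(
            [
                self.params["node_emb"][action_idx],
                self.params["step_emb"][step_idx],
                self.params["node_emb"][adr_idx],
            ],
            axis=1,
        )
        cache = {"x": x, "a": [], "mask": []}
        h = x
        for l in range(self.n_layers - 1):
            z = h @ self.params[f"W{l}"] + self.params[f"b{l}"]
            a = np.maximum(z, 0.0)
            if training and self.dropout > 0:
                assert rng is not None, "training-mode forward needs an rng for dropout"
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
            else:
                mask = None
            cache["a"].append(a)
            cache["mask"].append(mask)
            h = a
        L = self.n_layers - 1
        q = (h @ self.params[f"W{L}"] + self.params[f"b{L}"]).ravel()
        return q, cache

    def q_values(
        self,
        actions: Sequence[str],
        steps: Sequence[int],
        adrs: Sequence[str],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Batch of scalar Q-values; deterministic in evaluation mode."""
        if len(actions) == 0:
            return np.zeros(0)
        q, _ = self._forward(
            self._ids(actions), np.asarray(steps, dtype=np.int64), self._ids(adrs),
            training, rng,
        )
        return q

    def q_value(self, action: str, step: int, adr: str) -> float:
        return float(self.q_values([action], [step], [adr])[0])

    # -- training -----------------------------------------------------------

    def loss_and_grads(
        self,
        actions: Sequence[str],
        steps: Sequence[int],
        adrs: Sequence[str],
        targets: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean squared Bellman error and its gradients for one batch."""
        action_idx = self._ids(actions)
        step_idx = np.asarray(steps, dtype=np.int64)
        adr_idx = self._ids(adrs)
        q, cache = self._forward(action_idx, step_idx, adr_idx, True, rng)
        err = q - np.asarray(targets, dtype=float)
        B = len(err)
        loss = float(np.mean(err ** 2))

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        delta = (2.0 / B) * err[:, None]  # dL/dq, (B,1)
        L = self.n_layers - 1
        h_prev = cache["a"][L - 1] if L > 0 else cache["x"]
        grads[f"W{L}"] = h_prev.T @ delta
        grads[f"b{L}"] = delta.sum(axis=0)
        d = delta @ self.params[f"W{L}"].T
        for l in range(L - 1, -1, -1):
            a = cache["a"][l]
            mask = cache["mask"][l]
            if mask is not None:
                d = d * mask
            d = d * (a > 0)
            h_prev = cache["a"][l - 1] if l > 0 else cache["x"]
            grads[f"W{l}"] = h_prev.T @ d
            grads[f"b{l}"] = d.sum(axis=0)
            d = d @ self.params[f"W{l}"].T
        # d is now dL/dx, (B, 96): scatter into the embedding tables
        e = self.embed_dim
        np.add.at(grads["node_emb"], action_idx, d[:, :e])
        np.add.at(grads["step_emb"], step_idx, d[:, e : 2 * e])
        np.add.at(grads["node_emb"], adr_idx, d[:, 2 * e :])
        return loss, grads

    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g ** 2
            m_hat = m / (1 - beta1 ** t)
            v_hat = v / (1 - beta2 ** t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- persistence / cloning ---------------------------------------------

    def copy_weights_from(self, other: "QNetwork") -> None:
        for k, v in other.params.items():
            self.params[k] = v.copy()

    def clone(self) -> "QNetwork":
        dup = QNetwork(
            self.node_ids, self.embed_dim, self.hidden_sizes, self.dropout
        )
        dup.copy_weights_from(self)
        return dup

    def save(self, path: str | Path) -> None:
        """Portable checkpoint: an .npz tensor archive plus a JSON sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        meta = {
            "node_ids": self.node_ids,
            "embed_dim": self.embed_dim,
            "hidden_sizes": list(self.hidden_sizes),
            "dropout": self.dropout,
            "format_version": 1,
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "QNetwork":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta.get("format_version") != 1:
            raise KrdqnError(f"unsupported checkpoint version in {path}")
        net = cls(
            meta["node_ids"], meta["embed_dim"], tuple(meta["hidden_sizes"]),
            meta["dropout"],
        )
        with np.load(path.with_suffix(".npz")) as data:
            for k in net.params:
                net.params[k] = data[k]
        return net
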