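"""Biased second-order random walks with a skip-gram embedding.

Implements the node2vec procedure: walks over the undirected view of the
graph biased by a return parameter ``p`` and in-out parameter ``q``
(``p > 1`` with ``q < 1`` favours depth-first exploration), followed by a
skip-gram model with negative sampling trained by plain SGD on NumPy
arrays. Used to give ADR nodes — which carry no intrinsic attribute —
a structural feature vector.
"""
from __future__ import annotations

import numpy as np


def _undirected_adjacency(edges: list[tuple[str, str]], nodes: list[str]) -> dict[str, list[str]]:
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return {n: sorted(nbrs) for n, nbrs in adj.items()}


def biased_walks(
    adj: dict[str, list[str]],
    p: float,
    q: float,
    walk_length: int,
    num_walks: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Generate ``num_walks`` second-order biased walks from every node."""
    walks: list[list[str]] = []
    nodes = sorted(adj)
    for _ in range(num_walks):
        for start in nodes:
            if not adj[start]:
                continue
            walk = [start]
            while len(walk) < walk_length:
                cur = walk[-1]
                nbrs = adj[cur]
                if not nbrs:
                    break
                if len(walk) == 1:
                    nxt = nbrs[rng.integers(len(nbrs))]
                else:
                    prev = walk[-2]
                    prev_nbrs = adj[prev]
                    w = np.empty(len(nbrs))
                    for i, x in enumerate(nbrs):
                        if x == prev:
                            w[i] = 1.0 / p
                        elif x in prev_nbrs:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / q
                    w /= w.sum()
                    nxt = nbrs[rng.choice(len(nbrs), p=w)]
                walk.append(nxt)
            walks.append(walk)
    return walks


def skipgram_embedding(
    walks: list[list[str]],
    vocab: list[str],
    dim: int,
    window: int,
    rng: np.random.Generator,
    epochs: int = 3,
    negative: int = 5,
    lr: float = 0.5,
) -> np.ndarray:
    """Skip-gram with negative sampling over walk corpora.

    Returns a ``(len(vocab), dim)`` matrix of input embeddings. Negative
    samples are drawn from the unigram distribution raised to 3/4.
    Gradients are averaged over each minibatch (rather than applied
    per pair), which keeps the update magnitude independent of how often
    a node recurs within the batch.
    """
    index = {n: i for i, n in enumerate(vocab)}
    counts = np.zeros(len(vocab))
    pairs: list[tuple[int, int]] = []
    for walk in walks:
        ids = [index[n] for n in walk]
        for c in ids:
            counts[c] += 1
        for i, center in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, ids[j]))
    if not pairs:
        return np.zeros((len(vocab), dim))

    noise = counts ** 0.75
    noise /= noise.sum()

    W_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    W_out = np.zeros((len(vocab), dim))
    pair_arr = np.array(pairs, dtype=np.int64)
    n_pairs = len(pair_arr)
    batch = 512
    total_steps = epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            cur_lr = lr * max(1e-4, 1.0 - step / total_steps)
            step += 1
            idx = pair_arr[order[s : s + batch]]
            centers, contexts = idx[:, 0], idx[:, 1]
            B = len(centers)
            negs = rng.choice(len(vocab), size=(B, negative), p=noise)
            # (B, 1+neg) output rows: first column positive, rest negative
            out_ids = np.concatenate([contexts[:, None], negs], axis=1)
            labels = np.zeros((B, 1 + negative))
            labels[:, 0] = 1.0
            v_in = W_in[centers]                      # (B, d)
            v_out = W_out[out_ids]                    # (B, 1+neg, d)
            logits = np.einsum("bd,bkd->bk", v_in, v_out)
            sig = 1.0 / (1.0 + np.exp(-np.clip(logits, -30, 30)))
            err = sig - labels                        # (B, 1+neg)
            grad_in = np.einsum("bk,bkd->bd", err, v_out) / B
            grad_out = err[:, :, None] * v_in[:, None, :] / B
            np.add.at(W_in, centers, -cur_lr * grad_in)
            np.add.at(W_out, out_ids.ravel(), -cur_lr * grad_out.reshape(-1, dim))
    return W_in
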