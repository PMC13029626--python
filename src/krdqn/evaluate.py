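"""Turning the trained agent into a drug-ADR classifier and scoring it.

Covers balanced negative sampling, leakage-free drug-level splits and
5-fold cross-validation, Q-to-probability scoring via beam search, the
four confusion-matrix metrics plus rank-based AUC, and the
frequency-stratified confusion analysis for common vs. rare ADRs.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .env import admissible_actions, State
from .errors import SamplingError, SplitError, UndefinedMetricError
from .graph import KnowledgeGraph
from .network import QNetwork
from .search import beam_complete_paths

logger = logging.getLogger(__name__)


@dataclass
class PredictionRecord:
    drug: str
    adr: str
    label: int
    score: float
    best_path: tuple[str, ...] | None = None


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class SplitPlan:
    train_drugs: set[str]
    test_drugs: set[str]
    folds: list[set[str]] | None = None


# ---------------------------------------------------------------------------
# sampling and splitting


def sample_negatives(
    positives: Sequence[tuple[str, str]],
    all_adrs: Iterable[str],
    rng: np.random.Generator,
) -> list[tuple[str, str, int]]:
    """One negative per positive: a uniformly chosen ADR not recorded for
    that drug, giving an exactly balanced pair table."""
    adr_pool = sorted(set(all_adrs))
    known: dict[str, set[str]] = {}
    for d, a in positives:
        known.setdefault(d, set()).add(a)
    out = []
    for d, _ in positives:
        candidates = [a for a in adr_pool if a not in known[d]]
        if not candidates:
            raise SamplingError(f"drug {d!r} is associated with every ADR")
        out.append((d, candidates[rng.integers(len(candidates))], 0))
    return out


def split_by_drug(
    drugs: Iterable[str], ratio: float = 0.8, rng: np.random.Generator | None = None
) -> SplitPlan:
    """Drug-level train/test split; no drug appears in both sets."""
    rng = rng or np.random.default_rng(0)
    pool = sorted(set(drugs))
    if len(pool) < 2:
        raise SplitError("need at least 2 drugs to split")
    order = rng.permutation(len(pool))
    n_train = int(round(ratio * len(pool)))
    train = {pool[i] for i in order[:n_train]}
    test = {pool[i] for i in order[n_train:]}
    return SplitPlan(train_drugs=train, test_drugs=test)


def make_folds(
    drugs: Iterable[str], k: int = 5, rng: np.random.Generator | None = None
) -> list[set[str]]:
    rng = rng or np.random.default_rng(0)
    pool = sorted(set(drugs))
    if len(pool) < k:
        raise SplitError(f"cannot make {k} folds from {len(pool)} drugs")
    order = rng.permutation(len(pool))
    return [set(pool[i] for i in chunk) for chunk in np.array_split(order, k)]


# ---------------------------------------------------------------------------
# scoring


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def score_pair(
    net: QNetwork,
    g: KnowledgeGraph,
    drug: str,
    adr: str,
    beam_width: int = 10,
) -> tuple[float, tuple[str, ...] | None]:
    """Association score and best explanation path for one (drug, ADR) pair.

    Beam search (conditioned on the query ADR) expands the four-layer
    template by Q-rank. The score is the logistic of the best terminal-step
    Q over complete beam paths; when the beam completes no path at all it
    falls back to the logistic of the best first-hop Q. ``best_path`` is the
    highest-total-Q complete path that actually ends at the query ADR.
    """
    complete = beam_complete_paths(net, g, drug, adr, beam_width)
    reaching = [p for p in complete if p.adr == adr]
    best_path = None
    if reaching:
        reaching.sort(key=lambda p: (-p.total_q, p.nodes))
        best_path = reaching[0].nodes
    if complete:
        return _logistic(max(p.terminal_q for p in complete)), best_path
    actions = admissible_actions(g, State(drug, 0, adr))
    if not actions:
        return 0.0, None
    q = net.q_values(actions, [0] * len(actions), [adr] * len(actions))
    return _logistic(float(q.max())), None


def score_pairs(
    net: QNetwork,
    g: KnowledgeGraph,
    pairs: Sequence[tuple[str, str, int]],
    beam_width: int = 10,
) -> list[PredictionRecord]:
    return [
        PredictionRecord(d, a, label, *score_pair(net, g, d, a, beam_width))
        for d, a, label in pairs
    ]


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(
    records: Sequence[PredictionRecord], threshold: float = 0.5
) -> ConfusionCounts:
    c = ConfusionCounts()
    for r in records:
        pred = r.score >= threshold
        if r.label == 1:
            c.TP += pred
            c.FN += not pred
        else:
            c.FP += pred
            c.TN += not pred
    return c


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean F1 = 2 P R / (P + R)."""
    if precision + recall == 0:
        raise UndefinedMetricError("F1 undefined: precision + recall = 0")
    return 2 * precision * recall / (precision + recall)


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no records")
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined: no positive labels")
    precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN)
    return {
        "accuracy": (c.TP + c.TN) / c.total,
        "precision": precision,
        "recall": recall,
        "f1": f1_from_precision_recall(precision, recall),
    }


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """ROC-AUC by the Mann-Whitney rank statistic with midrank tie credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # midranks
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(
    records: Sequence[PredictionRecord], threshold: float = 0.5
) -> dict[str, float]:
    """Accuracy, precision, recall, F1 at ``threshold`` plus rank AUC."""
    c = confusion_counts(records, threshold)
    out = metrics_from_counts(c)
    out["auc"] = auc_score([r.label for r in records], [r.score for r in records])
    return out


# ---------------------------------------------------------------------------
# frequency-stratified confusion analysis


def stratified_confusion(
    records: Sequence[PredictionRecord],
    adr_frequencies: Mapping[str, float],
    top_frac: float = 0.05,
    bottom_frac: float = 0.05,
    threshold: float = 0.5,
) -> dict[str, dict]:
    """Confusion counts for common (top fraction) vs. rare (bottom fraction)
    ADRs by frequency, with per-group precision.

    Every ADR occurring in ``records`` must appear in ``adr_frequencies``.
    """
    missing = {r.adr for r in records} - set(adr_frequencies)
    if missing:
        raise UndefinedMetricError(f"no frequency for ADRs: {sorted(missing)}")
    by_freq = sorted(adr_frequencies, key=lambda a: (-adr_frequencies[a], a))
    n = len(by_freq)
    n_top = max(1, math.ceil(top_frac * n))
    n_bot = max(1, math.ceil(bottom_frac * n))
    groups = {
        "common": set(by_freq[:n_top]),
        "rare": set(by_freq[n - n_bot:]) - set(by_freq[:n_top]),
    }
    out: dict[str, dict] = {}
    for name, adrs in groups.items():
        sub = [r for r in records if r.adr in adrs]
        if not sub:
            warnings.warn(f"stratum {name!r} is empty; skipped", stacklevel=2)
            continue
        c = confusion_counts(sub, threshold)
        entry: dict = {"counts": c, "n_records": len(sub), "n_adrs": len({r.adr for r in sub})}
        if c.TP + c.FP > 0:
            entry["precision"] = c.TP / (c.TP + c.FP)
        out[name] = entry
    return out


def write_confusion_tsv(result: dict[str, dict], path: str | Path) -> None:
    """Heat-map-ready export: one row per stratum with the four counts."""
    lines = ["group\tTP\tFP\tFN\tTN\tprecision"]
    for name, entry in result.items():
        c = entry["counts"]
        prec = entry.get("precision")
        lines.append(
            f"{name}\t{c.TP}\t{c.FP}\t{c.FN}\t{c.TN}\t"
            f"{'' if prec is None else f'{prec:.4f}'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cross-validation driver


def cross_validate(
    run_fold,
    drugs: Iterable[str],
    k: int = 5,
    rng: np.random.Generator | None = None,
) -> list[dict[str, float]]:
    """Drug-level k-fold CV. ``run_fold(train_drugs, held_out_drugs)`` must
    return a metrics dict; the per-fold dicts are returned in fold order."""
    folds = make_folds(drugs, k, rng)
    all_drugs = set().union(*folds)
    results = []
    for i, held in enumerate(folds):
        results.append(run_fold(all_drugs - held, held))
        logger.info("fold %d/%d: %s", i + 1, k, results[-1])
    return results
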