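"""Explanation-path ranking, similarity concordance, and masking fidelity.

Three complementary views of interpretability:

* ranked mechanism chains (top-k paths by Q) for a (drug, ADR) query;
* per-ADR Spearman concordance between drug-drug chemical similarity and
  the similarity of the mechanism paths the model assigns those drugs,
  with Benjamini-Hochberg control across ADRs;
* masking fidelity: how much the association score drops (or rises) when
  the node an explanation cites is deleted from the graph.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import false_discovery_control, spearmanr

from .errors import UndefinedMetricError
from .graph import EntityType, KnowledgeGraph
from .network import QNetwork
from .search import (
    beam_complete_paths,
    count_paths_to_adr,
    enumerate_paths_to_adr,
    score_paths,
)

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10 ** 5

_LEVEL_INDEX = {"target": 1, "pathway": 2, "gene": 3}


@dataclass(frozen=True)
class ExplanationPath:
    node_ids: tuple[str, str, str, str, str]
    q_value: float  # summed per-transition Q (estimated return of the chain)
    rank: int


@dataclass
class AdrSimilarityResult:
    adr_id: str
    n_drugs: int
    spearman_rho: float
    p_value: float
    adjusted_p: float | None = None
    degenerate: bool = False


def top_k_paths(
    net: QNetwork,
    g: KnowledgeGraph,
    drug: str,
    adr: str,
    k: int = 10,
) -> list[ExplanationPath]:
    """The k highest-Q complete chains from ``drug`` to ``adr``.

    Exhaustive enumeration when at most ``EXHAUSTIVE_LIMIT`` candidate
    chains exist, otherwise beam search with a beam of ``max(10 * k, 50)``.
    Sorted by q_value descending; exact ties break lexicographically.
    """
    if count_paths_to_adr(g, drug, adr) <= EXHAUSTIVE_LIMIT:
        scored = score_paths(net, g, enumerate_paths_to_adr(g, drug, adr), adr)
    else:
        scored = [
            p
            for p in beam_complete_paths(net, g, drug, adr, beam_width=max(10 * k, 50))
            if p.adr == adr
        ]
    if not scored:
        logger.info("no complete path from %s to %s", drug, adr)
        return []
    scored.sort(key=lambda p: (-p.total_q, p.nodes))
    return [
        ExplanationPath(p.nodes, p.total_q, rank)
        for rank, p in enumerate(scored[:k], start=1)
    ]


# ---------------------------------------------------------------------------
# drug-similarity vs. path-similarity concordance


def _cosine_condensed(vectors: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities (condensed upper triangle)."""
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vectors / norms
    sim = unit @ unit.T
    iu = np.triu_indices(len(vectors), k=1)
    return sim[iu]


def path_vector(
    path: Sequence[str], feature_vectors: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Path representation: mean attribute vector of its target, pathway,
    and gene nodes."""
    return np.mean([np.asarray(feature_vectors[n], float) for n in path[1:4]], axis=0)


def similarity_concordance(
    feature_vectors: Mapping[str, np.ndarray],
    paths_by_adr: Mapping[str, Mapping[str, Sequence[str]]],
    min_drugs: int = 8,
) -> list[AdrSimilarityResult]:
    """Per-ADR Spearman correlation of drug-drug vs. path-path similarity.

    ``paths_by_adr`` maps each ADR to {drug: rank-1 explanation path}. For
    every ADR with at least ``min_drugs`` drugs, pairwise cosine
    similarities of the drugs' fingerprint vectors are rank-correlated with
    pairwise cosine similarities of their path vectors; p-values are
    Benjamini-Hochberg adjusted across the retained (non-degenerate) ADRs.
    """
    results: list[AdrSimilarityResult] = []
    for adr in sorted(paths_by_adr):
        drug_paths = paths_by_adr[adr]
        drugs = sorted(drug_paths)
        if len(drugs) < min_drugs:
            continue
        dvecs = np.vstack([np.asarray(feature_vectors[d], float) for d in drugs])
        pvecs = np.vstack([path_vector(drug_paths[d], feature_vectors) for d in drugs])
        dsim = _cosine_condensed(dvecs)
        psim = _cosine_condensed(pvecs)
        if np.ptp(dsim) == 0 or np.ptp(psim) == 0:
            results.append(AdrSimilarityResult(adr, len(drugs), np.nan, np.nan,
                                               degenerate=True))
            continue
        rho, p = spearmanr(dsim, psim)
        results.append(AdrSimilarityResult(adr, len(drugs), float(rho), float(p)))

    valid = [r for r in results if not r.degenerate]
    if valid:
        adjusted = false_discovery_control([r.p_value for r in valid], method="bh")
        for r, ap in zip(valid, adjusted):
            r.adjusted_p = float(ap)
    return results


# ---------------------------------------------------------------------------
# masking fidelity


def fidelity(
    net: QNetwork,
    g: KnowledgeGraph,
    test_pairs: Sequence[tuple[str, str]],
    level: str,
    beam_width: int = 10,
) -> float:
    """Mean masking fidelity at one explanation level.

    For each (drug, ADR) pair with an explanation path, the node the
    explanation cites at ``level`` (target, pathway, or gene) is removed
    from the graph and the pair is re-scored; fidelity is the original
    score minus the masked score. Negative values are legal — removing a
    cited node can reroute the beam through higher-Q alternatives.
    """
    from .evaluate import score_pair  # local import avoids a cycle

    if level not in _LEVEL_INDEX:
        raise ValueError(f"level must be one of {sorted(_LEVEL_INDEX)}")
    idx = _LEVEL_INDEX[level]
    values = []
    for drug, adr in test_pairs:
        score_orig, best_path = score_pair(net, g, drug, adr, beam_width)
        if best_path is None:
            logger.info("pair (%s, %s) has no explanation path; skipped", drug, adr)
            continue
        masked = g.without_node(best_path[idx])
        if drug not in masked.nodes or not masked.adjacency[drug]:
            logger.info("masking disconnects drug %s entirely; pair skipped", drug)
            continue
        score_masked, _ = score_pair(net, masked, drug, adr, beam_width)
        values.append(score_orig - score_masked)
    if not values:
        raise UndefinedMetricError("fidelity undefined: no scorable pairs")
    return float(np.mean(values))
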