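"""Fixed-length (32-dim) attribute features for all five entity types.

Every extractor emits exactly :data:`EMBED_DIM` values so the vectors can
initialize the rows of the learnable node-embedding table directly:

* drugs      — 32-bit Morgan/ECFP fingerprint (radius 2) from SMILES
* targets    — 20 amino-acid frequencies + 12 mean physicochemical scales
* pathways   — TF-IDF over member tokens, reduced by PCA
* genes      — 64-dim relative 3-mer frequencies, reduced by PCA
* ADRs       — node2vec structural embedding of the heterogeneous graph
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import TfidfVectorizer

from ._scales import AMINO_ACIDS, SCALE_MATRIX
from .errors import FeatureError
from .graph import EntityType, KnowledgeGraph
from .node2vec import _undirected_adjacency, biased_walks, skipgram_embedding

RDLogger.DisableLog("rdApp.*")

EMBED_DIM = 32

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_KMERS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_KMER_INDEX = {k: i for i, k in enumerate(_KMERS)}


@dataclass
class FeatureVector:
    node_id: str
    values: np.ndarray  # shape (32,)
    source: str  # one of ecfp | aa_profile | tfidf_pca | kmer_pca | node2vec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (EMBED_DIM,):
            raise FeatureError(
                f"{self.node_id}: feature vector has shape {self.values.shape}, "
                f"expected ({EMBED_DIM},)"
            )


@dataclass
class PCAModel:
    """Fitted principal components (possibly fewer than 32; scores are zero-padded)."""

    component_matrix: np.ndarray  # (k, n_features), rows orthonormal
    mean_vector: np.ndarray
    explained_variance_fractions: np.ndarray


# ---------------------------------------------------------------------------
# sklearn-style transformers


class MorganFingerprinter(TransformerMixin, BaseEstimator):
    """Stateless transformer: SMILES strings -> binary Morgan/ECFP bit vectors."""

    def __init__(self, radius: int = 2, n_bits: int = EMBED_DIM):
        self.radius = radius
        self.n_bits = n_bits

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.n_bits
        )
        out = np.zeros((len(X), self.n_bits))
        for i, smiles in enumerate(X):
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise FeatureError(f"unparseable SMILES {smiles!r}")
            out[i] = np.array(gen.GetFingerprint(mol), dtype=float)
        return out


class AminoAcidComposition(TransformerMixin, BaseEstimator):
    """Residue frequencies (20) + sequence means of 12 physicochemical scales."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(X), EMBED_DIM))
        for i, seq in enumerate(X):
            out[i] = _aa_vector(seq)
        return out


def _aa_vector(sequence: str) -> np.ndarray:
    if not sequence:
        raise FeatureError("empty amino-acid sequence")
    counts = np.zeros(20)
    for ch in sequence:
        idx = _AA_INDEX.get(ch)
        if idx is None:
            raise FeatureError(f"non-standard residue {ch!r}")
        counts[idx] += 1
    freqs = counts / counts.sum()
    means = freqs @ SCALE_MATRIX  # frequency-weighted mean of each scale
    return np.concatenate([freqs, means])


class _TfidfPCABase(TransformerMixin, BaseEstimator):
    """Shared fit logic: a raw matrix builder followed by PCA to 32 scores."""

    def __init__(self, n_components: int = EMBED_DIM):
        self.n_components = n_components

    def _raw_matrix(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        M = self._raw_matrix(X)
        if M.shape[0] < 2:
            warnings.warn(
                "only one sample available; principal components are "
                "undefined and scores are all-zero", stacklevel=2,
            )
            self.pca_ = None
            self.n_components_ = 0
            self.explained_variance_ratio_ = np.zeros(0)
            return self
        k = min(self.n_components, M.shape[0], M.shape[1])
        if k < self.n_components:
            warnings.warn(
                f"only {M.shape[0]} samples x {M.shape[1]} features available; "
                f"fitting {k} principal components and zero-padding scores "
                f"to {self.n_components}",
                stacklevel=2,
            )
        self.pca_ = PCA(n_components=k, svd_solver="full", random_state=0).fit(M)
        self.n_components_ = k
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        return self

    def transform(self, X) -> np.ndarray:
        M = self._raw_matrix(X)
        if self.pca_ is None:
            return np.zeros((M.shape[0], self.n_components))
        scores = self.pca_.transform(M)
        if scores.shape[1] < self.n_components:
            pad = np.zeros((scores.shape[0], self.n_components - scores.shape[1]))
            scores = np.hstack([scores, pad])
        return scores

    @property
    def pca_model_(self) -> PCAModel:
        if self.pca_ is None:
            return PCAModel(np.zeros((0, 0)), np.zeros(0), np.zeros(0))
        return PCAModel(
            component_matrix=self.pca_.components_,
            mean_vector=self.pca_.mean_,
            explained_variance_fractions=self.pca_.explained_variance_ratio_,
        )


class PathwayTfidfPCA(_TfidfPCABase):
    """TF-IDF over pathway member tokens (natural tf x smoothed log idf,
    L2-normalized rows), reduced to principal-component scores."""

    def _raw_matrix(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "vectorizer_"):
            self.vectorizer_ = TfidfVectorizer(
                tokenizer=str.split, preprocessor=None, lowercase=False,
                token_pattern=None, norm="l2", smooth_idf=True,
            )
            try:
                return self.vectorizer_.fit_transform(X).toarray()
            except ValueError as exc:
                del self.vectorizer_
                raise FeatureError(f"empty pathway vocabulary: {exc}") from exc
        return self.vectorizer_.transform(X).toarray()

    def fit(self, X, y=None):
        if hasattr(self, "vectorizer_"):
            del self.vectorizer_
        return super().fit(X)


class GeneKmerPCA(_TfidfPCABase):
    """Relative overlapping 3-mer frequencies (64-dim), reduced by PCA."""

    def __init__(self, n_components: int = EMBED_DIM, k: int = 3):
        super().__init__(n_components=n_components)
        self.k = k

    def _raw_matrix(self, X: Sequence[str]) -> np.ndarray:
        return np.vstack([kmer_frequencies(seq, self.k) for seq in X])


def kmer_frequencies(sequence: str, k: int = 3) -> np.ndarray:
    """Sliding-window relative k-mer frequencies, lexicographic ACGT order."""
    if len(sequence) < k:
        raise FeatureError(f"sequence shorter than {k} nt: {sequence!r}")
    counts = np.zeros(4 ** k)
    for i in range(len(sequence) - k + 1):
        idx = _KMER_INDEX.get(sequence[i : i + k])
        if idx is None:
            raise FeatureError(f"invalid nucleotide in k-mer {sequence[i:i + k]!r}")
        counts[idx] += 1
    return counts / counts.sum()


class Node2VecEmbedder(TransformerMixin, BaseEstimator):
    """node2vec over the undirected view of the heterogeneous graph.

    Defaults favour depth-first exploration (p=2 > 1, q=0.5 < 1). Isolated
    nodes receive a zero vector with a warning.
    """

    def __init__(
        self,
        dim: int = EMBED_DIM,
        p: float = 2.0,
        q: float = 0.5,
        walk_length: int = 20,
        num_walks: int = 100,
        window: int = 5,
        epochs: int = 3,
        random_state: int = 0,
    ):
        self.dim = dim
        self.p = p
        self.q = q
        self.walk_length = walk_length
        self.num_walks = num_walks
        self.window = window
        self.epochs = epochs
        self.random_state = random_state

    def fit(self, X: KnowledgeGraph, y=None):
        rng = np.random.default_rng(self.random_state)
        nodes = sorted(X.nodes)
        adj = _undirected_adjacency([(e.source, e.target) for e in X.edges], nodes)
        walks = biased_walks(adj, self.p, self.q, self.walk_length, self.num_walks, rng)
        emb = skipgram_embedding(
            walks, nodes, self.dim, self.window, rng, epochs=self.epochs
        )
        self.embedding_ = {}
        for n, row in zip(nodes, emb):
            if not adj[n]:
                warnings.warn(f"node {n!r} is isolated; zero embedding", stacklevel=2)
                row = np.zeros(self.dim)
            self.embedding_[n] = row
        return self

    def transform(self, node_ids: Sequence[str]) -> np.ndarray:
        return np.vstack([self.embedding_[n] for n in node_ids])


# ---------------------------------------------------------------------------
# functional API


def drug_features(smiles: str, node_id: str = "") -> FeatureVector:
    """32-bit binary ECFP (radius 2); deterministic for a given molecule."""
    try:
        values = MorganFingerprinter().transform([smiles])[0]
    except FeatureError as exc:
        raise FeatureError(f"drug {node_id or '?'}: {exc}") from exc
    return FeatureVector(node_id, values, "ecfp")


def target_features(sequence: str, node_id: str = "") -> FeatureVector:
    try:
        values = _aa_vector(sequence)
    except FeatureError as exc:
        raise FeatureError(f"target {node_id or '?'}: {exc}") from exc
    return FeatureVector(node_id, values, "aa_profile")


def pathway_features(
    pathway_texts: Mapping[str, str]
) -> tuple[dict[str, FeatureVector], PCAModel]:
    ids = sorted(pathway_texts)
    texts = [pathway_texts[i] for i in ids]
    tr = PathwayTfidfPCA().fit(texts)
    scores = tr.transform(texts)
    return (
        {i: FeatureVector(i, row, "tfidf_pca") for i, row in zip(ids, scores)},
        tr.pca_model_,
    )


def gene_features(
    transcripts: Mapping[str, str]
) -> tuple[dict[str, FeatureVector], PCAModel]:
    ids = sorted(transcripts)
    tr = GeneKmerPCA().fit([transcripts[i] for i in ids])
    scores = tr.transform([transcripts[i] for i in ids])
    return (
        {i: FeatureVector(i, row, "kmer_pca") for i, row in zip(ids, scores)},
        tr.pca_model_,
    )


def adr_features(
    g: KnowledgeGraph, dims: int = EMBED_DIM, seed: int = 0, **walk_params
) -> dict[str, FeatureVector]:
    emb = Node2VecEmbedder(dim=dims, random_state=seed, **walk_params).fit(g)
    return {
        a: FeatureVector(a, emb.embedding_[a], "node2vec")
        for a in g.nodes_of_type(EntityType.ADR)
    }


def compute_all_features(
    g: KnowledgeGraph, seed: int = 0, **node2vec_params
) -> dict[str, np.ndarray]:
    """Attribute feature vectors for every node in the graph.

    Nodes whose raw attribute is missing get a zero vector with a warning so
    partially annotated graphs remain usable.
    """
    out: dict[str, np.ndarray] = {}

    def _missing(nid: str) -> np.ndarray:
        warnings.warn(f"node {nid!r} has no raw attribute; zero features", stacklevel=2)
        return np.zeros(EMBED_DIM)

    for nid in g.nodes_of_type(EntityType.DRUG):
        attr = g.nodes[nid].raw_attribute
        out[nid] = drug_features(attr, nid).values if attr else _missing(nid)
    for nid in g.nodes_of_type(EntityType.TARGET):
        attr = g.nodes[nid].raw_attribute
        out[nid] = target_features(attr, nid).values if attr else _missing(nid)

    pw = {
        nid: g.nodes[nid].raw_attribute
        for nid in g.nodes_of_type(EntityType.PATHWAY)
        if g.nodes[nid].raw_attribute
    }
    if pw:
        vecs, _ = pathway_features(pw)
        out.update({i: v.values for i, v in vecs.items()})
    for nid in g.nodes_of_type(EntityType.PATHWAY):
        if nid not in out:
            out[nid] = _missing(nid)

    tx = {
        nid: g.nodes[nid].raw_attribute
        for nid in g.nodes_of_type(EntityType.GENE)
        if g.nodes[nid].raw_attribute
    }
    if tx:
        vecs, _ = gene_features(tx)
        out.update({i: v.values for i, v in vecs.items()})
    for nid in g.nodes_of_type(EntityType.GENE):
        if nid not in out:
            out[nid] = _missing(nid)

    if g.nodes_of_type(EntityType.ADR):
        for nid, fv in adr_features(g, seed=seed, **node2vec_params).items():
            out[nid] = fv.values
    return out
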