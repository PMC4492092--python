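"""Numeric encodings of relation labels, edges, paths and concept pairs.

Two label encodings are supported:

* **plain** (one-of-N) — each distinct label key gets its own indicator
  dimension.  Expressive but high-dimensional; redundant surface forms of
  one underlying relation are unrelated dimensions.
* **lda** — connected concept pairs are treated as documents whose words are
  the labels of the edges between them; a topic model over this corpus
  yields, for every label ``l``, the topic posterior
  ``p(t|l) ∝ p(t)·p(l|t)`` as a dense semantic vector.  Topics play the
  role of the latent "true" relations behind many redundant surface labels.

An edge between two concepts is encoded as the sum of its label vectors
(renormalised to a distribution for the lda encoding).  A path of n
concepts is the flattened outer product of its n−1 edge vectors, so each
dimension of the path feature corresponds to one tuple of label (or topic)
indices — a label sequence.  A pair is the normalised sum of its path
features, with paths of different lengths kept in separate blocks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from .kg import KnowledgeGraph, Label

logger = logging.getLogger(__name__)

PLAIN = "plain"
LDA = "lda"

#: Norm used in the pair-feature normalisation, per encoding: Euclidean for
#: indicator features, L1 (sum) for topic posteriors, which keeps the
#: probabilistic reading.  Overridable per FeatureSpace.
DEFAULT_NORMS = {PLAIN: "l2", LDA: "l1"}


@dataclass
class LdaRelationModel:
    """Fitted topic model over the pair-as-document corpus."""

    n_topics: int
    topic_prior: np.ndarray  # p(t), shape (T,)
    label_given_topic: dict[str, np.ndarray]  # label key -> p(l|t) column, shape (T,)
    alpha: float
    beta: float

    def label_posterior(self, key: str) -> np.ndarray | None:
        """p(t|l) ∝ p(t)·p(l|t), normalised over topics."""
        col = self.label_given_topic.get(key)
        if col is None:
            return None
        joint = self.topic_prior * col
        total = joint.sum()
        if total <= 0:
            return np.full(self.n_topics, 1.0 / self.n_topics)
        return joint / total


class FeatureSpace:
    """Maps each relation label to a fixed-dimension vector.

    ``kind`` is "plain" (one-of-N over a frozen label vocabulary, inverse
    labels included as their own dimensions) or "lda" (topic posteriors).
    Unknown labels map to the zero vector with a logged warning: the space
    is frozen at training time.
    """

    def __init__(
        self,
        kind: str,
        dimension: int,
        label_index: Mapping[str, int] | None = None,
        lda_model: LdaRelationModel | None = None,
        norm: str | None = None,
    ) -> None:
        if kind not in (PLAIN, LDA):
            raise ValueError(f"unknown feature space kind: {kind}")
        self.kind = kind
        self.dimension = dimension
        self.label_index = dict(label_index or {})
        self.lda_model = lda_model
        self.norm = norm or DEFAULT_NORMS[kind]
        self._warned: set[str] = set()

    # -- construction --------------------------------------------------------

    @classmethod
    def plain_from_graph(cls, graph: KnowledgeGraph) -> "FeatureSpace":
        """Freeze a one-of-N vocabulary on the graph's labels and their
        inverses (paths traverse edges in both directions)."""
        keys: set[str] = set()
        for _, label, _, _ in graph.iter_triples():
            keys.add(label.full_key)
            keys.add(label.invert().full_key)
        index = {k: i for i, k in enumerate(sorted(keys))}
        return cls(kind=PLAIN, dimension=len(index), label_index=index)

    @classmethod
    def lda_from_graph(
        cls,
        graph: KnowledgeGraph,
        n_topics: int = 200,
        alpha: float = 0.1,
        beta: float = 0.1,
        seed: int = 0,
        max_iter: int = 50,
    ) -> "FeatureSpace":
        documents = build_pair_documents(graph)
        model = train_lda([doc for _, doc in documents], n_topics, alpha, beta, seed, max_iter)
        return cls(kind=LDA, dimension=n_topics, lda_model=model)

    # -- label/edge encodings ------------------------------------------------

    def label_vector(self, label: Label) -> np.ndarray:
        """Encode one label: indicator (plain) or topic posterior (lda)."""
        key = label.full_key
        if self.kind == PLAIN:
            vec = np.zeros(self.dimension)
            idx = self.label_index.get(key)
            if idx is None:
                self._warn_unknown(key)
            else:
                vec[idx] = 1.0
            return vec
        posterior = self.lda_model.label_posterior(key)
        if posterior is None:
            self._warn_unknown(key)
            return np.zeros(self.dimension)
        return posterior

    def _warn_unknown(self, key: str) -> None:
        if key not in self._warned:
            self._warned.add(key)
            logger.warning("label unknown to frozen feature space: %s", key)

    def edge_feature(self, graph: KnowledgeGraph, ci: str, cj: str) -> np.ndarray:
        """Sum of label vectors over all edges between ci and cj (both
        directions, multiplicity counted); lda vectors are renormalised to
        sum 1.  Disconnected pairs yield the zero vector."""
        total = np.zeros(self.dimension)
        for full_key, count in graph.edges_between(ci, cj).items():
            total += count * self.label_vector(Label.from_full_key(full_key))
        if self.kind == LDA:
            s = total.sum()
            if s > 0:
                total = total / s
        return total

    # -- serialization ---------------------------------------------------------

    def save(self, path: str) -> None:
        payload: dict = {
            "format_version": 1,
            "kind": self.kind,
            "dimension": self.dimension,
            "norm": self.norm,
        }
        if self.kind == PLAIN:
            payload["label_index"] = self.label_index
        else:
            m = self.lda_model
            payload["lda"] = {
                "n_topics": m.n_topics,
                "alpha": m.alpha,
                "beta": m.beta,
                "topic_prior": m.topic_prior.tolist(),
                "label_given_topic": {k: v.tolist() for k, v in m.label_given_topic.items()},
            }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "FeatureSpace":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload["kind"] == PLAIN:
            return cls(
                kind=PLAIN,
                dimension=payload["dimension"],
                label_index=payload["label_index"],
                norm=payload["norm"],
            )
        lda = payload["lda"]
        model = LdaRelationModel(
            n_topics=lda["n_topics"],
            topic_prior=np.asarray(lda["topic_prior"]),
            label_given_topic={k: np.asarray(v) for k, v in lda["label_given_topic"].items()},
            alpha=lda["alpha"],
            beta=lda["beta"],
        )
        return cls(kind=LDA, dimension=payload["dimension"], lda_model=model, norm=payload["norm"])


# -- pair-as-document corpus ---------------------------------------------------


def build_pair_documents(graph: KnowledgeGraph) -> list[tuple[tuple[str, str], dict[str, int]]]:
    """One bag-of-labels document per connected unordered pair.

    The pair is oriented by sorted concept id; edges stored against that
    orientation contribute their inverse-marked key.  Each stored edge
    contributes one word per multiplicity unit (the inverse is not added as
    an extra word for the same edge).
    """
    documents = []
    for ci, cj in sorted(graph.connected_pairs()):
        bag = dict(graph.edges_between(ci, cj, directed=False))
        documents.append(((ci, cj), bag))
    return documents


def train_lda(
    documents: Sequence[Mapping[str, int]],
    n_topics: int,
    alpha: float = 0.1,
    beta: float = 0.1,
    seed: int = 0,
    max_iter: int = 50,
) -> LdaRelationModel:
    """Fit the topic model on bag-of-labels documents.

    Hyper-parameters well below 1 encode that a concept pair typically
    realises very few true relations and each relation uses few surface
    labels.  Batch variational inference, deterministic given the seed.
    """
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    if not documents:
        raise ValueError("empty corpus")
    vocab = sorted({w for doc in documents for w in doc})
    if not vocab:
        raise ValueError("empty corpus")
    vocab_index = {w: i for i, w in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for d, doc in enumerate(documents):
        for w, n in doc.items():
            rows.append(d)
            cols.append(vocab_index[w])
            vals.append(n)
    X = sparse.csr_matrix((vals, (rows, cols)), shape=(len(documents), len(vocab)))
    if n_topics == 1:
        # degenerate single-topic model: every label maps to (1.0,)
        counts = np.asarray(X.sum(axis=0)).ravel()
        probs = counts / counts.sum()
        return LdaRelationModel(
            n_topics=1,
            topic_prior=np.array([1.0]),
            label_given_topic={w: np.array([probs[i]]) for w, i in vocab_index.items()},
            alpha=alpha,
            beta=beta,
        )
    lda = LatentDirichletAllocation(
        n_components=n_topics,
        doc_topic_prior=alpha,
        topic_word_prior=beta,
        learning_method="batch",
        max_iter=max_iter,
        random_state=seed,
    )
    doc_topic = lda.fit_transform(X)
    # p(l|t): rows of the fitted topic-word pseudo-counts, normalised
    word_given_topic = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    # p(t): corpus-level topic mass, length-weighted over documents
    lengths = np.asarray(X.sum(axis=1)).ravel()
    topic_mass = (doc_topic * lengths[:, None]).sum(axis=0)
    topic_prior = topic_mass / topic_mass.sum()
    label_given_topic = {w: word_given_topic[:, i].copy() for w, i in vocab_index.items()}
    return LdaRelationModel(
        n_topics=n_topics,
        topic_prior=topic_prior,
        label_given_topic=label_given_topic,
        alpha=alpha,
        beta=beta,
    )


# -- path and pair features ----------------------------------------------------


def flatten_index(index_tuple: Sequence[int], n_dims: int) -> int:
    """Row-major flattening of a tuple in {0..N-1}^(n-1): the last index
    varies fastest, matching the column-stacked outer-product layout."""
    flat = 0
    for i in index_tuple:
        if not 0 <= i < n_dims:
            raise ValueError(f"index {i} out of range [0, {n_dims})")
        flat = flat * n_dims + i
    return flat


def unflatten_index(flat: int, n_dims: int, order: int) -> tuple[int, ...]:
    """Inverse of :func:`flatten_index` for a tuple of ``order`` components."""
    if not 0 <= flat < n_dims**order:
        raise ValueError(f"flat index {flat} out of range")
    out = []
    for _ in range(order):
        out.append(flat % n_dims)
        flat //= n_dims
    return tuple(reversed(out))


@dataclass
class PathFeature:
    """Sparse flattened outer product of a path's edge features."""

    n_concepts: int  # path length n; the tensor has n-1 modes
    dimension: int  # N^(n-1)
    values: dict[int, float]  # flat index -> value

    @property
    def order(self) -> int:
        return self.n_concepts - 1


def path_feature(
    space: FeatureSpace, path: Sequence[str], graph: KnowledgeGraph
) -> PathFeature:
    """Flattened outer product of the n−1 edge features along the path.

    Any all-zero edge feature makes the whole product zero (logged): the
    path crosses an edge the frozen space cannot encode.
    """
    n = len(path)
    edge_vecs = [space.edge_feature(graph, a, b) for a, b in zip(path, path[1:])]
    values: dict[int, float] = {}
    sparse_vecs = []
    for vec in edge_vecs:
        nz = np.nonzero(vec)[0]
        if nz.size == 0:
            logger.info("all-zero edge feature on path %s", path)
            return PathFeature(n, space.dimension ** (n - 1), {})
        sparse_vecs.append([(int(i), float(vec[i])) for i in nz])
    # iterative sparse outer product over the edge vectors
    partial: dict[tuple[int, ...], float] = {(): 1.0}
    for vec in sparse_vecs:
        partial = {
            idx + (i,): v * x for idx, v in partial.items() for i, x in vec
        }
    for idx, v in partial.items():
        values[flatten_index(idx, space.dimension)] = v
    return PathFeature(n, space.dimension ** (n - 1), values)


class PairFeatureLayout:
    """Fixed block layout for pair features: one block per allowed path
    length, concatenated in increasing length order."""

    def __init__(self, dimension: int, lengths: Sequence[int]) -> None:
        self.dimension = dimension
        self.lengths = tuple(sorted(lengths))
        self.offsets: dict[int, int] = {}
        off = 0
        for n in self.lengths:
            self.offsets[n] = off
            off += dimension ** (n - 1)
        self.total_dimension = off

    def decode(self, flat: int) -> tuple[int, tuple[int, ...]]:
        """Map a flat pair-feature dimension back to (path length, index tuple)."""
        for n in reversed(self.lengths):
            if flat >= self.offsets[n]:
                return n, unflatten_index(flat - self.offsets[n], self.dimension, n - 1)
        raise ValueError(f"flat index {flat} out of layout range")


def pair_feature(
    space: FeatureSpace,
    paths: Iterable[Sequence[str]],
    graph: KnowledgeGraph,
    layout: PairFeatureLayout,
) -> sparse.csr_matrix:
    """Normalised sum of the path features of one concept pair.

    Paths of equal length are summed within their block; the concatenated
    vector is normalised to unit norm (Euclidean or L1 per the space's
    convention).  An empty path set yields the zero vector.
    """
    acc: dict[int, float] = {}
    for path in paths:
        n = len(path)
        if n not in layout.offsets:
            continue
        pf = path_feature(space, path, graph)
        off = layout.offsets[n]
        for idx, v in pf.values.items():
            acc[off + idx] = acc.get(off + idx, 0.0) + v
    if acc:
        vals = np.array(list(acc.values()))
        norm = np.sqrt((vals**2).sum()) if space.norm == "l2" else np.abs(vals).sum()
        if norm > 0:
            acc = {k: v / norm for k, v in acc.items()}
    cols = np.fromiter(acc.keys(), dtype=np.int64, count=len(acc))
    data = np.fromiter(acc.values(), dtype=np.float64, count=len(acc))
    return sparse.csr_matrix(
        (data, (np.zeros(len(acc), dtype=np.int64), cols)),
        shape=(1, layout.total_dimension),
    )


def path_sequence_features(
    space: FeatureSpace, path: Sequence[str], graph: KnowledgeGraph
) -> np.ndarray:
    """The (n−1, N) sequence of edge features along a path, oriented
    source → target; input for the sequence classifiers."""
    return np.vstack([space.edge_feature(graph, a, b) for a, b in zip(path, path[1:])])
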