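"""Confidence scorers for relation discovery.

Three model families assign a pair of concepts a confidence in [0, 1] that
the query relation holds, given the graph paths connecting them:

* **pair-based logistic regression** — one feature vector per pair (the
  normalised sum of flattened outer-product path features), L2-regularised
  LR fitted with LBFGS.  With the plain encoding its dimensions are label
  sequences, so the highest-weighted dimensions decode directly into the
  characteristic path patterns the model has learned.
* **path-based logistic regression** — one vector per path: the edge
  feature sequence zero-padded to ``m·N`` (tail padding); pair score =
  mean of the best k path scores.
* **dual hidden Markov models** — one HMM fitted on positive example paths
  and one on negative ones; a path's score combines the two forward
  likelihoods as ``p(P|q) / (p(P|q) + p(P|¬q))`` under the working
  assumption ``p(q) = p(¬q)`` (the ranking, not the calibrated probability,
  is what matters here).

The HMM observation model is not uniquely determined by the method
description; two reconstructions are provided and tagged on the model: a
categorical HMM over the label vocabulary (plain encoding: each edge emits
its label multiset, in index order) and a diagonal-covariance Gaussian HMM
over topic posteriors (lda encoding: each edge emits its edge feature).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from hmmlearn.hmm import CategoricalHMM, GaussianHMM

from .features import FeatureSpace, PairFeatureLayout

logger = logging.getLogger(__name__)

CATEGORICAL = "categorical"
GAUSSIAN = "gaussian"


# -- logistic regression (pair- and path-based) --------------------------------


@dataclass
class PairLRModel:
    """L2-regularised logistic regression over pair features."""

    weights: np.ndarray
    intercept: float
    l2_strength: float
    layout: PairFeatureLayout
    space_kind: str

    def score(self, feature: sparse.spmatrix | np.ndarray) -> float:
        return float(self.score_many(feature)[0])

    def score_many(self, features: sparse.spmatrix | np.ndarray) -> np.ndarray:
        if features.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {features.shape[1]} != model dimension {self.weights.shape[0]}"
            )
        z = features @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-np.asarray(z).ravel()))


def train_pair_lr(
    features: sparse.spmatrix,
    labels: Sequence[int],
    layout: PairFeatureLayout,
    space_kind: str,
    l2_strength: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PairLRModel:
    """Fit the pair-based LR by LBFGS on the L2-penalised log-likelihood.

    ``l2_strength`` is the coefficient of ``0.5·||w||²`` in the penalised
    negative log-likelihood (the intercept is unpenalised).  Deterministic
    given the inputs; requires at least one example of each class.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = LogisticRegression(
        C=1.0 / l2_strength,
        solver="lbfgs",
        tol=tol,
        max_iter=max_iter,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        clf.fit(features, y)
    for w in caught:
        if "ConvergenceWarning" in type(w.message).__name__:
            logger.warning("pair LR did not converge within %d iterations", max_iter)
    return PairLRModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        l2_strength=l2_strength,
        layout=layout,
        space_kind=space_kind,
    )


@dataclass
class PathLRModel:
    """Logistic regression over tail-padded edge-feature sequences."""

    weights: np.ndarray
    intercept: float
    max_length: int  # m: maximum path length in concepts
    dimension: int  # N: per-edge feature dimension

    def encode(self, sequence: np.ndarray) -> np.ndarray:
        """Pad an (n-1, N) edge-feature sequence to a flat (m-1)·N vector."""
        flat = np.zeros((self.max_length - 1) * self.dimension)
        k = min(sequence.shape[0], self.max_length - 1)
        flat[: k * self.dimension] = sequence[:k].ravel()
        return flat

    def score_path(self, sequence: np.ndarray) -> float:
        z = self.encode(sequence) @ self.weights + self.intercept
        return float(1.0 / (1.0 + np.exp(-z)))


def train_path_lr(
    pos_sequences: Sequence[np.ndarray],
    neg_sequences: Sequence[np.ndarray],
    max_length: int,
    dimension: int,
    l2_strength: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PathLRModel:
    if not pos_sequences or not neg_sequences:
        raise ValueError("both positive and negative path sequences are required")
    model = PathLRModel(
        weights=np.zeros((max_length - 1) * dimension),
        intercept=0.0,
        max_length=max_length,
        dimension=dimension,
    )
    X = np.vstack([model.encode(s) for s in list(pos_sequences) + list(neg_sequences)])
    y = np.array([1] * len(pos_sequences) + [0] * len(neg_sequences))
    clf = LogisticRegression(
        C=1.0 / l2_strength, solver="lbfgs", tol=tol, max_iter=max_iter
    )
    clf.fit(X, y)
    model.weights = clf.coef_.ravel().copy()
    model.intercept = float(clf.intercept_[0])
    return model


# -- dual hidden Markov models --------------------------------------------------


@dataclass
class DualHMM:
    """Positive/negative HMM pair with a tagged emission family."""

    positive: CategoricalHMM | GaussianHMM
    negative: CategoricalHMM | GaussianHMM
    emission: str  # CATEGORICAL or GAUSSIAN
    n_states: int
    pos_history: list[float] = field(default_factory=list)
    neg_history: list[float] = field(default_factory=list)

    def score_path(self, sequence: np.ndarray) -> float:
        return hmm_path_score(self, sequence)


def _fit_hmm(
    sequences: Sequence[np.ndarray],
    n_states: int,
    emission: str,
    seed: int,
    max_iter: int,
    tol: float,
):
    lengths = [len(s) for s in sequences]
    if emission == CATEGORICAL:
        X = np.concatenate(sequences).reshape(-1, 1).astype(int)
        model = CategoricalHMM(
            n_components=n_states,
            n_iter=max_iter,
            tol=tol,
            random_state=seed,
            init_params="ste",
        )
    else:
        X = np.vstack(sequences)
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            random_state=seed,
            min_covar=1e-3,
            init_params="stmc",
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, lengths)
    return model, list(model.monitor_.history)


def train_dual_hmm(
    pos_sequences: Sequence[np.ndarray],
    neg_sequences: Sequence[np.ndarray],
    n_states: int = 4,
    emission: str = CATEGORICAL,
    seed: int = 0,
    max_iter: int = 50,
    tol: float = 1e-3,
) -> DualHMM:
    """Baum-Welch training of the positive and negative HMMs.

    Categorical sequences are integer symbol arrays; Gaussian sequences are
    (n_steps, N) float arrays.  Deterministic given the seed.
    """
    if emission not in (CATEGORICAL, GAUSSIAN):
        raise ValueError(f"unknown emission family: {emission}")
    for name, seqs in (("positive", pos_sequences), ("negative", neg_sequences)):
        if not seqs:
            raise ValueError(f"empty {name} training set")
        if all(len(s) == 0 for s in seqs):
            raise ValueError(f"degenerate {name} training set: all sequences empty")
    pos_sequences = [s for s in pos_sequences if len(s) > 0]
    neg_sequences = [s for s in neg_sequences if len(s) > 0]
    if emission == CATEGORICAL:
        # both models must share the symbol alphabet
        n_symbols = int(max(np.concatenate(pos_sequences + neg_sequences))) + 1
        pos, pos_hist = _fit_hmm(pos_sequences, n_states, emission, seed, max_iter, tol)
        neg, neg_hist = _fit_hmm(neg_sequences, n_states, emission, seed, max_iter, tol)
        for m in (pos, neg):
            if m.emissionprob_.shape[1] < n_symbols:
                pad = np.full((n_states, n_symbols - m.emissionprob_.shape[1]), 1e-12)
                probs = np.hstack([m.emissionprob_, pad])
                m.emissionprob_ = probs / probs.sum(axis=1, keepdims=True)
                m.n_features = n_symbols
    else:
        pos, pos_hist = _fit_hmm(pos_sequences, n_states, emission, seed, max_iter, tol)
        neg, neg_hist = _fit_hmm(neg_sequences, n_states, emission, seed, max_iter, tol)
    return DualHMM(
        positive=pos,
        negative=neg,
        emission=emission,
        n_states=n_states,
        pos_history=pos_hist,
        neg_history=neg_hist,
    )


def _hmm_loglik(model, sequence: np.ndarray, emission: str) -> float:
    if len(sequence) == 0:
        return -np.inf
    if emission == CATEGORICAL:
        X = np.asarray(sequence).reshape(-1, 1).astype(int)
        if X.max() >= model.emissionprob_.shape[1]:
            return -np.inf  # symbol unseen by this model
    else:
        X = np.atleast_2d(sequence)
    try:
        return float(model.score(X))
    except ValueError:
        return -np.inf


def hmm_path_score(model: DualHMM, sequence: np.ndarray) -> float:
    """Combine the forward likelihoods of the two HMMs:
    ``p(P|q) / (p(P|q) + p(P|¬q))``, computed in log space as
    ``1 / (1 + exp(logp_neg − logp_pos))``.  Both likelihoods −∞ → 0.5."""
    lp = _hmm_loglik(model.positive, sequence, model.emission)
    ln = _hmm_loglik(model.negative, sequence, model.emission)
    if np.isneginf(lp) and np.isneginf(ln):
        return 0.5
    if np.isneginf(lp):
        return 0.0
    if np.isneginf(ln):
        return 1.0
    diff = np.clip(ln - lp, -700, 700)
    return float(1.0 / (1.0 + np.exp(diff)))


# -- pooling and interpretation --------------------------------------------------


def pair_score_from_paths(path_scores: Sequence[float], k: int = 3) -> tuple[float, bool]:
    """Mean of the k best path scores; fewer than k paths → mean of all.

    Returns ``(score, has_paths)``; an empty score list yields (0.0, False).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scores = sorted(path_scores, reverse=True)
    if not scores:
        return 0.0, False
    top = scores[: min(k, len(scores))]
    return float(np.mean(top)), True


def top_weighted_patterns(
    model: PairLRModel, space: FeatureSpace, top_n: int = 10
) -> list[tuple[tuple[str, ...], float]]:
    """Decode the model's highest-weighted dimensions into label sequences.

    Only meaningful for the plain encoding, where each dimension is a tuple
    of label indices; topic dimensions do not decode into labels.
    """
    if space.kind != "plain":
        raise ValueError("pattern decoding requires a plain (one-of-N) feature space")
    inverse_index = {i: k for k, i in space.label_index.items()}
    order = np.argsort(model.weights)[::-1][:top_n]
    out = []
    for flat in order:
        _, index_tuple = model.layout.decode(int(flat))
        labels = tuple(inverse_index[i] for i in index_tuple)
        out.append((labels, float(model.weights[flat])))
    return out
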