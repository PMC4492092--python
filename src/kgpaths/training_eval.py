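"""Distant-supervision training and cross-validated evaluation.

Positive concept pairs for a query relation ``q`` come from a structured
source; every graph path between such a pair is treated as a (noisy)
positive example of ``q``.  Negative pairs are built by re-pairing the
positive sources with random positive targets, which forces the models to
learn about the paths between pairs rather than about the concepts
themselves.  During path collection the query relation, its inverse and the
sibling relation are excluded so that the label being predicted (or a
trivial surrogate of it) can never leak into the features, and direct
connections are excluded when the goal is discovery from indirect knowledge.

Evaluation is 10-fold cross-validation over concept pairs (never over
paths, so one pair's paths cannot appear on both sides of a split), pooled
into a single ROC curve and its AUC.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import models as _models
from .features import (
    PLAIN,
    FeatureSpace,
    PairFeatureLayout,
    pair_feature,
    path_sequence_features,
)
from .kg import KnowledgeGraph, Label
from .pathsearch import SearchConfig, find_paths

logger = logging.getLogger(__name__)

#: Label excluded from training paths in addition to the query relation:
#: siblings share a parent concept and trivially mirror the query relation.
SIBLING_LABEL = "SIB"

Pair = tuple[str, str]


@dataclass
class RelationDataset:
    """Positive and negative concept pairs for one query relation."""

    relation: str  # query label key q
    positives: list[Pair]
    negatives: list[Pair]
    provenance: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"positive/negative overlap: {sorted(overlap)[:3]}...")


@dataclass
class ModelSpec:
    """Which scorer to train and how."""

    model: str = "lr-pair"  # lr-pair | lr-path | hmm-path
    encoding: str = PLAIN  # plain | lda
    path_lengths: tuple[int, ...] = (3,)
    k: int = 3  # top-k pooling for path-based scorers
    n_states: int = 4  # HMM hidden states
    l2_strength: float = 1.0
    lda_topics: int = 200
    lda_alpha: float = 0.1
    lda_beta: float = 0.1
    noise_prune_iterations: int = 0
    noise_prune_threshold: float = 0.5
    seed: int = 0


@dataclass
class EvalResult:
    auc: float
    roc_fpr: list[float]
    roc_tpr: list[float]
    fold_scores: list[list[float]]
    fold_labels: list[list[int]]
    n_excluded_no_paths: int
    n_unscoreable: int
    config: dict

    def to_dict(self) -> dict:
        return asdict(self)


# -- dataset assembly ------------------------------------------------------------


def sample_negatives(
    e_plus: Sequence[Pair], r_q: Iterable[Pair], seed: int = 0
) -> list[Pair]:
    """Re-pair each positive source with a random positive target.

    Candidates already known to be in the relation (``r_q``) or already
    drawn are rejected; a source whose candidate pool is exhausted
    contributes nothing, so the negative set may come out slightly smaller
    than the positive set.
    """
    if len(e_plus) < 2:
        raise ValueError("need at least two positive pairs")
    rng = np.random.default_rng(seed)
    known = set(r_q) | set(e_plus)
    targets = [t for _, t in e_plus]
    negatives: list[Pair] = []
    taken: set[Pair] = set()
    for source, _ in e_plus:
        order = rng.permutation(len(targets))
        for idx in order:
            candidate = (source, targets[idx])
            if candidate in known or candidate in taken or candidate[0] == candidate[1]:
                continue
            negatives.append(candidate)
            taken.add(candidate)
            break
    return negatives


def dedupe_concepts(pairs: Sequence[Pair]) -> list[Pair]:
    """Optional dataset filter: greedily keep only the first pair in which
    each source or target concept appears, so no concept occurs twice."""
    seen: set[str] = set()
    kept = []
    for s, t in pairs:
        if s in seen or t in seen:
            continue
        kept.append((s, t))
        seen.update((s, t))
    return kept


def collect_paths(
    graph: KnowledgeGraph,
    dataset: RelationDataset,
    search_config: SearchConfig,
) -> tuple[dict[Pair, set[tuple[str, ...]]], list[Pair]]:
    """Per-pair path sets under the training exclusions.

    The query relation (and thereby its inverse) and the sibling label are
    always excluded.  Pairs whose concepts are missing from the graph are
    returned separately as unscoreable.
    """
    excluded = frozenset(search_config.excluded_labels | {dataset.relation, SIBLING_LABEL})
    config = SearchConfig(
        max_length=search_config.max_length,
        hub_degree_threshold=search_config.hub_degree_threshold,
        h=search_config.h,
        time_budget=search_config.time_budget,
        excluded_labels=excluded,
        exclude_direct=search_config.exclude_direct,
        rng_seed=search_config.rng_seed,
        deterministic=search_config.deterministic,
    )
    path_sets: dict[Pair, set[tuple[str, ...]]] = {}
    unscoreable: list[Pair] = []
    for pair in list(dataset.positives) + list(dataset.negatives):
        s, t = pair
        if s not in graph or t not in graph:
            unscoreable.append(pair)
            continue
        result = find_paths(graph, s, t, config)
        if result.truncated:
            logger.warning("path search truncated for pair %s", pair)
        path_sets[pair] = result.paths
    return path_sets, unscoreable


# -- noise pruning ----------------------------------------------------------------


def prune_noisy_positives(
    train_fn: Callable[[list, list], object],
    pos_paths: Sequence,
    neg_paths: Sequence,
    threshold: float = 0.5,
    iterations: int = 1,
):
    """Iteratively drop positive paths the current model scores <= threshold.

    Under distant supervision most paths between positive pairs do not
    express the relation; training once, discarding low-scoring positives
    and retraining on the pruned set against the original negatives cleans
    the positive path distribution.  Returns (pruned positive paths,
    retrained scorer).  Scores must come from a ``score_path`` method.
    """
    current = list(pos_paths)
    scorer = train_fn(current, list(neg_paths))
    for _ in range(iterations):
        kept = [p for p in current if scorer.score_path(p) > threshold]
        if not kept:
            raise ValueError(
                f"noise pruning at threshold {threshold} removed every positive path "
                f"({len(current)} candidates)"
            )
        current = kept
        scorer = train_fn(current, list(neg_paths))
    return current, scorer


# -- ROC / AUC ---------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> dict:
    """ROC by threshold sweep (ties grouped) and trapezoidal AUC, equal to
    the normalised Mann-Whitney U statistic with ties counted half."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(y, s)
    return {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": float(roc_auc_score(y, s))}


# -- model training within a fold ---------------------------------------------------


def _symbol_sequence(
    space: FeatureSpace, path: tuple[str, ...], graph: KnowledgeGraph
) -> np.ndarray:
    """Discrete observation sequence for the categorical HMM: each edge
    emits its label multiset as plain-vocabulary indices, in index order."""
    symbols: list[int] = []
    for a, b in zip(path, path[1:]):
        step = []
        for full_key, count in graph.edges_between(a, b).items():
            idx = space.label_index.get(full_key)
            if idx is not None:
                step.extend([idx] * count)
        symbols.extend(sorted(step))
    return np.asarray(symbols, dtype=int)


def build_feature_space(
    graph: KnowledgeGraph, spec: ModelSpec
) -> FeatureSpace:
    if spec.encoding == PLAIN:
        return FeatureSpace.plain_from_graph(graph)
    return FeatureSpace.lda_from_graph(
        graph,
        n_topics=spec.lda_topics,
        alpha=spec.lda_alpha,
        beta=spec.lda_beta,
        seed=spec.seed,
    )


class _PairLRScorer:
    def __init__(self, model, space, layout, graph):
        self.model, self.space, self.layout, self.graph = model, space, layout, graph

    def score_pair(self, paths) -> float:
        feat = pair_feature(self.space, paths, self.graph, self.layout)
        return self.model.score(feat)


class _PathScorer:
    """Wraps a path-level scorer (path-LR or dual HMM) with top-k pooling."""

    def __init__(self, scorer, encode_fn, k: int):
        self.scorer, self.encode_fn, self.k = scorer, encode_fn, k

    def score_pair(self, paths) -> float:
        scores = [self.scorer.score_path(self.encode_fn(p)) for p in paths]
        score, _ = _models.pair_score_from_paths(scores, k=self.k)
        return score


def train_scorer(
    graph: KnowledgeGraph,
    space: FeatureSpace,
    spec: ModelSpec,
    train_pairs: Sequence[Pair],
    train_labels: Sequence[int],
    path_sets: Mapping[Pair, set[tuple[str, ...]]],
):
    """Fit the scorer named by the spec on the training pairs' paths."""
    layout = PairFeatureLayout(space.dimension, spec.path_lengths)
    if spec.model == "lr-pair":
        X = sparse.vstack(
            [pair_feature(space, path_sets[p], graph, layout) for p in train_pairs]
        )
        model = _models.train_pair_lr(
            X.tocsr(), train_labels, layout, space.kind, l2_strength=spec.l2_strength
        )
        return _PairLRScorer(model, space, layout, graph)

    max_len = max(spec.path_lengths)
    if spec.model == "hmm-path" and spec.encoding == PLAIN:
        encode = lambda p: _symbol_sequence(space, p, graph)  # noqa: E731
    else:
        encode = lambda p: path_sequence_features(space, p, graph)  # noqa: E731
    pos_seqs, neg_seqs = [], []
    for pair, label in zip(train_pairs, train_labels):
        for path in sorted(path_sets[pair]):
            if len(path) not in spec.path_lengths:
                continue
            (pos_seqs if label == 1 else neg_seqs).append(encode(path))
    if spec.model == "lr-path":
        train_fn = lambda pos, neg: _models.train_path_lr(  # noqa: E731
            pos, neg, max_length=max_len, dimension=space.dimension, l2_strength=spec.l2_strength
        )
    elif spec.model == "hmm-path":
        emission = _models.CATEGORICAL if spec.encoding == PLAIN else _models.GAUSSIAN
        train_fn = lambda pos, neg: _models.train_dual_hmm(  # noqa: E731
            pos, neg, n_states=spec.n_states, emission=emission, seed=spec.seed
        )
    else:
        raise ValueError(f"unknown model: {spec.model}")
    if spec.noise_prune_iterations > 0:
        _, scorer = prune_noisy_positives(
            train_fn,
            pos_seqs,
            neg_seqs,
            threshold=spec.noise_prune_threshold,
            iterations=spec.noise_prune_iterations,
        )
    else:
        scorer = train_fn(pos_seqs, neg_seqs)
    return _PathScorer(scorer, encode, spec.k)


# -- cross-validation ----------------------------------------------------------------


def cross_validate(
    graph: KnowledgeGraph,
    dataset: RelationDataset,
    spec: ModelSpec,
    search_config: SearchConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    include_no_path_pairs: bool = False,
    max_fold_retries: int = 5,
    path_sets: Mapping[Pair, set[tuple[str, ...]]] | None = None,
) -> EvalResult:
    """Stratified k-fold CV over concept pairs, pooled ROC/AUC.

    Pairs without any path of an allowed length are excluded from training
    and evaluation (counted in the result) unless ``include_no_path_pairs``,
    in which case they are evaluated with score 0 — the mode used to measure
    how many positives become scoreable at all as longer paths are allowed.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    search_config = search_config or SearchConfig()
    if path_sets is None:
        path_sets, unscoreable = collect_paths(graph, dataset, search_config)
    else:
        unscoreable = [p for p in dataset.positives + dataset.negatives if p not in path_sets]

    def usable(pair: Pair) -> set[tuple[str, ...]]:
        return {
            p for p in path_sets.get(pair, set()) if len(p) in spec.path_lengths
        }

    labelled = [(p, 1) for p in dataset.positives] + [(p, 0) for p in dataset.negatives]
    labelled = [(p, y) for p, y in labelled if p not in set(unscoreable)]
    with_paths = [(p, y) for p, y in labelled if usable(p)]
    n_excluded = len(labelled) - len(with_paths)
    eval_set = labelled if include_no_path_pairs else with_paths
    pairs = [p for p, _ in eval_set]
    y = np.array([lab for _, lab in eval_set])
    if len(np.unique(y)) < 2:
        raise ValueError("dataset is degenerate after path filtering")

    usable_sets = {p: usable(p) for p in pairs}
    space = build_feature_space(graph, spec)

    fold_scores: list[list[float]] = []
    fold_labels: list[list[int]] = []
    for attempt in range(max_fold_retries):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(pairs)), y))
        train_ok = all(
            len(np.unique(y[tr])) == 2
            and any(usable_sets[pairs[i]] for i in tr if y[i] == 1)
            and any(usable_sets[pairs[i]] for i in tr if y[i] == 0)
            for tr, _ in splits
        )
        if train_ok:
            break
    else:
        raise ValueError("could not draw folds with both classes present")

    for train_idx, test_idx in splits:
        train_pairs = [pairs[i] for i in train_idx if usable_sets[pairs[i]]]
        train_y = [int(y[i]) for i in train_idx if usable_sets[pairs[i]]]
        scorer = train_scorer(graph, space, spec, train_pairs, train_y, usable_sets)
        scores = []
        for i in test_idx:
            paths = usable_sets[pairs[i]]
            scores.append(scorer.score_pair(paths) if paths else 0.0)
        fold_scores.append(scores)
        fold_labels.append([int(y[i]) for i in test_idx])

    pooled_scores = [s for fold in fold_scores for s in fold]
    pooled_labels = [l for fold in fold_labels for l in fold]
    roc = roc_auc(pooled_scores, pooled_labels)
    config = {
        "model": asdict(spec),
        "folds": folds,
        "seed": seed,
        "include_no_path_pairs": include_no_path_pairs,
        "search": {
            "max_length": search_config.max_length,
            "hub_degree_threshold": search_config.hub_degree_threshold,
            "h": search_config.h,
            "time_budget": search_config.time_budget,
            "exclude_direct": search_config.exclude_direct,
            "excluded_labels": sorted(search_config.excluded_labels),
        },
        "relation": dataset.relation,
    }
    return EvalResult(
        auc=roc["auc"],
        roc_fpr=roc["fpr"],
        roc_tpr=roc["tpr"],
        fold_scores=fold_scores,
        fold_labels=fold_labels,
        n_excluded_no_paths=n_excluded,
        n_unscoreable=len(unscoreable),
        config=config,
    )
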