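"""Graph path discovery between a source and a target concept.

Paths are simple tuples of concepts ``(c1, ..., cn)`` with at least one
usable edge (in either direction) between consecutive concepts; "length"
counts concepts, so a direct connection has length 2 and indirect knowledge
means length > 2.

The search is bidirectional: partial simple paths are grown from both
endpoints to roughly half the maximum length and joined where the frontiers
meet.  Three pruning devices keep the search tractable on dense graphs:

* hub exclusion — vertices with degree above a threshold are never used as
  intermediates (they are overly general concepts such as *cell*);
* synonym blocking — a concept that is a synonym of any concept already on
  the partial path is not explored (it would duplicate the path's meaning);
* stochastic frontier expansion — each neighbour is expanded with
  probability ``min(1, sqrt(h + |N(c)|) / |N(c)|)``, damping exploration
  from highly connected vertices while keeping it exhaustive elsewhere.

A per-pair wall-clock budget truncates pathological searches; partial
results are returned with a truncation flag.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from .kg import KnowledgeGraph, Label


class ConceptNotInGraphError(KeyError):
    pass


@dataclass
class SearchConfig:
    max_length: int = 4  # concepts per path (m)
    hub_degree_threshold: int = 100_000
    h: float = 100_000.0  # smoothing constant of the exploration probability
    time_budget: float = 40.0  # seconds per pair
    excluded_labels: frozenset[str] = frozenset()  # label keys (kind-less)
    exclude_direct: bool = True
    rng_seed: int = 0
    deterministic: bool = False  # forces every expansion (p_explore = 1)

    def __post_init__(self) -> None:
        if self.max_length < 2:
            raise ValueError("max_length must be >= 2")
        if self.h < 0:
            raise ValueError("h must be >= 0")


@dataclass
class SearchResult:
    paths: set[tuple[str, ...]]
    truncated: bool = False


def p_explore(graph: KnowledgeGraph, ci: str, config: SearchConfig) -> float:
    """Probability of expanding the search from ``ci`` to one neighbour."""
    n = len(graph.neighbors(ci))
    if n == 0:
        return 1.0
    return min(1.0, math.sqrt(config.h + n) / n)


def _edge_usable(graph: KnowledgeGraph, a: str, b: str, excluded: frozenset[str]) -> bool:
    """An edge between a and b is usable if at least one label (either
    direction) is not excluded.  Exclusion is by bare label key, covering
    the label and its inverse alike."""
    for full_key in graph.edges_between(a, b):
        if Label.from_full_key(full_key).key not in excluded:
            return True
    return False


def _is_hub(graph: KnowledgeGraph, c: str, config: SearchConfig) -> bool:
    return graph.degree(c) > config.hub_degree_threshold


def _valid_extension(
    graph: KnowledgeGraph, path: tuple[str, ...], nxt: str, config: SearchConfig
) -> bool:
    """May ``nxt`` follow ``path``?  Applies simplicity, hub exclusion,
    synonym blocking and edge usability; endpoints are exempt from the hub
    rule (they are the query)."""
    if nxt in path:
        return False
    if not _edge_usable(graph, path[-1], nxt, config.excluded_labels):
        return False
    syns = graph.synonyms(nxt)
    if any(c in syns for c in path):
        return False
    return True


def path_is_valid(
    graph: KnowledgeGraph, path: tuple[str, ...], config: SearchConfig
) -> bool:
    """Check the full GraphPath invariants for a candidate tuple."""
    if len(path) < 2 or len(path) > config.max_length:
        return False
    if len(set(path)) != len(path):
        return False
    for c in path[1:-1]:
        if _is_hub(graph, c, config):
            return False
    cur = (path[0],)
    for nxt in path[1:]:
        if not _valid_extension(graph, cur, nxt, config):
            return False
        cur = cur + (nxt,)
    return True


def enumerate_paths_exhaustive(
    graph: KnowledgeGraph, cs: str, ct: str, config: SearchConfig
) -> set[tuple[str, ...]]:
    """Depth-first enumeration of every simple path of length <= m under the
    same hub/synonym/label exclusions — no stochastic skipping, no time
    budget.  Reference enumeration for small graphs."""
    _require_in_graph(graph, cs, ct)
    found: set[tuple[str, ...]] = set()

    def dfs(path: tuple[str, ...]) -> None:
        last = path[-1]
        if len(path) >= 2 and last == ct:
            if not (config.exclude_direct and len(path) == 2):
                found.add(path)
            return  # ct is the terminus; paths do not pass through it
        if len(path) == config.max_length:
            return
        for nxt in sorted(graph.neighbors(last)):
            if nxt != ct and _is_hub(graph, nxt, config):
                continue
            if _valid_extension(graph, path, nxt, config):
                dfs(path + (nxt,))

    dfs((cs,))
    return found


def _require_in_graph(graph: KnowledgeGraph, cs: str, ct: str) -> None:
    if cs not in graph:
        raise ConceptNotInGraphError(f"concept not in graph: {cs}")
    if ct not in graph:
        raise ConceptNotInGraphError(f"concept not in graph: {ct}")
    if cs == ct:
        raise ValueError("source and target must differ")


def _grow_frontier(
    graph: KnowledgeGraph,
    root: str,
    other_root: str,
    depth: int,
    config: SearchConfig,
    rng: np.random.Generator,
    deadline: float,
) -> tuple[dict[str, list[tuple[str, ...]]], bool]:
    """All partial simple paths from ``root`` up to ``depth`` edges, keyed by
    terminal vertex.  The other query endpoint is only allowed as a
    terminus, never passed through."""
    by_end: dict[str, list[tuple[str, ...]]] = {root: [(root,)]}
    frontier: list[tuple[str, ...]] = [(root,)]
    truncated = False
    for _ in range(depth):
        nxt_frontier: list[tuple[str, ...]] = []
        for path in frontier:
            last = path[-1]
            if last == other_root:
                continue  # terminus only
            if time.monotonic() > deadline:
                return by_end, True
            expand_p = 1.0 if config.deterministic else p_explore(graph, last, config)
            for nbr in sorted(graph.neighbors(last)):
                if nbr != other_root and nbr != root and _is_hub(graph, nbr, config):
                    continue
                if not _valid_extension(graph, path, nbr, config):
                    continue
                if not config.deterministic and expand_p < 1.0 and rng.random() >= expand_p:
                    continue
                new_path = path + (nbr,)
                by_end.setdefault(nbr, []).append(new_path)
                nxt_frontier.append(new_path)
        frontier = nxt_frontier
    return by_end, truncated


def find_paths(
    graph: KnowledgeGraph, cs: str, ct: str, config: SearchConfig
) -> SearchResult:
    """Bidirectional discovery of paths from ``cs`` to ``ct`` up to length m.

    Frontier trees are grown from both endpoints to depth ``⌊(m+1)/2⌋`` and
    joined at common vertices; joins producing a repeated concept or an
    invalid full path are discarded.  With ``deterministic=True`` the result
    equals :func:`enumerate_paths_exhaustive`.
    """
    _require_in_graph(graph, cs, ct)
    rng = np.random.default_rng(config.rng_seed)
    deadline = time.monotonic() + config.time_budget
    half = (config.max_length + 1) // 2
    fwd, trunc_f = _grow_frontier(graph, cs, ct, half, config, rng, deadline)
    bwd, trunc_b = _grow_frontier(graph, ct, cs, half, config, rng, deadline)
    paths: set[tuple[str, ...]] = set()
    for meet, fwd_paths in fwd.items():
        if meet not in bwd:
            continue
        for fp in fwd_paths:
            for bp in bwd[meet]:
                # bp runs ct -> meet; reverse its tail to continue fp
                full = fp + tuple(reversed(bp[:-1]))
                if len(full) > config.max_length or full[-1] != ct:
                    continue
                if config.exclude_direct and len(full) == 2:
                    continue
                if full in paths:
                    continue
                if path_is_valid(graph, full, config):
                    paths.add(full)
    return SearchResult(paths=paths, truncated=trunc_f or trunc_b)
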