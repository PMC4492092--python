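"""Edge-labelled knowledge multigraph.

Concepts are vertices, relations are labelled edges.  Each triple
``(c_i, l, c_j)`` is stored in one canonical direction only; the inverse
triple ``(c_j, l^-1, c_i)`` is implied and materialised on demand during
queries and path traversal.  Edges are a multiset: the same triple may be
asserted many times (once per supporting sentence, for instance) and the
multiplicity is preserved because it carries evidence weight.

Two label kinds coexist in one graph: ``structured`` labels from curated
databases and ``dependency_path`` labels extracted from parsed text.  The
kind is part of label identity, so a structured relation can never collide
with a dependency path that happens to share its string.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: Structured relations treated as synonymy between concepts.  Concepts
#: connected by any of these are blocked from co-occurring on a search path.
DEFAULT_SYNONYM_RELATIONS = frozenset(
    {
        "same_as",
        "clinically_similar",
        "has_tradename",
        "has_alias",
        "gene_encodes_gene_product",
        "mapped_from",
        "SY",
        "RL",
    }
)

STRUCTURED = "structured"
DEPENDENCY_PATH = "dependency_path"
_INVERSE_PREFIX = "^"


class MalformedTripleError(ValueError):
    """Raised when an input record is missing a field or otherwise invalid."""


@dataclass(frozen=True)
class Concept:
    """A vertex: an opaque identifier (CUI-style) plus optional display name."""

    id: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("concept id must be non-empty")


@dataclass(frozen=True)
class Label:
    """A relation label: a structured relation or a canonical dependency path.

    ``inverse`` marks a label obtained by traversing a stored edge against
    its stored direction.  Inverses are never stored in the graph; they are
    produced by queries.
    """

    kind: str
    key: str
    inverse: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (STRUCTURED, DEPENDENCY_PATH):
            raise ValueError(f"unknown label kind: {self.kind!r}")
        if not self.key:
            raise ValueError("label key must be non-empty")

    def invert(self) -> "Label":
        return replace(self, inverse=not self.inverse)

    @property
    def full_key(self) -> str:
        """Serialized identity, e.g. ``structured:may_treat`` or
        ``^dependency_path:>nsubjpass:use|<pobj``."""
        prefix = _INVERSE_PREFIX if self.inverse else ""
        return f"{prefix}{self.kind}:{self.key}"

    @classmethod
    def from_full_key(cls, full_key: str) -> "Label":
        inverse = full_key.startswith(_INVERSE_PREFIX)
        if inverse:
            full_key = full_key[1:]
        kind, _, key = full_key.partition(":")
        return cls(kind=kind, key=key, inverse=inverse)


@dataclass(frozen=True)
class Triple:
    """One directed, labelled edge assertion: (source, label, target)."""

    source: str
    label: Label
    target: str

    def canonical(self) -> "Triple":
        """The stored form: inverse-marked triples are flipped back."""
        if self.label.inverse:
            return Triple(self.target, self.label.invert(), self.source)
        return self


class KnowledgeGraph:
    """Directed edge-labelled multigraph with occurrence bookkeeping.

    Internally ``_out[src][tgt]`` is a ``Counter`` over label full keys
    (canonical direction, never inverse-marked); ``_in`` is the reverse
    adjacency for O(1) undirected neighbourhood queries.
    """

    def __init__(self, synonym_relations: Iterable[str] | None = None) -> None:
        self._out: dict[str, dict[str, Counter]] = {}
        self._in: dict[str, set[str]] = {}
        self._names: dict[str, str] = {}
        self._concept_occurrence: Counter = Counter()
        self._explicit_occurrence: dict[str, int] = {}
        self._label_occurrence: Counter = Counter()
        self._degree: Counter = Counter()
        self._n_edges = 0
        self.synonym_relations = frozenset(
            DEFAULT_SYNONYM_RELATIONS if synonym_relations is None else synonym_relations
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def vertices(self) -> set[str]:
        return set(self._out)

    @property
    def n_vertices(self) -> int:
        return len(self._out)

    @property
    def n_edges(self) -> int:
        """Number of stored edge assertions, counting multiplicity."""
        return self._n_edges

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._out

    def name_of(self, concept_id: str) -> str | None:
        return self._names.get(concept_id)

    def degree(self, concept_id: str) -> int:
        """Total edge incidence (in + out), counting multiplicity."""
        return self._degree.get(concept_id, 0)

    def concept_occurrence(self, concept_id: str) -> int:
        """Corpus occurrence count if supplied, else total edge incidence."""
        if concept_id in self._explicit_occurrence:
            return self._explicit_occurrence[concept_id]
        return self._degree.get(concept_id, 0)

    def label_occurrence(self, label: Label) -> int:
        canonical = label.invert() if label.inverse else label
        return self._label_occurrence.get(canonical.full_key, 0)

    @property
    def label_occurrences(self) -> Mapping[str, int]:
        return dict(self._label_occurrence)

    def set_concept_occurrences(self, table: Mapping[str, int]) -> None:
        """Attach explicit corpus occurrence counts (annotation frequency)."""
        self._explicit_occurrence.update(table)

    # -- mutation ----------------------------------------------------------

    def _ensure_vertex(self, concept_id: str, name: str | None = None) -> None:
        if concept_id not in self._out:
            self._out[concept_id] = {}
            self._in[concept_id] = set()
        if name:
            self._names.setdefault(concept_id, name)

    def add_triple(self, triple: Triple, count: int = 1, name: str | None = None) -> None:
        if not isinstance(triple, Triple):
            raise MalformedTripleError(f"not a triple: {triple!r}")
        if not triple.source or not triple.target or triple.label is None:
            raise MalformedTripleError(f"triple with missing field: {triple!r}")
        if count < 1:
            raise MalformedTripleError(f"non-positive multiplicity: {count}")
        canon = triple.canonical()
        if canon.source == canon.target:
            logger.warning("dropping self-loop on %s (label %s)", canon.source, canon.label.key)
            return
        self._ensure_vertex(canon.source, name)
        self._ensure_vertex(canon.target)
        bucket = self._out[canon.source].setdefault(canon.target, Counter())
        bucket[canon.label.full_key] += count
        self._in[canon.target].add(canon.source)
        self._label_occurrence[canon.label.full_key] += count
        self._degree[canon.source] += count
        self._degree[canon.target] += count
        self._n_edges += count

    def add_triples(self, triples: Iterable[Triple]) -> list[str]:
        """Insert triples; returns a report of rejected records (empty if all ok)."""
        rejected: list[str] = []
        for t in triples:
            try:
                self.add_triple(t)
            except MalformedTripleError as exc:
                rejected.append(str(exc))
        return rejected

    # -- queries -----------------------------------------------------------

    def edges_between(self, ci: str, cj: str, directed: bool = False) -> Counter:
        """Multiset of labels between ``ci`` and ``cj``.

        Undirected (the default, used for features): stored ``ci -> cj``
        labels plus inverse-marked labels for each stored ``cj -> ci`` edge.
        Unknown concepts yield an empty multiset.
        """
        out = Counter()
        fwd = self._out.get(ci, {}).get(cj)
        if fwd:
            out.update(fwd)
        if not directed:
            rev = self._out.get(cj, {}).get(ci)
            if rev:
                for full_key, n in rev.items():
                    out[_INVERSE_PREFIX + full_key] += n
        return out

    def edge_labels_between(self, ci: str, cj: str, directed: bool = False) -> list[Label]:
        """Like :meth:`edges_between` but materialised as Label objects
        (one entry per multiplicity unit)."""
        labels: list[Label] = []
        for full_key, n in self.edges_between(ci, cj, directed=directed).items():
            labels.extend([Label.from_full_key(full_key)] * n)
        return labels

    def neighbors(self, c: str) -> set[str]:
        """Undirected neighbourhood: sources and targets of incident edges."""
        nbrs = set(self._out.get(c, {})) | self._in.get(c, set())
        nbrs.discard(c)
        return nbrs

    def synonyms(self, c: str) -> set[str]:
        """Concepts connected to ``c`` by a synonym relation, either direction."""
        syns: set[str] = set()
        for nbr in self.neighbors(c):
            for full_key in self.edges_between(c, nbr):
                label = Label.from_full_key(full_key)
                if label.kind == STRUCTURED and label.key in self.synonym_relations:
                    syns.add(nbr)
                    break
        return syns

    def iter_triples(self) -> Iterator[tuple[str, Label, str, int]]:
        """Yield (source, label, target, multiplicity) in stored direction."""
        for src in sorted(self._out):
            for tgt in sorted(self._out[src]):
                for full_key in sorted(self._out[src][tgt]):
                    yield src, Label.from_full_key(full_key), tgt, self._out[src][tgt][full_key]

    def connected_pairs(self) -> Iterator[tuple[str, str]]:
        """Unordered connected pairs, oriented by sorted concept id."""
        seen: set[tuple[str, str]] = set()
        for src in self._out:
            for tgt in self._out[src]:
                pair = (src, tgt) if src <= tgt else (tgt, src)
                if pair not in seen:
                    seen.add(pair)
                    yield pair

    # -- pruning -----------------------------------------------------------

    def prune(self, min_concept_occurrence: int = 40, min_label_occurrence: int = 50) -> "KnowledgeGraph":
        """Remove rare concepts and rare dependency-path labels.

        Vertices whose total occurrence falls below ``min_concept_occurrence``
        are dropped with all incident edges.  Dependency-path edges whose
        label occurs fewer than ``min_label_occurrence`` times in total are
        dropped; structured edges are exempt from the label threshold (only
        the text-derived part of the graph is pruned on label frequency).
        Returns a new graph with recomputed counters.
        """
        if min_concept_occurrence < 1 or min_label_occurrence < 1:
            raise ValueError("pruning thresholds must be >= 1")
        keep_vertex = {
            c for c in self._out if self.concept_occurrence(c) >= min_concept_occurrence
        }
        pruned = KnowledgeGraph(synonym_relations=self.synonym_relations)
        for src, label, tgt, count in self.iter_triples():
            if src not in keep_vertex or tgt not in keep_vertex:
                continue
            if (
                label.kind == DEPENDENCY_PATH
                and self._label_occurrence[label.full_key] < min_label_occurrence
            ):
                continue
            pruned.add_triple(Triple(src, label, tgt), count=count, name=self._names.get(src))
        # occurrence is a corpus property, not a topological one: carry the
        # pre-prune values over so pruning is idempotent
        for c in keep_vertex:
            if c in pruned:
                pruned._explicit_occurrence[c] = self.concept_occurrence(c)
        for c, name in self._names.items():
            if c in pruned:
                pruned._names.setdefault(c, name)
        return pruned

    # -- serialization -----------------------------------------------------

    def save_edges(self, path: str) -> None:
        """Write the edge list: TSV with columns
        source_id, label_kind, label_key, target_id, count."""
        with open(path, "w", encoding="utf-8") as fh:
            for src, label, tgt, count in self.iter_triples():
                fh.write(f"{src}\t{label.kind}\t{label.key}\t{tgt}\t{count}\n")

    def save_occurrences(self, path: str) -> None:
        """Write the concept occurrence table: TSV concept_id, count."""
        with open(path, "w", encoding="utf-8") as fh:
            for c in sorted(self._out):
                fh.write(f"{c}\t{self.concept_occurrence(c)}\n")

    @classmethod
    def load_edges(
        cls,
        path: str,
        occurrence_path: str | None = None,
        synonym_relations: Iterable[str] | None = None,
    ) -> "KnowledgeGraph":
        graph = cls(synonym_relations=synonym_relations)
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 5:
                    raise MalformedTripleError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
                src, kind, key, tgt, count = parts
                graph.add_triple(Triple(src, Label(kind, key), tgt), count=int(count))
        if occurrence_path:
            graph.set_concept_occurrences(load_occurrence_table(occurrence_path))
        return graph


def load_occurrence_table(path: str) -> dict[str, int]:
    table: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            concept_id, count = line.split("\t")
            table[concept_id] = int(count)
    return table


def load_pair_file(path: str) -> list[tuple[str, str, int | None]]:
    """Read a pair file: TSV source_id, target_id[, label(1/0)]."""
    pairs: list[tuple[str, str, int | None]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            label = int(parts[2]) if len(parts) > 2 else None
            pairs.append((parts[0], parts[1], label))
    return pairs
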