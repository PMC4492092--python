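"""Dependency-path triple extraction from parsed, concept-annotated sentences.

A sentence arrives as a dependency tree (CoNLL-U) plus stand-off concept
annotations (JSON Lines mapping token spans to concept ids and semantic
types).  For every admissible annotated concept pair, the unique tree path
between their headwords becomes a relation label, and the triple
``(concept_i, path, concept_j)`` feeds the knowledge graph.

Admissibility rules:

* the path must contain at least one verb form — verbless paths are taken
  to express no relation;
* paths whose verbs sit in two distinct conjunct sub-sentences (two verb
  forms separated by a ``conj`` edge on the path) are discarded;
* after post-processing the path may span at most ``max_path_len``
  dependency edges (default 6) — longer paths are unspecific, rare, and
  error-prone.

Post-processing removes ``conj``/``appos`` steps together with their head
words (they are usually mere enumeration), and marks the whole path negated
when any remaining path node or endpoint headword carries a negation
dependent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Sequence

from .kg import DEPENDENCY_PATH, Label, Triple

logger = logging.getLogger(__name__)

TOWARD_ROOT = ">"
AWAY_FROM_ROOT = "<"

#: Penn Treebank verb tags; what counts as a "verb form" on a path.
DEFAULT_VERB_TAGS = frozenset({"VB", "VBD", "VBG", "VBN", "VBP", "VBZ"})
#: Dependency relations removed (with their head words) in post-processing.
REMOVABLE_DEPRELS = frozenset({"conj", "appos"})
#: Explicit negation cues in addition to the ``neg`` dependency relation.
DEFAULT_NEGATION_CUES = frozenset({"not", "no", "never"})
NEGATION_PREFIX = "neg_"

#: UMLS semantic types admitted for annotation filtering.
DEFAULT_SEMANTIC_TYPES = (
    "Organisms",
    "Clinical Drug",
    "Substances",
    "Sign or Symptom",
    "Anatomical Structure",
    "Molecular Sequence",
    "Body Space or Junction",
    "Body Location or Region",
    "Pathologic Function",
    "Injury or Poisening",
)

#: Semantic types treated as gene/protein, subject to the common-word stop list.
GENE_SEMANTIC_TYPES = frozenset({"Gene or Genome", "Molecular Sequence"})


class TreeError(ValueError):
    """Malformed dependency tree (cycle, no root, multiple roots)."""


@dataclass(frozen=True)
class ParsedToken:
    index: int  # 1-based
    form: str
    lemma: str
    pos: str
    head: int  # 0 = root
    deprel: str


@dataclass(frozen=True)
class ConceptAnnotation:
    sentence_id: str
    start: int  # 1-based inclusive token indices
    end: int
    concept_id: str
    semantic_type: str
    surface: str = ""


@dataclass(frozen=True)
class PathStep:
    """One dependency edge on a path, with the lemma of the node it arrives
    at (empty for endpoint tokens, which are the concepts themselves)."""

    direction: str  # TOWARD_ROOT or AWAY_FROM_ROOT
    deprel: str
    node_lemma: str


@dataclass(frozen=True)
class DependencyPath:
    steps: tuple[PathStep, ...]
    negated: bool = False
    # token indices of the nodes visited, endpoints included; used by the
    # admissibility and post-processing rules, not part of label identity
    nodes: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def key(self) -> str:
        """Canonical, byte-reproducible string form."""
        body = "|".join(
            f"{s.direction}{s.deprel}" + (f":{s.node_lemma}" if s.node_lemma else "")
            for s in self.steps
        )
        return (NEGATION_PREFIX if self.negated else "") + body

    def reversed(self, sentence: Sequence[ParsedToken]) -> "DependencyPath":
        """The same tree path traversed from the other endpoint."""
        rev_nodes = tuple(reversed(self.nodes))
        return _path_from_nodes(sentence, rev_nodes, negated=self.negated)


@dataclass
class ExtractionConfig:
    max_path_len: int = 6
    verb_tags: frozenset[str] = DEFAULT_VERB_TAGS
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES
    allowed_types: tuple[str, ...] = DEFAULT_SEMANTIC_TYPES
    gene_stoplist: frozenset[str] = field(default_factory=lambda: load_gene_stoplist())


def load_gene_stoplist(path: str | None = None) -> frozenset[str]:
    """Common English words wrongly annotated as genes (e.g. "impact",
    "rare", "an"); packaged default is editable."""
    if path is None:
        text = resources.files("kgpaths.data").joinpath("gene_stoplist.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(
        w.strip().lower() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


def load_semantic_types(path: str) -> tuple[str, ...]:
    with open(path, encoding="utf-8") as fh:
        return tuple(l.strip() for l in fh if l.strip() and not l.startswith("#"))


# -- CoNLL-U and annotation I/O ---------------------------------------------


def read_conllu(path_or_text: str, is_text: bool = False) -> Iterator[tuple[str, list[ParsedToken]]]:
    """Yield (sentence_id, tokens) from 10-column CoNLL-U.

    Sentence ids come from ``# sent_id = ...`` comment lines (fallback:
    running index).  Multiword-token and empty-node lines are skipped.
    """
    if is_text:
        text = path_or_text
    else:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    sent_id: str | None = None
    tokens: list[ParsedToken] = []
    counter = 0
    for raw in text.splitlines() + [""]:
        line = raw.rstrip()
        if not line:
            if tokens:
                counter += 1
                yield (sent_id or str(counter)), tokens
            sent_id, tokens = None, []
            continue
        if line.startswith("#"):
            if line[1:].strip().startswith("sent_id"):
                sent_id = line.split("=", 1)[1].strip()
            continue
        cols = line.split("\t")
        if len(cols) != 10 or "-" in cols[0] or "." in cols[0]:
            continue
        tokens.append(
            ParsedToken(
                index=int(cols[0]),
                form=cols[1],
                lemma=cols[2],
                pos=cols[4] if cols[4] != "_" else cols[3],
                head=int(cols[6]),
                deprel=cols[7],
            )
        )


def read_annotations(path_or_text: str, is_text: bool = False) -> list[ConceptAnnotation]:
    """Read stand-off annotations: JSON Lines with fields sentence_id,
    start, end, concept_id, semantic_type, optional surface."""
    if is_text:
        text = path_or_text
    else:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(
            ConceptAnnotation(
                sentence_id=str(rec["sentence_id"]),
                start=int(rec["start"]),
                end=int(rec["end"]),
                concept_id=rec["concept_id"],
                semantic_type=rec["semantic_type"],
                surface=rec.get("surface", ""),
            )
        )
    return out


# -- tree machinery ----------------------------------------------------------


def _check_tree(sentence: Sequence[ParsedToken]) -> dict[int, ParsedToken]:
    by_index = {t.index: t for t in sentence}
    roots = [t for t in sentence if t.head == 0]
    if len(roots) != 1:
        raise TreeError(f"expected exactly one root, found {len(roots)}")
    for t in sentence:
        seen = {t.index}
        cur = t
        while cur.head != 0:
            if cur.head not in by_index:
                raise TreeError(f"head {cur.head} of token {cur.index} missing")
            if cur.head in seen:
                raise TreeError(f"cycle through token {cur.index}")
            seen.add(cur.head)
            cur = by_index[cur.head]
    return by_index


def _ancestors(by_index: dict[int, ParsedToken], idx: int) -> list[int]:
    """Token index chain from ``idx`` to the root, inclusive."""
    chain = [idx]
    while by_index[chain[-1]].head != 0:
        chain.append(by_index[chain[-1]].head)
    return chain


def _path_from_nodes(
    sentence: Sequence[ParsedToken], nodes: tuple[int, ...], negated: bool = False
) -> DependencyPath:
    """Build the step list for a node sequence along tree edges."""
    by_index = {t.index: t for t in sentence}
    steps = []
    for a, b in zip(nodes, nodes[1:]):
        ta, tb = by_index[a], by_index[b]
        if ta.head == b:
            direction, deprel = TOWARD_ROOT, ta.deprel
        elif tb.head == a:
            direction, deprel = AWAY_FROM_ROOT, tb.deprel
        else:  # pragma: no cover - guarded by construction
            raise TreeError(f"tokens {a} and {b} not tree-adjacent")
        lemma = tb.lemma if b not in (nodes[0], nodes[-1]) else ""
        steps.append(PathStep(direction, deprel, lemma))
    return DependencyPath(steps=tuple(steps), negated=negated, nodes=nodes)


def dependency_path(
    sentence: Sequence[ParsedToken], head_i: int, head_j: int
) -> DependencyPath:
    """The unique tree path between two headword tokens.

    Directions are recorded relative to traversal from ``head_i`` to
    ``head_j``; endpoint lemmas are excluded (the endpoints are the concepts
    being related, not part of the pattern).
    """
    by_index = _check_tree(sentence)
    if head_i not in by_index or head_j not in by_index:
        raise TreeError(f"token index out of range: {head_i}, {head_j}")
    if head_i == head_j:
        return DependencyPath(steps=(), nodes=(head_i,))
    up_i = _ancestors(by_index, head_i)
    up_j = _ancestors(by_index, head_j)
    in_j = set(up_j)
    lca = next(n for n in up_i if n in in_j)
    part_i = up_i[: up_i.index(lca) + 1]
    part_j = up_j[: up_j.index(lca)]
    nodes = tuple(part_i + list(reversed(part_j)))
    return _path_from_nodes(sentence, nodes)


# -- admissibility and post-processing ---------------------------------------


def _is_verb(token: ParsedToken, config: ExtractionConfig) -> bool:
    return token.pos in config.verb_tags


def _has_negation_dependent(
    sentence: Sequence[ParsedToken], idx: int, config: ExtractionConfig
) -> bool:
    for t in sentence:
        if t.head == idx and (t.deprel == "neg" or t.lemma.lower() in config.negation_cues):
            return True
    return False


def postprocess(
    path: DependencyPath, sentence: Sequence[ParsedToken], config: ExtractionConfig | None = None
) -> DependencyPath:
    """Remove conj/appos steps with their head words; detect negation.

    The head word of a removed edge is the node closer to the root; when it
    is an intermediate path node it is spliced out and the adjacent step
    re-attaches to the surviving node.  Negation, once set, is never unset.
    """
    config = config or ExtractionConfig()
    by_index = {t.index: t for t in sentence}
    nodes = list(path.nodes)
    steps = list(path.steps)
    changed = True
    while changed:
        changed = False
        for i, step in enumerate(steps):
            if step.deprel not in REMOVABLE_DEPRELS:
                continue
            # the head word of the removed edge is the node nearer the root
            parent_pos = i + 1 if step.direction == TOWARD_ROOT else i
            if parent_pos in (0, len(nodes) - 1):
                continue  # endpoints are the concepts; never removed
            if parent_pos == i + 1:
                # splice out the right node; the following step re-attaches
                del nodes[i + 1]
                del steps[i]
            else:
                # splice out the left node; the preceding step re-attaches
                # and now arrives at the node across the removed edge
                arrival = nodes[i + 1]
                lemma = by_index[arrival].lemma if i + 1 < len(nodes) - 1 else ""
                steps[i - 1] = replace(steps[i - 1], node_lemma=lemma)
                del nodes[i]
                del steps[i]
            changed = True
            break
    negated = path.negated
    for idx in nodes:
        if _has_negation_dependent(sentence, idx, config):
            negated = True
    return DependencyPath(steps=tuple(steps), negated=negated, nodes=tuple(nodes))


def _conjoined_verbs(
    path: DependencyPath, sentence: Sequence[ParsedToken], config: ExtractionConfig
) -> bool:
    """True when two verb forms on the path sit in distinct conjunct
    sub-sentences, i.e. are separated on the path by a conj edge joining two
    verbs."""
    by_index = {t.index: t for t in sentence}
    for step, (a, b) in zip(path.steps, zip(path.nodes, path.nodes[1:])):
        if step.deprel == "conj" and _is_verb(by_index[a], config) and _is_verb(by_index[b], config):
            return True
    return False


def admissible(
    path: DependencyPath,
    sentence: Sequence[ParsedToken],
    config: ExtractionConfig | None = None,
) -> bool:
    """Apply the three extraction rules to a raw path (see module docstring).

    The length cap applies AFTER conj/appos removal: a raw length-7 path
    that shrinks to 6 is admissible.
    """
    config = config or ExtractionConfig()
    if not path.steps:
        return False
    by_index = {t.index: t for t in sentence}
    # the verb requirement is checked on the raw path: a verb that is later
    # spliced out as a conjunction head still licensed the relation
    if not any(_is_verb(by_index[i], config) for i in path.nodes[1:-1]):
        return False
    if _conjoined_verbs(path, sentence, config):
        return False
    processed = postprocess(path, sentence, config)
    return len(processed.steps) <= config.max_path_len


# -- annotation handling ------------------------------------------------------


def headword(annotation: ConceptAnnotation, sentence: Sequence[ParsedToken]) -> int:
    """Token of the span whose governor lies outside the span; ties and
    fully-internal spans resolve to the rightmost candidate."""
    span = range(annotation.start, annotation.end + 1)
    span_set = set(span)
    candidates = [
        t.index for t in sentence if t.index in span_set and t.head not in span_set
    ]
    if not candidates:
        return annotation.end
    return max(candidates)


def semantic_type_admissible(
    annotation: ConceptAnnotation, config: ExtractionConfig | None = None
) -> bool:
    """Type filter plus the common-word gene stop list."""
    config = config or ExtractionConfig()
    if annotation.semantic_type not in config.allowed_types:
        return False
    if annotation.semantic_type in GENE_SEMANTIC_TYPES:
        if annotation.surface.lower() in config.gene_stoplist:
            return False
    return True


def extract_triples(
    sentence: Sequence[ParsedToken],
    annotations: Sequence[ConceptAnnotation],
    config: ExtractionConfig | None = None,
) -> list[Triple]:
    """Extract dependency-path triples for one sentence.

    One triple per admissible unordered annotation pair with distinct
    concept ids; the stored direction runs from the annotation appearing
    earlier in the sentence.  Negation is encoded in the label key.
    """
    config = config or ExtractionConfig()
    n = len(sentence)
    valid = []
    for ann in annotations:
        if ann.start < 1 or ann.end > n or ann.start > ann.end:
            logger.warning("annotation span %s outside sentence; skipped", ann)
            continue
        if semantic_type_admissible(ann, config):
            valid.append(ann)
    valid.sort(key=lambda a: (a.start, a.end))
    triples: list[Triple] = []
    for i in range(len(valid)):
        for j in range(i + 1, len(valid)):
            ai, aj = valid[i], valid[j]
            if ai.concept_id == aj.concept_id:
                continue
            if ai.end >= aj.start:  # overlapping spans: degenerate path
                continue
            hi, hj = headword(ai, sentence), headword(aj, sentence)
            if hi == hj:
                continue
            raw = dependency_path(sentence, hi, hj)
            if not admissible(raw, sentence, config):
                continue
            processed = postprocess(raw, sentence, config)
            label = Label(kind=DEPENDENCY_PATH, key=processed.key)
            triples.append(Triple(ai.concept_id, label, aj.concept_id))
    return triples


def extract_corpus(
    conllu_path: str,
    annotations_path: str,
    config: ExtractionConfig | None = None,
) -> list[Triple]:
    """Run extraction over a CoNLL-U file plus its annotation file."""
    config = config or ExtractionConfig()
    anns_by_sentence: dict[str, list[ConceptAnnotation]] = {}
    for ann in read_annotations(annotations_path):
        anns_by_sentence.setdefault(ann.sentence_id, []).append(ann)
    triples: list[Triple] = []
    for sent_id, tokens in read_conllu(conllu_path):
        anns = anns_by_sentence.get(sent_id, [])
        if len(anns) < 2:
            continue
        try:
            triples.extend(extract_triples(tokens, anns, config))
        except TreeError as exc:
            logger.warning("sentence %s skipped: %s", sent_id, exc)
    return triples
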