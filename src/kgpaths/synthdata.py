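"""Synthetic knowledge graphs, relation datasets and parsed-sentence fixtures.

Real inputs for this method are licensed at scale (a MetaMapped abstract
corpus, UMLS, DrugBank), so every module is exercised against generated data
with known ground truth.  The generator emulates the statistical structure
that matters to the method:

* a multigraph whose vertex degrees and label frequencies are heavy-tailed
  (most concepts and labels are rare; a few dominate);
* redundant surface labels: every edge label is one of several surface
  realisations of a smaller set of latent relations — the regime in which a
  topic-model encoding should beat one-of-N on sparse training data;
* positive pairs of a query relation connected by planted characteristic
  label sequences (paths of length 2-4 over designated latent relations)
  amid noise paths that connect positives and negatives alike;
* hubs, synonym groups, and structured query-relation edges, so that hub
  exclusion, synonym blocking and label exclusion all have work to do.

Sentence fixtures are template dependency trees covering every extraction
rule (verb requirement, conjunct sub-sentences, conj/appos removal,
negation, the length cap at 6, multi-token spans, the gene stop list),
including a worked drug/disease example whose two expected triples are
fixed by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .kg import DEPENDENCY_PATH, STRUCTURED, KnowledgeGraph, Label, Triple
from .training_eval import RelationDataset, sample_negatives

QUERY_RELATION = "q_rel"
DIRECT_LATENT = -1  # latent id reserved for direct-connection surface labels


@dataclass
class SyntheticSpec:
    n_concepts: int = 2000
    n_latent_relations: int = 20
    surface_per_latent: int = 5
    #: characteristic latent-relation sequences for the query relation;
    #: a sequence of k latents plants paths of k+1 concepts
    planted_patterns: tuple[tuple[int, ...], ...] = ((0, 1),)
    n_positive_pairs: int = 300
    pattern_instantiation_prob: float = 1.0
    #: copies of each planted hop, each with a fresh surface label draw
    planted_edge_multiplicity: int = 1
    noise_edge_count: int = 6000
    #: edges per background relation instance (same latent, several
    #: surfaces between one pair) — the co-occurrence a topic model learns from
    noise_instance_edges: tuple[int, int] = (2, 4)
    #: random connecting paths added per dataset pair (positive and negative)
    noise_paths_per_pair: int = 2
    degree_exponent: float = 2.0  # power-law exponent of the degree weights
    label_zipf_exponent: float = 1.5  # heavy tail of latent usage
    hub_count: int = 2
    hub_degree: int = 400
    n_synonym_groups: int = 10
    direct_edge_prob: float = 0.0  # fraction of positives given a direct edge
    add_query_edges: bool = True  # store the query relation for positives
    max_search_length: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.planted_patterns:
            if len(p) + 1 > self.max_search_length:
                raise ValueError(f"pattern {p} longer than max search length allows")
            if any(l >= self.n_latent_relations or l < 0 for l in p):
                raise ValueError(f"pattern {p} references an unknown latent relation")
        if not (
            self.n_concepts > 0
            and self.n_latent_relations > 0
            and self.surface_per_latent > 0
            and self.n_positive_pairs > 0
        ):
            raise ValueError("all counts must be positive")


@dataclass
class GroundTruth:
    surface_to_latent: dict[str, int]
    planted: dict[tuple[str, str], list[tuple[str, ...]]]
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    direct_positives: set[tuple[str, str]] = field(default_factory=set)
    pattern_latents: tuple[tuple[int, ...], ...] = ()

    def latent_sequence(self, label_keys: tuple[str, ...]) -> tuple[int, ...] | None:
        """Map a decoded label-key sequence to latent ids (None if any label
        is unknown); inverse markers are ignored for the latent lookup."""
        out = []
        for full_key in label_keys:
            key = Label.from_full_key(full_key).key
            if key not in self.surface_to_latent:
                return None
            out.append(self.surface_to_latent[key])
        return tuple(out)

    def matches_planted(self, label_keys: tuple[str, ...]) -> bool:
        seq = self.latent_sequence(label_keys)
        return seq is not None and (
            seq in self.pattern_latents or tuple(reversed(seq)) in self.pattern_latents
        )


def _concept_id(i: int) -> str:
    return f"C{i:07d}"


def _surface_key(latent: int, j: int) -> str:
    if latent == DIRECT_LATENT:
        return f"dp_direct_s{j}"
    return f"dp_l{latent}_s{j}"


def generate_graph(
    spec: SyntheticSpec,
) -> tuple[KnowledgeGraph, RelationDataset, GroundTruth]:
    """Build a seeded synthetic graph, dataset and ground truth.

    Deterministic: the same spec (including its seed) yields byte-identical
    serialized outputs.
    """
    rng = np.random.default_rng(spec.seed)
    graph = KnowledgeGraph()
    concepts = [_concept_id(i) for i in range(spec.n_concepts)]

    surface_to_latent: dict[str, int] = {}
    latent_surfaces: dict[int, list[str]] = {}
    for latent in list(range(spec.n_latent_relations)) + [DIRECT_LATENT]:
        latent_surfaces[latent] = [
            _surface_key(latent, j) for j in range(spec.surface_per_latent)
        ]
        for key in latent_surfaces[latent]:
            surface_to_latent[key] = latent

    def dep_label(latent: int) -> Label:
        key = latent_surfaces[latent][int(rng.integers(spec.surface_per_latent))]
        return Label(DEPENDENCY_PATH, key)

    # -- dataset pairs -----------------------------------------------------
    # positives use the first third of the concept range as sources and the
    # second third as targets; intermediates come from the final third, so
    # planted paths never collide with dataset endpoints
    n_third = spec.n_concepts // 3
    sources = concepts[:n_third]
    targets = concepts[n_third : 2 * n_third]
    intermediates = concepts[2 * n_third :]
    src_pick = rng.choice(len(sources), size=spec.n_positive_pairs, replace=False)
    tgt_pick = rng.choice(len(targets), size=spec.n_positive_pairs, replace=False)
    positives = [(sources[i], targets[j]) for i, j in zip(src_pick, tgt_pick)]
    negatives = sample_negatives(positives, positives, seed=spec.seed + 1)

    # -- planted characteristic paths --------------------------------------
    planted: dict[tuple[str, str], list[tuple[str, ...]]] = {}
    direct_positives: set[tuple[str, str]] = set()
    for s, t in positives:
        if spec.add_query_edges:
            graph.add_triple(Triple(s, Label(STRUCTURED, QUERY_RELATION), t))
        if rng.random() < spec.direct_edge_prob:
            direct_positives.add((s, t))
            for _ in range(spec.planted_edge_multiplicity):
                graph.add_triple(Triple(s, dep_label(DIRECT_LATENT), t))
        if rng.random() >= spec.pattern_instantiation_prob:
            continue
        pattern = spec.planted_patterns[int(rng.integers(len(spec.planted_patterns)))]
        mids = [
            intermediates[int(i)]
            for i in rng.choice(len(intermediates), size=len(pattern) - 1, replace=False)
        ]
        nodes = [s] + mids + [t]
        for (a, b), latent in zip(zip(nodes, nodes[1:]), pattern):
            for _ in range(spec.planted_edge_multiplicity):
                graph.add_triple(Triple(a, dep_label(latent), b))
        planted.setdefault((s, t), []).append(tuple(nodes))

    # -- noise paths connecting every dataset pair --------------------------
    # drawn from latents NOT used by the planted patterns: the patterns are
    # characteristic of the query relation by construction, so ambient paths
    # between pairs must not reproduce them by accident
    latent_weights = 1.0 / np.arange(1, spec.n_latent_relations + 1) ** spec.label_zipf_exponent
    latent_weights /= latent_weights.sum()
    pattern_latents = {l for p in spec.planted_patterns for l in p}
    ambient = [l for l in range(spec.n_latent_relations) if l not in pattern_latents]
    ambient = ambient or list(range(spec.n_latent_relations))
    ambient_weights = latent_weights[: len(ambient)] / latent_weights[: len(ambient)].sum()

    def noise_latent(pool: list[int] | None = None, weights: np.ndarray | None = None) -> int:
        if pool is None:
            return int(rng.choice(spec.n_latent_relations, p=latent_weights))
        return int(pool[int(rng.choice(len(pool), p=weights))])

    for s, t in positives + negatives:
        for _ in range(spec.noise_paths_per_pair):
            n_mid = int(rng.integers(1, spec.max_search_length - 1))
            mids = [
                intermediates[int(i)]
                for i in rng.choice(len(intermediates), size=n_mid, replace=False)
            ]
            nodes = [s] + mids + [t]
            for a, b in zip(nodes, nodes[1:]):
                graph.add_triple(Triple(a, dep_label(noise_latent(ambient, ambient_weights)), b))

    # -- background noise with heavy-tailed degree ---------------------------
    # emitted as relation instances: a pair of concepts asserted to stand in
    # one latent relation by several surface labels at once, which is where
    # the redundancy of surface labels is observable
    vertex_weights = 1.0 / np.arange(1, spec.n_concepts + 1) ** spec.degree_exponent
    vertex_weights /= vertex_weights.sum()
    perm = rng.permutation(spec.n_concepts)  # decouple weight rank from id
    lo, hi = spec.noise_instance_edges
    edges_left = spec.noise_edge_count
    while edges_left > 0:
        a_i, b_i = rng.choice(spec.n_concepts, size=2, p=vertex_weights)
        a, b = concepts[perm[a_i]], concepts[perm[b_i]]
        if a == b:
            continue
        latent = noise_latent()
        k = min(int(rng.integers(lo, hi + 1)), edges_left)
        for _ in range(k):
            graph.add_triple(Triple(a, dep_label(latent), b))
        edges_left -= k

    # every declared concept takes part in at least one edge so the emitted
    # graph has exactly n_concepts vertices
    for i, c in enumerate(concepts):
        if c not in graph:
            other = concepts[(i + 1 + int(rng.integers(spec.n_concepts - 1))) % spec.n_concepts]
            graph.add_triple(Triple(c, dep_label(noise_latent()), other))

    # -- hubs ----------------------------------------------------------------
    hub_ids = [intermediates[-(i + 1)] for i in range(spec.hub_count)]
    for hub in hub_ids:
        others = rng.choice(spec.n_concepts, size=spec.hub_degree, replace=True)
        for o in others:
            other = concepts[int(o)]
            if other != hub:
                graph.add_triple(Triple(hub, dep_label(noise_latent()), other))

    # -- synonym groups -------------------------------------------------------
    for g in range(spec.n_synonym_groups):
        pick = rng.choice(len(intermediates) - spec.hub_count, size=2, replace=False)
        a, b = intermediates[int(pick[0])], intermediates[int(pick[1])]
        if a != b:
            graph.add_triple(Triple(a, Label(STRUCTURED, "same_as"), b))

    dataset = RelationDataset(
        relation=QUERY_RELATION,
        positives=positives,
        negatives=negatives,
        provenance=f"synthetic(seed={spec.seed})",
    )
    truth = GroundTruth(
        surface_to_latent=surface_to_latent,
        planted=planted,
        positives=positives,
        negatives=negatives,
        direct_positives=direct_positives,
        pattern_latents=tuple(spec.planted_patterns),
    )
    return graph, dataset, truth


def save_dataset(dataset: RelationDataset, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s, t in dataset.positives:
            fh.write(f"{s}\t{t}\t1\n")
        for s, t in dataset.negatives:
            fh.write(f"{s}\t{t}\t0\n")


# ---------------------------------------------------------------------------
# parsed-sentence fixtures
# ---------------------------------------------------------------------------

# Each template: (sentence_id, token rows, annotations, gold triples).
# Token row: (index, form, lemma, pos, head, deprel).
# Annotation: (start, end, concept_id, semantic_type, surface).
# Gold triple: (source_cid, canonical path key, target_cid).

_TEMPLATES: list[dict] = [
    {
        # the worked drug/disease example: passive verb chain, one pair
        # reached through a conjunction (removed, negated), one verbless pair
        "id": "s-worked-example",
        "tokens": [
            (1, "Aspirin", "aspirin", "NN", 3, "nsubjpass"),
            (2, "is", "be", "VBZ", 3, "auxpass"),
            (3, "used", "use", "VBN", 0, "root"),
            (4, "in", "in", "IN", 3, "prep"),
            (5, "the", "the", "DT", 6, "det"),
            (6, "treatment", "treatment", "NN", 4, "pobj"),
            (7, "of", "of", "IN", 6, "prep"),
            (8, "inflammation", "inflammation", "NN", 7, "pobj"),
            (9, "and", "and", "CC", 8, "cc"),
            (10, "not", "not", "RB", 12, "neg"),
            (11, "nasal", "nasal", "JJ", 12, "amod"),
            (12, "polyps", "polyp", "NNS", 8, "conj"),
        ],
        "annotations": [
            (1, 1, "C0004057", "Substances", "Aspirin"),
            (8, 8, "C0021368", "Pathologic Function", "inflammation"),
            (11, 12, "C0027430", "Pathologic Function", "nasal polyps"),
        ],
        "gold": [
            ("C0004057", ">nsubjpass:use|<prep:in|<pobj:treatment|<prep:of|<pobj", "C0021368"),
            (
                "C0004057",
                "neg_>nsubjpass:use|<prep:in|<pobj:treatment|<prep:of|<pobj",
                "C0027430",
            ),
        ],
    },
    {
        # verbless path: no relation asserted
        "id": "s-verbless",
        "tokens": [
            (1, "Aspirin", "aspirin", "NN", 2, "nn"),
            (2, "therapy", "therapy", "NN", 0, "root"),
            (3, "for", "for", "IN", 2, "prep"),
            (4, "arthritis", "arthritis", "NN", 3, "pobj"),
        ],
        "annotations": [
            (1, 1, "C0004057", "Substances", "Aspirin"),
            (4, 4, "C0003864", "Pathologic Function", "arthritis"),
        ],
        "gold": [],
    },
    {
        # apposition removed with its head word
        "id": "s-appos",
        "tokens": [
            (1, "Ibuprofen", "ibuprofen", "NN", 6, "nsubj"),
            (2, ",", ",", ",", 1, "punct"),
            (3, "a", "a", "DT", 4, "det"),
            (4, "painkiller", "painkiller", "NN", 1, "appos"),
            (5, ",", ",", ",", 1, "punct"),
            (6, "reduces", "reduce", "VBZ", 0, "root"),
            (7, "fever", "fever", "NN", 6, "dobj"),
        ],
        "annotations": [
            (1, 1, "C0020740", "Substances", "Ibuprofen"),
            (4, 4, "C0002771", "Substances", "painkiller"),
            (7, 7, "C0015967", "Sign or Symptom", "fever"),
        ],
        "gold": [
            ("C0020740", ">nsubj:reduce|<dobj", "C0015967"),
            ("C0002771", ">nsubj:reduce|<dobj", "C0015967"),
        ],
    },
    {
        # negation cue on the path verb
        "id": "s-negation",
        "tokens": [
            (1, "Aspirin", "aspirin", "NN", 4, "nsubj"),
            (2, "does", "do", "VBZ", 4, "aux"),
            (3, "not", "not", "RB", 4, "neg"),
            (4, "prevent", "prevent", "VB", 0, "root"),
            (5, "migraine", "migraine", "NN", 4, "dobj"),
        ],
        "annotations": [
            (1, 1, "C0004057", "Substances", "Aspirin"),
            (5, 5, "C0149931", "Pathologic Function", "migraine"),
        ],
        "gold": [("C0004057", "neg_>nsubj:prevent|<dobj", "C0149931")],
    },
    {
        # length boundary: 6 dependency edges pass, 7 are rejected
        "id": "s-length-cap",
        "tokens": [
            (1, "Aspirin", "aspirin", "NN", 3, "nsubjpass"),
            (2, "is", "be", "VBZ", 3, "auxpass"),
            (3, "thought", "think", "VBN", 0, "root"),
            (4, "to", "to", "TO", 6, "aux"),
            (5, "be", "be", "VB", 6, "auxpass"),
            (6, "used", "use", "VBN", 3, "xcomp"),
            (7, "in", "in", "IN", 6, "prep"),
            (8, "treatment", "treatment", "NN", 7, "pobj"),
            (9, "of", "of", "IN", 8, "prep"),
            (10, "knee", "knee", "NN", 11, "nn"),
            (11, "arthritis", "arthritis", "NN", 9, "pobj"),
        ],
        "annotations": [
            (1, 1, "C0004057", "Substances", "Aspirin"),
            (10, 10, "C1456798", "Anatomical Structure", "knee"),
            (11, 11, "C0003864", "Pathologic Function", "arthritis"),
        ],
        "gold": [
            (
                "C0004057",
                ">nsubjpass:think|<xcomp:use|<prep:in|<pobj:treatment|<prep:of|<pobj",
                "C0003864",
            )
        ],
    },
    {
        # gene alias that is a common word: stop-listed
        "id": "s-gene-stoplist",
        "tokens": [
            (1, "Impact", "impact", "NN", 2, "nsubj"),
            (2, "interacts", "interact", "VBZ", 0, "root"),
            (3, "with", "with", "IN", 2, "prep"),
            (4, "aspirin", "aspirin", "NN", 3, "pobj"),
        ],
        "annotations": [
            (1, 1, "C1416779", "Molecular Sequence", "Impact"),
            (4, 4, "C0004057", "Substances", "aspirin"),
        ],
        "gold": [],
    },
    {
        # two verbs in distinct conjunct sub-sentences: rejected; the pair
        # inside the first clause is kept
        "id": "s-conjoined-verbs",
        "tokens": [
            (1, "Aspirin", "aspirin", "NN", 2, "nsubj"),
            (2, "reduces", "reduce", "VBZ", 0, "root"),
            (3, "fever", "fever", "NN", 2, "dobj"),
            (4, "and", "and", "CC", 2, "cc"),
            (5, "prevents", "prevent", "VBZ", 2, "conj"),
            (6, "inflammation", "inflammation", "NN", 5, "dobj"),
        ],
        "annotations": [
            (1, 1, "C0004057", "Substances", "Aspirin"),
            (3, 3, "C0015967", "Sign or Symptom", "fever"),
            (6, 6, "C0021368", "Pathologic Function", "inflammation"),
        ],
        "gold": [("C0004057", ">nsubj:reduce|<dobj", "C0015967")],
    },
    {
        # disallowed semantic type: annotation filtered out
        "id": "s-bad-type",
        "tokens": [
            (1, "Aspirin", "aspirin", "NN", 2, "nsubj"),
            (2, "supports", "support", "VBZ", 0, "root"),
            (3, "homeostasis", "homeostasis", "NN", 2, "dobj"),
        ],
        "annotations": [
            (1, 1, "C0004057", "Substances", "Aspirin"),
            (3, 3, "C0019868", "Physiologic Function", "homeostasis"),
        ],
        "gold": [],
    },
]

WORKED_EXAMPLE_ID = "s-worked-example"


def generate_parsed_fixtures(
    seed: int = 0, n_sentences: int | None = None
) -> tuple[str, str, list[Triple]]:
    """Render the fixture corpus: (CoNLL-U text, JSON Lines annotations,
    gold triples).  The seed permutes sentence order; content is fixed."""
    templates = _TEMPLATES[: n_sentences if n_sentences is not None else len(_TEMPLATES)]
    order = np.random.default_rng(seed).permutation(len(templates))
    conllu_lines: list[str] = []
    ann_lines: list[str] = []
    gold: list[Triple] = []
    for idx in order:
        tpl = templates[int(idx)]
        conllu_lines.append(f"# sent_id = {tpl['id']}")
        for i, form, lemma, pos, head, deprel in tpl["tokens"]:
            conllu_lines.append(
                f"{i}\t{form}\t{lemma}\t_\t{pos}\t_\t{head}\t{deprel}\t_\t_"
            )
        conllu_lines.append("")
        for start, end, cid, stype, surface in tpl["annotations"]:
            ann_lines.append(
                json.dumps(
                    {
                        "sentence_id": tpl["id"],
                        "start": start,
                        "end": end,
                        "concept_id": cid,
                        "semantic_type": stype,
                        "surface": surface,
                    }
                )
            )
        for src, key, tgt in tpl["gold"]:
            gold.append(Triple(src, Label(DEPENDENCY_PATH, key), tgt))
    return "\n".join(conllu_lines) + "\n", "\n".join(ann_lines) + "\n", gold


def worked_example_fixture() -> tuple[str, str, list[Triple]]:
    """Only the worked drug/disease sentence and its two expected triples."""
    tpl = next(t for t in _TEMPLATES if t["id"] == WORKED_EXAMPLE_ID)
    conllu = [f"# sent_id = {tpl['id']}"]
    for i, form, lemma, pos, head, deprel in tpl["tokens"]:
        conllu.append(f"{i}\t{form}\t{lemma}\t_\t{pos}\t_\t{head}\t{deprel}\t_\t_")
    conllu.append("")
    anns = [
        json.dumps(
            {
                "sentence_id": tpl["id"],
                "start": s,
                "end": e,
                "concept_id": cid,
                "semantic_type": st,
                "surface": surf,
            }
        )
        for s, e, cid, st, surf in tpl["annotations"]
    ]
    gold = [Triple(s, Label(DEPENDENCY_PATH, k), t) for s, k, t in tpl["gold"]]
    return "\n".join(conllu) + "\n", "\n".join(anns) + "\n", gold
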