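# Methods

This note documents the model assumptions, the tunable parameters, the
synthetic data the package is validated on, and the design choices made
where the method description left the design open.

## Knowledge graph

The graph is an in-memory directed multigraph of labelled triples.  Each
triple is stored once, in a canonical direction; the inverse triple
*(cⱼ, l⁻¹, cᵢ)* is implied and materialised by queries (serialized inverse
keys carry the reserved prefix `^`).  Multiplicity is preserved — a
dependency path asserted by fifty sentences is stored with count 50 —
because repetition is evidence.  Label identity includes the source kind
(`structured` vs `dependency_path`), so names can never collide across
sources.  Self-loops are dropped with a warning: a relation of a concept
with itself carries no path information here.

**Pruning** removes vertices whose total occurrence falls below
`min_concept_occurrence` (default 40) and text-derived edges whose label
occurs fewer than `min_label_occurrence` times (default 50); structured
edges are exempt from the label threshold, since only the text-derived part
of the graph suffers from the long tail of one-off parses.  "Occurrence" of
a concept is ambiguous between corpus annotation frequency and edge
incidence; both are supported — an explicit occurrence table takes
precedence, total edge incidence is the fallback — and pruned graphs carry
their pre-prune occurrence values forward, which makes pruning idempotent.

## Extraction from parsed text

Input is CoNLL-U dependency trees plus stand-off annotations mapping token
spans to concept ids and semantic types.  Parsing and concept annotation
are upstream concerns; this package consumes their output.  For every
annotated concept pair in a sentence the unique tree path between their
headwords becomes a candidate relation label.

Rules, in the order applied:

1. **Verb requirement** — a path without a verb form among its interior
   nodes asserts no relation.  "Verb form" = POS tag in a configurable set
   (default Penn `VB/VBD/VBG/VBN/VBP/VBZ`); checked on the *raw* path, so a
   verb later removed as a conjunction head still licenses the relation.
2. **Conjunct clauses** — two verb forms separated on the path by a `conj`
   edge indicate distinct sub-sentences; the pair is discarded.  This
   reading ("conj edge joining two verbs") is one operationalisation of the
   rule and is deliberately narrow; it is configurable in code.
3. **Post-processing** — `conj`/`appos` steps are removed together with
   their head words (they usually express enumeration); the adjacent step
   re-attaches to the surviving node.  A negation dependent (`neg` deprel
   or a cue lemma *not/no/never*) on any remaining path node or endpoint
   headword marks the whole path negated; negation is sticky and is encoded
   in the label key (`neg_` prefix).
4. **Length cap** — at most 6 dependency edges *after* post-processing
   (long paths are unspecific, rare, and parser-error-prone).  Whether the
   cap counts edges or nodes was ambiguous; edges are counted, and the cap
   is configurable.

Headword of a multi-token span = the span token governed from outside the
span, rightmost on ties.  Overlapping annotation pairs are skipped.  The
stored direction runs from the annotation appearing earlier in the
sentence; inverses are reconstructed at query time.  Semantic-type
filtering admits ten types (Organisms, Clinical Drug, Substances, Sign or
Symptom, Anatomical Structure, Molecular Sequence, Body Space or Junction,
Body Location or Region, Pathologic Function, Injury or Poisening), and
gene/protein annotations whose surface form is a common English word
("impact", "rare", "an" — a packaged, editable stop list) are dropped:
concept annotators notoriously mis-tag such gene aliases.

## Path discovery

Bidirectional search grows partial simple paths from both endpoints to
⌊(m+1)/2⌋ edges and joins them at common vertices; joins that would repeat
a concept are discarded.  Defaults: maximum path length m = 4 concepts,
hub threshold 100 000 (vertices above it are never used as intermediates —
hubs like *cell* are uninformative and explode the frontier), exploration
smoothing h = 100 000, time budget 40 s per pair (partial results are
returned with a truncation flag).  A neighbour that is a synonym
(`same_as`, `clinically_similar`, `has_tradename`, `has_alias`,
`gene_encodes_gene_product`, `mapped_from`, `SY`, `RL`) of any concept
already on the partial path is never explored.  Excluded labels suppress
*edges*, not vertices: a hop whose only labels are excluded is unusable.

Stochastic expansion accepts each (vertex, neighbour) event with
probability min(1, √(h+|N|)/|N|) from a generator seeded in the search
configuration, so runs are reproducible; `deterministic=True` forces every
expansion, in which case the search provably returns the same set as the
exhaustive depth-first enumeration that serves as its reference
implementation (`enumerate_paths_exhaustive`).  Paths are simple: loops
add noise, and the synonym rule presupposes non-revisiting.

## Encodings and features

The plain space freezes the one-of-N vocabulary on the training graph's
labels *and their inverses*; labels unseen at that point map to the zero
vector with a logged warning.  The LDA space is fitted on the
pair-as-document corpus: one document per connected pair, oriented by
sorted concept id, containing one word per stored edge occurrence (an edge
stored against the orientation contributes its inverse-marked key; the
inverse is *not* additionally added for forward edges, which would double
every count).  Defaults T = 200 topics, α = β = 0.1 — sparse priors
encoding that a pair realises few true relations and each relation uses
few surface forms.  Inference is batch variational (scikit-learn),
seed-fixed; at the scales this package targets, any standard LDA fit is
adequate.  `p(t)` is the length-weighted average document-topic posterior;
`f_l = p(t|l) ∝ p(t)·p(l|t)` is normalised per label.

Path features are flattened outer products (row-major; the printed 4-dim
example ordering `u₁v₁, u₁v₂, …` is the frozen contract, tested
exhaustively), kept sparse as index→value maps since the dimension is
N^(n−1).  Pair features concatenate one block per allowed path length —
summing tensors of different orders is otherwise ill-defined — and are
normalised to unit norm: Euclidean for plain features, L1 for LDA features
(keeping the probabilistic reading); both are selectable.

## Models

* Pair LR and path LR: L2-penalised logistic regression fitted with LBFGS
  (scikit-learn backend; l2_strength 1.0 = coefficient of ½‖w‖², intercept
  unpenalised; tol 1e-6, max_iter 500).  Path sequences are oriented
  source → target and tail-padded to (m−1)·N.
* Dual HMM: Baum-Welch (hmmlearn), default S = 4 hidden states.  The
  original observation model is not described; two reconstructions ship:
  **categorical** emissions over the plain label vocabulary (each edge
  emits its label multiset, in index order) and **diagonal Gaussian**
  emissions over LDA edge posteriors.  Scores combine the forward
  log-likelihoods as 1/(1+exp(ℓ₋−ℓ₊)); −∞/−∞ → 0.5 by convention.
* Pair score from path scores: mean of the best k = 3 (default) path
  scores; pairs without paths are flagged and by default excluded.
* Noise pruning (distant supervision cleanup): train, drop positive paths
  scored ≤ 0.5, retrain on pruned positives + original negatives; one
  iteration by default.

S = 4 and k = 3 are package defaults chosen as conventional values; both
are configurable and echoed into all result files.

## Evaluation

Stratified k-fold (default 10) cross-validation partitions *pairs*, never
paths, so one pair's paths cannot leak across folds.  Stratification keeps
both classes in every fold; degenerate draws are retried with a shifted
seed up to 5 times.  ROC and AUC come from the grouped threshold sweep and
equal the normalised Mann-Whitney U with ties counted half (verified
against an O(n²) pairwise oracle).  Pairs with no usable path are excluded
from training and evaluation and counted; an `include_no_path_pairs` mode
scores them 0 instead, which is how the recall gain of allowing longer
paths is measured.  The negative sampler re-pairs each positive source with
a random positive target, rejecting known positives; exhausted sources
contribute nothing, so |E−| ≤ |E+|.

## Synthetic data

Real inputs (a concept-annotated abstract corpus, a licensed thesaurus, a
drug-target database) are licensed and large, so validation runs on
generated data with known ground truth.  The generator emulates the
features of those inputs that the method is sensitive to:

* **Redundant surface labels.** Every edge label is one of
  `surface_per_latent` (default 5) realisations of one of 20 latent
  relations.  Background noise is emitted as *relation instances* — 2–4
  edges with different surfaces of one latent between one pair — which is
  exactly the co-occurrence signal a topic model can learn from.
* **Planted patterns.** Each positive pair receives (with probability
  `pattern_instantiation_prob`) a path realising a designated latent
  sequence (default one pattern of two hops, i.e. path length 3) through
  fresh intermediates, with surfaces drawn per edge.  Ambient noise paths
  connecting dataset pairs (positives and negatives alike, so both classes
  are scoreable) draw from the *non-pattern* latents: the patterns are
  characteristic of the query relation by construction.
* **Heavy tails.** Latent usage is zipfian (exponent 1.5) and background
  edge endpoints are drawn from a power-law weight (exponent 2.0), so the
  top decile of labels carries most of the edge mass and a few vertices
  dominate the degree distribution, as in real graphs.  Dedicated hubs and
  `same_as` synonym pairs exercise the search exclusions; structured
  query-relation edges are stored for positives so label exclusion has
  work to do; an optional `direct_edge_prob` gives a fraction of positives
  a direct textual edge for the direct-vs-indirect comparison.

Defaults are 2 000 concepts, 300 positive pairs (negatives sampled to
match), 6 000 background noise edges, 2 noise paths per dataset pair.  The
generator is deterministic given its seed, and every planted path is
recoverable by the exhaustive search on the emitted graph (tested).

What passing on this data does **not** show: robustness to annotation and
parsing errors beyond the stop-list mechanism, to the vocabulary scale of
real corpora (millions of labels), or to the weaker and dirtier signal of
real relations — on the real task the published models reach AUCs near
0.8, not 0.99; the synthetic planted signal is deliberately clean so that
failures indicate implementation defects rather than hard data.

The sentence fixtures are hand-built dependency trees covering every
extraction rule (verb requirement, conjunct clauses, conj/appos removal
with re-attachment, negation, the 6-edge cap at the boundary, multi-token
spans, the gene stop list, a disallowed semantic type), including a worked
drug/disease sentence whose two expected triples are fixed by construction.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` uses: 50 random graphs of 40–200 vertices for
search/oracle agreement (6 settings each); the default 2 000-concept
generator for planted-pattern recovery and its null counterpart; 50- and
300-pair datasets with 8 surfaces per latent and T = 25 topics for the
encoding trend; a 100-pair dataset for dual-HMM noise pruning; a 150-pair
dataset with `direct_edge_prob = 0.4` for the indirect-recall comparison;
100 random score/label sets for the AUC oracle.  These sizes were chosen
as the smallest at which the studied effects are stable across seeds.

## Known limitations

* The conjunct-sub-sentence rule and the HMM observation model are
  reconstructions of under-specified steps; both are flagged in code and
  configurable.
* The LDA backoff for labels unseen in the pair-document corpus is the
  zero vector, which silently zeroes any path crossing such an edge
  (logged).
* Negative sampling does not verify that sampled pairs are truly negative,
  only that they are not known positives.
* The CLI stores graphs as flat TSV; there is no persistent database
  backend, by design.
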