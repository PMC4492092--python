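"""Label/edge/path/pair encodings and the topic model over pair documents."""

import itertools

import numpy as np
import pytest

from kgpaths.features import (
    FeatureSpace,
    PairFeatureLayout,
    build_pair_documents,
    flatten_index,
    pair_feature,
    path_feature,
    train_lda,
    unflatten_index,
)
from kgpaths.kg import STRUCTURED, KnowledgeGraph, Label, Triple

from conftest import make_random_graph


def L(key, kind=STRUCTURED, inverse=False):
    return Label(kind, key, inverse)


class TestPairDocuments:
    def test_single_edge_single_word(self):
        g = KnowledgeGraph()
        g.add_triple(Triple("a", L("r"), "b"))
        docs = build_pair_documents(g)
        assert docs == [(("a", "b"), {L("r").full_key: 1})]

    def test_multiplicity_counts(self):
        g = KnowledgeGraph()
        t = Triple("a", L("r"), "b")
        g.add_triples([t, t])
        (_, bag), = build_pair_documents(g)
        assert bag[L("r").full_key] == 2

    def test_document_count_equals_connected_pairs(self):
        g = make_random_graph(seed=31, n_vertices=20, n_edges=60)
        stored = list(g.iter_triples())
        pairs = {(min(s, t), max(s, t)) for s, _, t, _ in stored}
        assert len(build_pair_documents(g)) == len(pairs)

    def test_reverse_stored_edge_becomes_inverse_word(self):
        g = KnowledgeGraph()
        g.add_triple(Triple("b", L("r"), "a"))  # stored against sorted order
        (_, bag), = build_pair_documents(g)
        assert bag == {L("r", inverse=True).full_key: 1}


class TestTrainLda:
    def test_single_topic_degenerate(self):
        model = train_lda([{"x": 2, "y": 1}], n_topics=1)
        assert model.label_posterior("x").tolist() == [1.0]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_lda([], n_topics=2)

    def test_topics_separate_disjoint_label_sets(self):
        # documents draw from one of 3 disjoint vocabularies; the argmax
        # topic of each label should respect the partition
        rng = np.random.default_rng(0)
        vocab = {k: [f"set{k}_w{i}" for i in range(6)] for k in range(3)}
        docs = []
        for _ in range(120):
            k = int(rng.integers(3))
            words = rng.choice(vocab[k], size=5)
            bag = {}
            for w in words:
                bag[w] = bag.get(w, 0) + 1
            docs.append(bag)
        model = train_lda(docs, n_topics=3, alpha=0.1, beta=0.1, seed=1)
        purity_hits = 0
        total = 0
        set_topic = {}
        for k in range(3):
            votes = {}
            for w in vocab[k]:
                t = int(np.argmax(model.label_posterior(w)))
                votes[t] = votes.get(t, 0) + 1
            set_topic[k] = max(votes, key=votes.get)
        for k in range(3):
            for w in vocab[k]:
                total += 1
                if int(np.argmax(model.label_posterior(w))) == set_topic[k]:
                    purity_hits += 1
        assert purity_hits / total >= 0.9

    def test_posteriors_sum_to_one(self):
        docs = [{"a": 2, "b": 1}, {"b": 3, "c": 1}, {"c": 2, "a": 1}]
        model = train_lda(docs, n_topics=2, seed=0)
        for w in ("a", "b", "c"):
            assert model.label_posterior(w).sum() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        docs = [{"a": 2, "b": 1}, {"b": 3, "c": 1}] * 10
        m1 = train_lda(docs, n_topics=3, seed=7)
        m2 = train_lda(docs, n_topics=3, seed=7)
        assert np.allclose(m1.topic_prior, m2.topic_prior)
        for w in ("a", "b", "c"):
            assert np.allclose(m1.label_given_topic[w], m2.label_given_topic[w])


class TestLabelAndEdgeVectors:
    def test_plain_indicator(self):
        space = FeatureSpace("plain", 4, {"structured:a": 0, "structured:b": 2})
        assert space.label_vector(L("b")).tolist() == [0, 0, 1, 0]

    def test_unknown_label_maps_to_zero(self):
        space = FeatureSpace("plain", 2, {"structured:a": 0})
        assert space.label_vector(L("zzz")).tolist() == [0, 0]

    def test_lda_posterior_hand_example(self):
        # p(t) = (0.5, 0.5), p(l|t1) = 0.2, p(l|t2) = 0.1 -> (2/3, 1/3)
        from kgpaths.features import LdaRelationModel

        model = LdaRelationModel(
            n_topics=2,
            topic_prior=np.array([0.5, 0.5]),
            label_given_topic={"structured:l": np.array([0.2, 0.1])},
            alpha=0.1,
            beta=0.1,
        )
        space = FeatureSpace("lda", 2, lda_model=model)
        vec = space.label_vector(L("l"))
        assert vec == pytest.approx([2 / 3, 1 / 3])

    def test_edge_feature_plain_sums_labels(self):
        g = KnowledgeGraph()
        g.add_triple(Triple("a", L("r1"), "b"))
        g.add_triple(Triple("a", L("r2"), "b"))
        space = FeatureSpace.plain_from_graph(g)
        vec = space.edge_feature(g, "a", "b")
        assert vec.sum() == 2
        assert set(np.nonzero(vec)[0]) == {
            space.label_index[L("r1").full_key],
            space.label_index[L("r2").full_key],
        }

    def test_edge_feature_lda_renormalised(self):
        from kgpaths.features import LdaRelationModel

        model = LdaRelationModel(
            n_topics=2,
            topic_prior=np.array([0.5, 0.5]),
            label_given_topic={
                "structured:r1": np.array([0.2, 0.1]),
                "structured:r2": np.array([0.1, 0.3]),
            },
            alpha=0.1,
            beta=0.1,
        )
        space = FeatureSpace("lda", 2, lda_model=model)
        g = KnowledgeGraph()
        g.add_triple(Triple("a", L("r1"), "b"))
        g.add_triple(Triple("a", L("r2"), "b"))
        expected = (space.label_vector(L("r1")) + space.label_vector(L("r2"))) / 2
        assert space.edge_feature(g, "a", "b") == pytest.approx(expected)

    def test_disconnected_pair_zero(self):
        g = KnowledgeGraph()
        g.add_triple(Triple("a", L("r"), "b"))
        g.add_triple(Triple("c", L("r"), "d"))
        space = FeatureSpace.plain_from_graph(g)
        assert not space.edge_feature(g, "a", "c").any()


class TestFlattenIndex:
    def test_corner_cases(self):
        assert flatten_index((0, 0), 4) == 0
        assert flatten_index((0, 1), 4) == 1
        assert flatten_index((3, 3), 4) == 15

    @pytest.mark.parametrize("n_dims,order", [(3, 2), (3, 3), (5, 2), (4, 3), (2, 4)])
    def test_bijection_exhaustive(self, n_dims, order):
        seen = set()
        for tup in itertools.product(range(n_dims), repeat=order):
            flat = flatten_index(tup, n_dims)
            assert unflatten_index(flat, n_dims, order) == tup
            seen.add(flat)
        assert seen == set(range(n_dims**order))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            flatten_index((4,), 4)


class TestPathFeature:
    @staticmethod
    def graph_with_vectors(vectors):
        """Chain graph with hand-set plain edge features: vectors[i] defines
        the labels present on hop i."""
        g = KnowledgeGraph()
        dim = len(vectors[0])
        index = {f"{STRUCTURED}:d{j}": j for j in range(dim)}
        nodes = [f"n{i}" for i in range(len(vectors) + 1)]
        for i, vec in enumerate(vectors):
            for j, v in enumerate(vec):
                for _ in range(int(v)):
                    g.add_triple(Triple(nodes[i], L(f"d{j}"), nodes[i + 1]))
        space = FeatureSpace("plain", dim, index)
        return g, space, tuple(nodes)

    def test_length_two_is_identity(self):
        g, space, nodes = self.graph_with_vectors([[1, 0, 2]])
        pf = path_feature(space, nodes, g)
        assert pf.dimension == 3
        assert pf.values == {0: 1.0, 2: 2.0}

    def test_printed_outer_product_ordering(self):
        # u = e0, v = e1 with N = 4: single 1 at flat index 1 (tuple (0, 1))
        g, space, nodes = self.graph_with_vectors([[1, 0, 0, 0], [0, 1, 0, 0]])
        pf = path_feature(space, nodes, g)
        assert pf.dimension == 16
        assert pf.values == {1: 1.0}

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(5)
        for n_edges in (2, 3):
            vecs = [rng.integers(0, 3, size=3) for _ in range(n_edges)]
            if any(v.sum() == 0 for v in vecs):
                vecs = [v + 1 for v in vecs]
            g, space, nodes = self.graph_with_vectors([v.tolist() for v in vecs])
            pf = path_feature(space, nodes, g)
            dense = np.zeros(3**n_edges)
            for k, v in pf.values.items():
                dense[k] = v
            tensor = vecs[0].astype(float)
            for v in vecs[1:]:
                tensor = np.multiply.outer(tensor, v.astype(float))
            assert dense == pytest.approx(tensor.ravel())  # row-major

    def test_zero_edge_feature_zeroes_path(self):
        g, space, nodes = self.graph_with_vectors([[1, 0, 0]])
        # extend the path with a hop the space cannot encode
        g.add_triple(Triple(nodes[-1], L("unseen"), "z"))
        space2 = FeatureSpace("plain", 3, dict(space.label_index))
        pf = path_feature(space2, nodes + ("z",), g)
        assert pf.values == {}


class TestPairFeature:
    def test_single_path_normalised(self):
        g, space, nodes = TestPathFeature.graph_with_vectors([[2, 0, 0], [0, 2, 0]])
        layout = PairFeatureLayout(3, [3])
        vec = pair_feature(space, [nodes], g, layout).toarray().ravel()
        assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_is_zero(self):
        g, space, _ = TestPathFeature.graph_with_vectors([[1, 0, 0]])
        layout = PairFeatureLayout(3, [2, 3])
        assert pair_feature(space, [], g, layout).nnz == 0

    def test_two_paths_hand_computation(self):
        g = KnowledgeGraph()
        index = {f"{STRUCTURED}:d{j}": j for j in range(2)}
        space = FeatureSpace("plain", 2, index)
        # two length-3 paths a-x-b and a-y-b with distinct label patterns
        g.add_triple(Triple("a", L("d0"), "x"))
        g.add_triple(Triple("x", L("d0"), "b"))
        g.add_triple(Triple("a", L("d1"), "y"))
        g.add_triple(Triple("y", L("d1"), "b"))
        layout = PairFeatureLayout(2, [3])
        vec = pair_feature(space, [("a", "x", "b"), ("a", "y", "b")], g, layout)
        dense = vec.toarray().ravel()
        # raw sum: 1 at (0,0) -> flat 0 and 1 at (1,1) -> flat 3; normalised
        assert dense == pytest.approx([1 / np.sqrt(2), 0, 0, 1 / np.sqrt(2)])

    def test_order_invariance(self):
        g, space, nodes = TestPathFeature.graph_with_vectors([[1, 1, 0], [0, 1, 1]])
        g.add_triple(Triple(nodes[0], L("d0"), "alt"))
        g.add_triple(Triple("alt", L("d2"), nodes[-1]))
        layout = PairFeatureLayout(3, [3])
        p1 = (nodes[0], nodes[1], nodes[2])
        p2 = (nodes[0], "alt", nodes[2])
        a = pair_feature(space, [p1, p2], g, layout).toarray()
        b = pair_feature(space, [p2, p1], g, layout).toarray()
        assert a == pytest.approx(b)

    def test_mixed_lengths_in_blocks(self):
        g, space, nodes = TestPathFeature.graph_with_vectors([[1, 0, 0], [0, 1, 0]])
        g.add_triple(Triple(nodes[0], L("d2"), nodes[2]))
        layout = PairFeatureLayout(3, [2, 3])
        vec = pair_feature(space, [(nodes[0], nodes[2]), tuple(nodes)], g, layout)
        dense = vec.toarray().ravel()
        assert dense[:3].any() and dense[3:].any()
        assert np.linalg.norm(dense) == pytest.approx(1.0, abs=1e-9)


class TestSerialization:
    def test_plain_round_trip(self, tmp_path):
        g = make_random_graph(seed=41, n_vertices=10, n_edges=30)
        space = FeatureSpace.plain_from_graph(g)
        p = tmp_path / "space.json"
        space.save(str(p))
        loaded = FeatureSpace.load(str(p))
        assert loaded.kind == space.kind
        assert loaded.label_index == space.label_index

    def test_lda_round_trip(self, tmp_path):
        docs = [{"a": 2, "b": 1}, {"b": 3, "c": 1}] * 5
        model = train_lda(docs, n_topics=2, seed=0)
        space = FeatureSpace("lda", 2, lda_model=model)
        p = tmp_path / "space.json"
        space.save(str(p))
        loaded = FeatureSpace.load(str(p))
        for w in ("a", "b", "c"):
            assert loaded.lda_model.label_posterior(w) == pytest.approx(
                model.label_posterior(w)
            )
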