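"""Scorers: logistic regression, dual HMMs, pooling, pattern decoding."""

import itertools

import numpy as np
import pytest
from scipy import optimize, sparse

from kgpaths.features import FeatureSpace, PairFeatureLayout
from kgpaths.models import (
    CATEGORICAL,
    GAUSSIAN,
    DualHMM,
    PairLRModel,
    hmm_path_score,
    pair_score_from_paths,
    top_weighted_patterns,
    train_dual_hmm,
    train_pair_lr,
    train_path_lr,
)


def toy_layout(dim=2, lengths=(2,)):
    return PairFeatureLayout(dim, lengths)


class TestPairLR:
    def test_separable_data_perfectly_ranked(self):
        X = sparse.csr_matrix(np.array([[1.0, 0.0]] * 10 + [[0.0, 1.0]] * 10))
        y = [1] * 10 + [0] * 10
        model = train_pair_lr(X, y, toy_layout(), "plain")
        scores = model.score_many(X)
        assert scores[:10].min() > scores[10:].max()

    def test_all_zero_features_constant_score(self):
        X = sparse.csr_matrix(np.zeros((8, 2)))
        y = [1, 0] * 4
        model = train_pair_lr(X, y, toy_layout(), "plain")
        scores = model.score_many(X)
        assert np.allclose(scores, scores[0])

    def test_single_class_rejected(self):
        X = sparse.csr_matrix(np.ones((4, 2)))
        with pytest.raises(ValueError):
            train_pair_lr(X, [1, 1, 1, 1], toy_layout(), "plain")

    def test_weights_match_independent_numeric_optimum(self):
        # 2-dim problem solved independently with a generic optimizer on the
        # penalised negative log-likelihood (intercept unpenalised)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 2))
        y = (X @ np.array([1.5, -2.0]) + 0.3 * rng.normal(size=60) > 0).astype(int)
        l2 = 1.0
        model = train_pair_lr(sparse.csr_matrix(X), y, toy_layout(), "plain", l2_strength=l2,
                              tol=1e-10)

        def objective(params):
            w, b = params[:2], params[2]
            z = X @ w + b
            nll = np.sum(np.logaddexp(0, -z) * y + np.logaddexp(0, z) * (1 - y))
            return nll + 0.5 * l2 * w @ w

        res = optimize.minimize(objective, np.zeros(3), method="L-BFGS-B",
                                options={"ftol": 1e-14, "gtol": 1e-10})
        assert model.weights == pytest.approx(res.x[:2], abs=1e-3)
        assert model.intercept == pytest.approx(res.x[2], abs=1e-3)

    def test_score_closed_forms(self):
        model = PairLRModel(np.zeros(2), 0.0, 1.0, toy_layout(), "plain")
        zero = sparse.csr_matrix(np.zeros((1, 2)))
        assert model.score(zero) == pytest.approx(0.5)
        model2 = PairLRModel(np.array([2.0, 0.0]), -0.5, 1.0, toy_layout(), "plain")
        x = sparse.csr_matrix(np.array([[1.0, 0.0]]))
        assert model2.score(x) == pytest.approx(1 / (1 + np.exp(-(2.0 - 0.5))))

    def test_dimension_mismatch_rejected(self):
        model = PairLRModel(np.zeros(2), 0.0, 1.0, toy_layout(), "plain")
        with pytest.raises(ValueError):
            model.score(sparse.csr_matrix(np.zeros((1, 3))))

    def test_batch_equals_single_scoring(self):
        rng = np.random.default_rng(1)
        model = PairLRModel(rng.normal(size=4), 0.1, 1.0, toy_layout(4), "plain")
        X = sparse.csr_matrix(rng.normal(size=(6, 4)))
        batch = model.score_many(X)
        singles = [model.score(X[i]) for i in range(6)]
        assert batch == pytest.approx(singles)


class TestPathLR:
    def test_tail_padding(self):
        model = train_path_lr(
            [np.array([[1.0, 0.0]])],
            [np.array([[0.0, 1.0]])],
            max_length=4,
            dimension=2,
        )
        flat = model.encode(np.array([[1.0, 0.0]]))
        assert flat.tolist() == [1.0, 0.0, 0.0, 0.0, 0.0, 0.0]

    def test_separates_simple_sequences(self):
        pos = [np.array([[1.0, 0.0], [1.0, 0.0]])] * 5
        neg = [np.array([[0.0, 1.0], [0.0, 1.0]])] * 5
        model = train_path_lr(pos, neg, max_length=3, dimension=2, l2_strength=0.1)
        assert model.score_path(pos[0]) > 0.9
        assert model.score_path(neg[0]) < 0.1


def hand_hmm(start, trans, emis):
    from hmmlearn.hmm import CategoricalHMM

    m = CategoricalHMM(n_components=len(start))
    m.startprob_ = np.asarray(start)
    m.transmat_ = np.asarray(trans)
    m.emissionprob_ = np.asarray(emis)
    m.n_features = np.asarray(emis).shape[1]
    return m


def forward_brute_force(start, trans, emis, seq):
    """Likelihood by explicit sum over all hidden state paths."""
    S = len(start)
    total = 0.0
    for states in itertools.product(range(S), repeat=len(seq)):
        p = start[states[0]] * emis[states[0]][seq[0]]
        for t in range(1, len(seq)):
            p *= trans[states[t - 1]][states[t]] * emis[states[t]][seq[t]]
        total += p
    return total


class TestDualHMM:
    def test_loglik_nondecreasing_during_training(self):
        rng = np.random.default_rng(0)
        pos = [rng.integers(0, 3, size=4) for _ in range(20)]
        neg = [rng.integers(1, 4, size=4) for _ in range(20)]
        model = train_dual_hmm(pos, neg, n_states=2, emission=CATEGORICAL, seed=1)
        for hist in (model.pos_history, model.neg_history):
            diffs = np.diff(hist)
            assert (diffs >= -1e-6).all()

    def test_two_state_parameter_recovery(self):
        # near-deterministic 2-state generator with distinct emissions
        gen = hand_hmm(
            [1.0, 0.0],
            [[0.1, 0.9], [0.9, 0.1]],
            [[0.95, 0.05], [0.05, 0.95]],
        )
        rng = np.random.default_rng(3)
        seqs = [gen.sample(12, random_state=int(rng.integers(1 << 30)))[0].ravel() for _ in range(60)]
        fitted, _ = __import__("kgpaths.models", fromlist=["_fit_hmm"])._fit_hmm(
            seqs, 2, CATEGORICAL, seed=0, max_iter=100, tol=1e-4
        )
        best = None
        for perm in itertools.permutations(range(2)):
            P = np.eye(2)[list(perm)]
            err = np.abs(P @ fitted.transmat_ @ P.T - gen.transmat_).max()
            best = err if best is None else min(best, err)
        assert best < 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        pos = [rng.integers(0, 3, size=4) for _ in range(10)]
        neg = [rng.integers(0, 3, size=4) for _ in range(10)]
        m1 = train_dual_hmm(pos, neg, n_states=2, seed=9)
        m2 = train_dual_hmm(pos, neg, n_states=2, seed=9)
        assert np.allclose(m1.positive.transmat_, m2.positive.transmat_)
        assert np.allclose(m1.negative.emissionprob_, m2.negative.emissionprob_)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            train_dual_hmm([np.array([], dtype=int)], [np.array([0, 1])], n_states=2)
        with pytest.raises(ValueError):
            train_dual_hmm([], [np.array([0, 1])], n_states=2)

    def test_gaussian_emission_variant(self):
        rng = np.random.default_rng(7)
        pos = [rng.normal(loc=1.0, size=(3, 2)) for _ in range(15)]
        neg = [rng.normal(loc=-1.0, size=(3, 2)) for _ in range(15)]
        model = train_dual_hmm(pos, neg, n_states=2, emission=GAUSSIAN, seed=2)
        assert hmm_path_score(model, pos[0]) > 0.5
        assert hmm_path_score(model, neg[0]) < 0.5


class TestHmmPathScore:
    def test_equal_likelihoods_give_half(self):
        m = hand_hmm([1.0], [[1.0]], [[0.5, 0.5]])
        dual = DualHMM(positive=m, negative=m, emission=CATEGORICAL, n_states=1)
        assert hmm_path_score(dual, np.array([0, 1])) == pytest.approx(0.5)

    def test_impossible_negative_gives_one(self):
        pos = hand_hmm([1.0], [[1.0]], [[0.5, 0.5]])
        neg = hand_hmm([1.0], [[1.0]], [[1.0, 0.0]])  # cannot emit symbol 1
        dual = DualHMM(positive=pos, negative=neg, emission=CATEGORICAL, n_states=1)
        assert hmm_path_score(dual, np.array([1])) == 1.0
        flipped = DualHMM(positive=neg, negative=pos, emission=CATEGORICAL, n_states=1)
        assert hmm_path_score(flipped, np.array([1])) == 0.0

    def test_matches_exhaustive_state_path_sum(self):
        start_p = [0.6, 0.4]
        trans_p = [[0.7, 0.3], [0.2, 0.8]]
        emis_p = [[0.5, 0.3, 0.2], [0.1, 0.1, 0.8]]
        start_n = [0.5, 0.5]
        trans_n = [[0.9, 0.1], [0.4, 0.6]]
        emis_n = [[0.2, 0.2, 0.6], [0.3, 0.5, 0.2]]
        dual = DualHMM(
            positive=hand_hmm(start_p, trans_p, emis_p),
            negative=hand_hmm(start_n, trans_n, emis_n),
            emission=CATEGORICAL,
            n_states=2,
        )
        for seq in ([0, 1], [2, 2, 1], [1]):
            lp = forward_brute_force(start_p, trans_p, emis_p, seq)
            ln = forward_brute_force(start_n, trans_n, emis_n, seq)
            expected = lp / (lp + ln)
            assert hmm_path_score(dual, np.array(seq)) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_positive_likelihood(self):
        # raising the positive model's fit to the sequence raises the score
        neg = hand_hmm([1.0], [[1.0]], [[0.5, 0.5]])
        scores = []
        for p in (0.55, 0.7, 0.9):
            pos = hand_hmm([1.0], [[1.0]], [[p, 1 - p]])
            dual = DualHMM(positive=pos, negative=neg, emission=CATEGORICAL, n_states=1)
            scores.append(hmm_path_score(dual, np.array([0, 0])))
        assert scores == sorted(scores)


class TestPooling:
    def test_top_k_mean(self):
        score, has = pair_score_from_paths([0.9, 0.2, 0.8], k=2)
        assert score == pytest.approx(0.85)
        assert has

    def test_k_larger_than_list_is_plain_mean(self):
        score, _ = pair_score_from_paths([0.2, 0.4], k=5)
        assert score == pytest.approx(0.3)

    def test_empty_flags_no_paths(self):
        score, has = pair_score_from_paths([], k=3)
        assert score == 0.0 and not has

    def test_matches_sort_then_slice_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            scores = rng.random(size=int(rng.integers(1, 12))).tolist()
            k = int(rng.integers(1, 6))
            expected = float(np.mean(sorted(scores, reverse=True)[:k]))
            assert pair_score_from_paths(scores, k)[0] == pytest.approx(expected)

    def test_invariant_to_order_and_monotone(self):
        base = [0.3, 0.6, 0.1]
        a, _ = pair_score_from_paths(base, k=2)
        b, _ = pair_score_from_paths(list(reversed(base)), k=2)
        assert a == b
        higher, _ = pair_score_from_paths([0.3, 0.9, 0.1], k=2)
        assert higher >= a


class TestPatternDecoding:
    def test_single_nonzero_weight_decodes(self):
        space = FeatureSpace("plain", 2, {"structured:a": 0, "structured:b": 1})
        layout = PairFeatureLayout(2, [3])
        weights = np.zeros(layout.total_dimension)
        weights[layout.offsets[3] + 1] = 3.0  # tuple (0, 1) -> (a, b)
        model = PairLRModel(weights, 0.0, 1.0, layout, "plain")
        (labels, w), *_ = top_weighted_patterns(model, space, top_n=1)
        assert labels == ("structured:a", "structured:b")
        assert w == 3.0

    def test_decode_encode_identity(self):
        from kgpaths.features import flatten_index

        layout = PairFeatureLayout(3, [2, 3, 4])
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.choice([2, 3, 4]))
            tup = tuple(int(x) for x in rng.integers(0, 3, size=n - 1))
            flat = layout.offsets[n] + flatten_index(tup, 3)
            assert layout.decode(flat) == (n, tup)

    def test_lda_space_rejected(self):
        space = FeatureSpace("lda", 2)
        layout = PairFeatureLayout(2, [3])
        model = PairLRModel(np.zeros(layout.total_dimension), 0.0, 1.0, layout, "lda")
        with pytest.raises(ValueError):
            top_weighted_patterns(model, space)
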