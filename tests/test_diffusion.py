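"""Biased walks and the CBOW negative-sampling embedder."""

import numpy as np
import pytest

from cdonbd import (
    CbowConfig,
    HigherOrderNetwork,
    WalkConfig,
    WalkCorpus,
    generate_walks,
    train_cbow,
    transform_weights,
    transition_distribution,
)
from cdonbd.diffusion import (
    corpus_to_windows,
    negative_sampling_objective,
    ns_loss_and_grad,
    read_corpus,
    unigram_noise_distribution,
    write_corpus,
)
from cdonbd.exceptions import DegenerateCorpusError

from oracles import empirical_transition_matrix, exact_first_order_kernel


class TestTransformWeights:
    def test_all_negative_edge_clamped_and_flagged(self):
        B = np.array([[1.0, -2.0], [-2.0, 3.0]])
        hon = HigherOrderNetwork("s", B, "encoder")
        with pytest.warns(UserWarning, match="no positive-weight neighbour"):
            W = transform_weights(hon, "clamp_negative_to_zero")
        assert W[0, 1] == 0.0 and W[1, 0] == 0.0

    def test_absolute_value_keeps_magnitude(self):
        B = np.array([[1.0, -2.0], [-2.0, 3.0]])
        W = transform_weights(HigherOrderNetwork("s", B, "encoder"), "absolute_value")
        assert W[0, 1] == 2.0

    def test_positive_entries_unchanged_diagonal_zeroed(self):
        rng = np.random.default_rng(0)
        B = np.abs(rng.normal(size=(4, 4)))
        B = (B + B.T) / 2
        W = transform_weights(HigherOrderNetwork("s", B, "encoder"))
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_array_equal(W[off], B[off])
        assert (np.diag(W) == 0).all()


class TestTransitionDistribution:
    def test_unbiased_walk_proportional_to_weights(self):
        rng = np.random.default_rng(1)
        W = np.abs(rng.normal(size=(5, 5)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        cand, probs = transition_distribution(W, prev=3, curr=0, p=1.0, q=1.0)
        expected = W[0, cand] / W[0, cand].sum()
        np.testing.assert_allclose(probs, expected, atol=1e-12)

    def test_path_graph_bias_hand_normalised(self):
        # a - b - c with unit weights; from b having come from a,
        # scores: return to a = 1/p * 1 = 0.5, advance to c = 1/q * 1 = 2
        W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        cand, probs = transition_distribution(W, prev=0, curr=1, p=2.0, q=0.5)
        lookup = dict(zip(cand.tolist(), probs.tolist()))
        assert lookup[0] == pytest.approx(0.2)
        assert lookup[2] == pytest.approx(0.8)

    def test_single_neighbour_is_forced(self):
        W = np.array([[0.0, 2.0], [2.0, 0.0]])
        cand, probs = transition_distribution(W, prev=None, curr=0, p=1.0, q=1.0)
        assert cand.tolist() == [1] and probs[0] == 1.0

    def test_isolated_node_terminates(self):
        W = np.zeros((3, 3))
        cand, probs = transition_distribution(W, prev=None, curr=0, p=1.0, q=1.0)
        assert cand.size == 0 and probs.size == 0

    def test_sums_to_one_and_supported_on_neighbours(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            W = np.abs(rng.normal(size=(6, 6))) * (rng.random((6, 6)) < 0.6)
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            for curr in range(6):
                if W[curr].sum() == 0:
                    continue
                prev = int(rng.integers(0, 6))
                cand, probs = transition_distribution(W, prev, curr, p=2.0, q=0.3)
                assert probs.sum() == pytest.approx(1.0, abs=1e-12)
                assert (W[curr, cand] > 0).all()

    def test_unit_p_q_independent_of_previous_node(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            W = np.abs(rng.normal(size=(6, 6)))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            for curr in range(6):
                base = transition_distribution(W, None, curr, 1.0, 1.0)
                for prev in range(6):
                    if prev == curr:
                        continue
                    cand, probs = transition_distribution(W, prev, curr, 1.0, 1.0)
                    np.testing.assert_array_equal(cand, base[0])
                    np.testing.assert_allclose(probs, base[1], atol=1e-12)


class TestGenerateWalks:
    def test_two_node_graph_alternates(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        corpus = generate_walks(W, WalkConfig(walks_per_node=1, walk_length=5, seed=0))
        for walk in corpus.walks:
            assert len(walk) == 5
            assert all(a != b for a, b in zip(walk, walk[1:]))

    def test_corpus_size_counts(self):
        rng = np.random.default_rng(4)
        W = np.abs(rng.normal(size=(7, 7)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        corpus = generate_walks(W, WalkConfig(walks_per_node=3, walk_length=10, seed=1))
        assert len(corpus) == 7 * 3

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        W = np.abs(rng.normal(size=(5, 5)))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        cfg = WalkConfig(walks_per_node=4, walk_length=12, seed=7)
        assert generate_walks(W, cfg).walks == generate_walks(W, cfg).walks

    def test_isolated_start_yields_length_one(self):
        W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        corpus = generate_walks(W, WalkConfig(walks_per_node=2, walk_length=6, seed=0))
        from_isolated = [w for w in corpus.walks if w[0] == 2]
        assert from_isolated and all(len(w) == 1 for w in from_isolated)

    def test_empirical_frequencies_match_exact_kernel(self):
        # weighted triangle, p=q=1: the walk is first-order Markov with
        # kernel = row-normalised weights
        W = np.array(
            [[0.0, 2.0, 1.0], [2.0, 0.0, 3.0], [1.0, 3.0, 0.0]]
        )
        cfg = WalkConfig(walks_per_node=900, walk_length=80, seed=0)
        corpus = generate_walks(W, cfg)
        empirical, n_steps = empirical_transition_matrix(corpus, 3)
        assert n_steps >= 200_000
        np.testing.assert_allclose(empirical, exact_first_order_kernel(W), atol=0.01)

    def test_corpus_serialisation_round_trip(self, tmp_path):
        corpus = WalkCorpus([[0, 1, 2], [2, 1]], 3)
        path = tmp_path / "walks.txt"
        write_corpus(corpus, path)
        assert read_corpus(path, 3).walks == corpus.walks


def _clique_corpus(seed=0):
    """Walks over two disconnected 4-cliques."""
    W = np.zeros((8, 8))
    W[:4, :4] = 1.0
    W[4:, 4:] = 1.0
    np.fill_diagonal(W, 0.0)
    return generate_walks(W, WalkConfig(walks_per_node=20, walk_length=20, seed=seed))


class TestTrainCbow:
    def test_gradients_match_central_differences(self):
        rng = np.random.default_rng(8)
        n, d, k = 4, 3, 2
        Win = rng.normal(scale=0.5, size=(n, d))
        Wout = rng.normal(scale=0.5, size=(n, d))
        context, target, negatives = [0, 2, 3], 1, [3, 0]
        _, gWin, gWout = ns_loss_and_grad(Win, Wout, context, target, negatives)
        eps = 1e-6
        for table, grad in ((Win, gWin), (Wout, gWout)):
            it = np.nditer(table, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = table[ix]
                table[ix] = orig + eps
                up = ns_loss_and_grad(Win, Wout, context, target, negatives)[0]
                table[ix] = orig - eps
                down = ns_loss_and_grad(Win, Wout, context, target, negatives)[0]
                table[ix] = orig
                assert grad[ix] == pytest.approx((up - down) / (2 * eps), abs=1e-4)

    def test_clique_structure_separates_embeddings(self):
        corpus = _clique_corpus()
        cfg = CbowConfig(dim=8, window=3, epochs=10, seed=0)
        E = train_cbow(corpus, cfg).E
        E = E / np.linalg.norm(E, axis=1, keepdims=True)
        sims = E @ E.T
        within, between = [], []
        for i in range(8):
            for j in range(i + 1, 8):
                (within if (i < 4) == (j < 4) else between).append(sims[i, j])
        assert np.mean(within) > np.mean(between)

    def test_deterministic_given_seed(self):
        corpus = _clique_corpus()
        cfg = CbowConfig(dim=6, epochs=2, seed=3)
        np.testing.assert_array_equal(train_cbow(corpus, cfg).E, train_cbow(corpus, cfg).E)

    def test_single_node_corpus_rejected(self):
        with pytest.raises(DegenerateCorpusError):
            train_cbow(WalkCorpus([[0], [0]], 2), CbowConfig(dim=4))

    def test_objective_increases_over_first_epoch(self):
        corpus = _clique_corpus(seed=5)
        n = corpus.n_nodes
        cfg = CbowConfig(dim=6, window=2, epochs=1, learning_rate=0.01, seed=0)
        centers, ctx, mask = corpus_to_windows(corpus.walks, cfg.window)
        rng = np.random.default_rng(99)
        noise = unigram_noise_distribution(corpus.walks, n, 0.75)
        fixed_negs = rng.choice(n, size=(centers.size, cfg.negatives), p=noise)

        rng_init = np.random.default_rng(cfg.seed)
        Win0 = (rng_init.random((n, cfg.dim)) - 0.5) / cfg.dim
        Wout0 = np.zeros((n, cfg.dim))
        before = negative_sampling_objective(Win0, Wout0, centers, ctx, mask, fixed_negs)

        emb = train_cbow(corpus, cfg)
        after = negative_sampling_objective(
            emb.E, emb.output_table, centers, ctx, mask, fixed_negs
        )
        assert after > before
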