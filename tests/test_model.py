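import math

import numpy as np
import pytest

from sagcn import (
    ModelConfig,
    fuse_and_classify,
    forward_branch,
    gcn_layer,
    load_model,
    normalize_adjacency,
    predict_proba,
    readout,
    sag_pool,
    save_model,
    train_model,
    windows_to_pairs,
)
from sagcn.graphs import Adjacency, GraphSample
from sagcn.model import _iter_params, _loss_and_grads, _stack, init_weights


def random_graph_pair(rng, r=6, label=0, sid="s", widx=1):
    a_lo = np.abs(rng.standard_normal((r, r)))
    a_lo = (a_lo + a_lo.T) / 2
    np.fill_diagonal(a_lo, 0.0)
    x_lo = rng.standard_normal((r, 2))
    a_ho = np.abs(rng.standard_normal((r, r)))
    a_ho = (a_ho + a_ho.T) / 2
    np.fill_diagonal(a_ho, 0.0)
    x_ho = rng.standard_normal((r, r))
    lo = GraphSample(Adjacency(a_lo), x_lo, label, sid, widx, "lo")
    ho = GraphSample(Adjacency(a_ho), x_ho, label, sid, widx, "ho")
    return lo, ho


class TestNormalize:
    def test_no_edges_gives_identity(self):
        np.testing.assert_allclose(normalize_adjacency(np.zeros((4, 4))), np.eye(4))

    def test_two_node_unit_edge(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_allclose(normalize_adjacency(a), [[0.5, 0.5], [0.5, 0.5]])

    def test_permutation_equivariance(self, rng):
        a = np.abs(rng.standard_normal((7, 7)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        perm = rng.permutation(7)
        p = np.eye(7)[perm]
        np.testing.assert_allclose(normalize_adjacency(p @ a @ p.T),
                                   p @ normalize_adjacency(a) @ p.T, atol=1e-12)

    def test_symmetric_with_bounded_spectrum(self, rng):
        for _ in range(25):
            a = np.abs(rng.standard_normal((8, 8))) * (rng.random((8, 8)) < 0.3)
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            an = normalize_adjacency(a)
            np.testing.assert_allclose(an, an.T, atol=1e-12)
            assert np.abs(np.linalg.eigvalsh(an)).max() <= 1.0 + 1e-10

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.array([[0.0, -0.2], [-0.2, 0.0]]))


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        x = np.abs(rng.standard_normal((4, 3)))
        out = gcn_layer(normalize_adjacency(np.zeros((4, 4))), x, np.eye(3))
        np.testing.assert_allclose(out, x)

    def test_zero_features_stay_zero(self, rng):
        an = normalize_adjacency(np.abs(rng.standard_normal((4, 4))) * 0.1)
        np.testing.assert_allclose(gcn_layer(an, np.zeros((4, 2)), rng.standard_normal((2, 5))), 0.0)

    def test_hand_two_node_case(self):
        an = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        out = gcn_layer(an, np.array([[1.0], [3.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(out, [[2.0], [2.0]])

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(20):
            a = np.abs(rng.standard_normal((6, 6)))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            an = normalize_adjacency(a)
            x = rng.standard_normal((6, 3))
            w = rng.standard_normal((3, 4))
            expected = np.zeros((6, 4))
            for i in range(6):
                for o in range(4):
                    acc = 0.0
                    for j in range(6):
                        for d in range(3):
                            acc += an[i, j] * x[j, d] * w[d, o]
                    expected[i, o] = max(acc, 0.0)
            np.testing.assert_allclose(gcn_layer(an, x, w), expected, atol=1e-10)

    def test_shape_mismatch_reported(self):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(np.eye(3), np.ones((4, 2)), np.ones((2, 2)))


class TestSagPool:
    @pytest.mark.parametrize("k", [0.25, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("n", [1, 2, 5, 17, 58, 116])
    def test_survivor_count_is_ceil_kn(self, rng, k, n):
        a = np.zeros((n, n))
        x = rng.standard_normal((n, 3))
        _, xp, idx = sag_pool(a, x, k, rng.standard_normal(3))
        assert len(idx) == math.ceil(k * n) == xp.shape[0]
        assert np.all(np.diff(idx) > 0)

    def test_hand_scores_select_expected_nodes(self):
        # A = 0 so A_norm = I and the score equals x @ theta directly
        x = np.array([[0.9], [-0.2], [0.5], [0.1]])
        a_p, x_p, idx = sag_pool(np.zeros((4, 4)), x, 0.5, np.array([1.0]))
        np.testing.assert_array_equal(idx, [0, 2])
        np.testing.assert_allclose(x_p, x[[0, 2]] * np.tanh(x[[0, 2]]))

    def test_ties_break_toward_lower_index(self):
        x = np.ones((4, 1))
        _, _, idx = sag_pool(np.zeros((4, 4)), x, 0.5, np.array([1.0]))
        np.testing.assert_array_equal(idx, [0, 1])

    def test_k_one_keeps_all_nodes_and_adjacency(self, rng):
        a = np.abs(rng.standard_normal((5, 5)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        x = rng.standard_normal((5, 2))
        theta = rng.standard_normal(2)
        a_p, x_p, idx = sag_pool(a, x, 1.0, theta)
        np.testing.assert_array_equal(idx, np.arange(5))
        np.testing.assert_allclose(a_p, a)
        g = np.tanh(normalize_adjacency(a) @ x @ theta)
        np.testing.assert_allclose(x_p, x * g[:, None])

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            sag_pool(np.zeros((3, 3)), np.ones((3, 1)), 0.0, np.array([1.0]))


class TestReadout:
    def test_single_node_duplicates_features(self):
        np.testing.assert_allclose(readout(np.array([[1.0, -2.0]])), [1.0, -2.0, 1.0, -2.0])

    def test_identical_rows(self):
        x = np.tile([[3.0, 1.0]], (4, 1))
        np.testing.assert_allclose(readout(x), [3.0, 1.0, 3.0, 1.0])

    def test_hand_case(self):
        np.testing.assert_allclose(readout(np.array([[1.0, 0.0], [3.0, 2.0]])),
                                   [2.0, 1.0, 3.0, 2.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            readout(np.zeros((0, 3)))


class TestForwardAndFusion:
    def test_embedding_dimension_independent_of_r(self, rng):
        cfg = ModelConfig(hidden_dim=8, seed=0)
        for r in (6, 10, 20):
            pair = random_graph_pair(rng, r=r)
            params = init_weights(cfg, {"lo": 2, "ho": r}, np.random.default_rng(0))
            emb = forward_branch(pair[0], params["branches"]["lo"], cfg)
            assert emb.shape == (16,)

    def test_branch_output_invariant_to_relabeling(self, rng):
        cfg = ModelConfig(hidden_dim=8, seed=0)
        lo, _ = random_graph_pair(rng, r=7)
        params = init_weights(cfg, {"lo": 2, "ho": 7}, np.random.default_rng(3))
        perm = rng.permutation(7)
        lo_p = GraphSample(Adjacency(lo.adjacency.values[np.ix_(perm, perm)]),
                           lo.node_features[perm], lo.label, lo.subject_id,
                           lo.window_index, "lo")
        emb = forward_branch(lo, params["branches"]["lo"], cfg)
        emb_p = forward_branch(lo_p, params["branches"]["lo"], cfg)
        np.testing.assert_allclose(emb, emb_p, atol=1e-10)

    def test_pooling_trace_uses_original_indices(self, rng):
        cfg = ModelConfig(hidden_dim=8, pool_ratio=0.5, blocks=2)
        lo, _ = random_graph_pair(rng, r=8)
        params = init_weights(cfg, {"lo": 2, "ho": 8}, np.random.default_rng(5))
        trace = []
        forward_branch(lo, params["branches"]["lo"], cfg, trace=trace)
        assert [len(t) for t in trace] == [4, 2]
        assert set(trace[1]) <= set(trace[0]) <= set(range(8))

    def test_softmax_head_normalizes(self, rng):
        head = {"W1": rng.standard_normal((8, 4)), "b1": rng.standard_normal(4),
                "W2": rng.standard_normal((4, 2)), "b2": rng.standard_normal(2)}
        probs = fuse_and_classify(rng.standard_normal(4), rng.standard_normal(4), head)
        assert probs.shape == (2,) and probs.sum() == pytest.approx(1.0)

    def test_zero_head_gives_uniform(self):
        head = {"W1": np.zeros((6, 4)), "b1": np.zeros(4),
                "W2": np.zeros((4, 2)), "b2": np.zeros(2)}
        np.testing.assert_allclose(fuse_and_classify(np.ones(3), np.ones(3), head),
                                   [0.5, 0.5])


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """The hand-written backprop must agree with central differences."""
        cfg = ModelConfig(blocks=2, hidden_dim=5, pool_ratio=0.6, dropout=0.0,
                          view="fused", standardize_lo=False, seed=0)
        pairs = [random_graph_pair(rng, r=6, label=i % 2, sid=f"s{i}") for i in range(4)]
        params = init_weights(cfg, {"lo": 2, "ho": 6}, np.random.default_rng(42))
        batch, y, _ = _stack(pairs, cfg)
        _, grads, _ = _loss_and_grads(batch, y, params, cfg)
        eps = 1e-6
        checked = 0
        for name, holder, key in _iter_params(params):
            flat = holder[key].reshape(-1)
            gflat = grads[name].reshape(-1)
            for pos in np.random.default_rng(7).choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[pos]
                flat[pos] = orig + eps
                lp, _, _ = _loss_and_grads(batch, y, params, cfg)
                flat[pos] = orig - eps
                lm, _, _ = _loss_and_grads(batch, y, params, cfg)
                flat[pos] = orig
                numeric = (lp - lm) / (2 * eps)
                assert gflat[pos] == pytest.approx(numeric, abs=2e-6, rel=1e-4)
                checked += 1
        assert checked > 30


@pytest.fixture(scope="module")
def trained(small_cohort):
    records, _ = small_cohort
    pairs = windows_to_pairs(records, 60, 10, 0.4)
    cfg = ModelConfig(epochs=100, seed=5)
    return pairs, cfg, train_model(pairs, cfg, seed=5)


class TestTraining:

    def test_loss_finite_and_decreasing_in_trend(self, trained):
        _, _, model = trained
        losses = np.array(model.loss_history)
        assert np.isfinite(losses).all()
        assert losses[-5:].mean() < losses[:5].mean()

    def test_same_seed_reproduces_weights_exactly(self, trained):
        pairs, cfg, model = trained
        model2 = train_model(pairs, cfg, seed=5)
        for name, holder, key in _iter_params(model.params):
            match = dict((n, (h, k)) for n, h, k in _iter_params(model2.params))[name]
            np.testing.assert_array_equal(holder[key], match[0][match[1]])

    def test_separable_cohort_reaches_high_training_accuracy(self, trained):
        pairs, _, model = trained
        probs = predict_proba(model, pairs)
        labels = np.array([p[0].label for p in pairs])
        assert ((probs[:, 1] >= 0.5).astype(int) == labels).mean() > 0.9

    def test_single_class_training_set_rejected(self, trained):
        pairs, cfg, _ = trained
        only_pos = [p for p in pairs if p[0].label == 1]
        with pytest.raises(ValueError, match="both classes"):
            train_model(only_pos, cfg)

    def test_checkpoint_roundtrip(self, trained, tmp_path):
        pairs, _, model = trained
        save_model(model, tmp_path / "ckpt.npz")
        reloaded = load_model(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(predict_proba(model, pairs[:10]),
                                      predict_proba(reloaded, pairs[:10]))

    def test_no_pool_ablation_runs(self, small_cohort):
        records, _ = small_cohort
        pairs = windows_to_pairs(records[:8] + records[-8:], 60, 20, 0.4)
        cfg = ModelConfig(epochs=5, hidden_dim=8, pool=False, blocks=1, view="lo", seed=1)
        model = train_model(pairs, cfg, seed=1)
        assert predict_proba(model, pairs).shape == (len(pairs), 2)
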