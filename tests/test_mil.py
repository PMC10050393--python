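"""Attention pooling, bag aggregation, MIL forward pass and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from her2mil._nn import cross_entropy
from her2mil.imaging import EmptyBagError
from her2mil.mil import (
    AttentionMILClassifier,
    AttentionParams,
    ConvTileEncoder,
    IdentityEncoder,
    aggregate_bag,
    attention_scores,
    make_attention,
    make_head,
    mil_forward,
)


@pytest.fixture
def params(rng):
    return make_attention(embed_dim=4, hidden_dim=3, rng=rng)


class TestAttentionScores:
    def test_singleton_bag_gets_weight_one(self, params, rng):
        w = attention_scores(rng.standard_normal((1, 4)), params)
        np.testing.assert_allclose(w, [1.0])

    def test_identical_embeddings_share_weight(self, params, rng):
        H = np.tile(rng.standard_normal(4), (4, 1))
        np.testing.assert_allclose(attention_scores(H, params), 0.25)

    def test_hand_computed_two_tile_example(self):
        # d=2, L=1, V=[[1,0]], w=[1]: scores are tanh(h_k[0]); softmax them
        p = AttentionParams(V=np.array([[1.0, 0.0]]), w=np.array([1.0]))
        H = np.array([[0.0, 0.0], [10.0, 0.0]])
        s = np.array([np.tanh(0.0), np.tanh(10.0)])
        expected = np.exp(s) / np.exp(s).sum()
        np.testing.assert_allclose(attention_scores(H, p), expected, atol=1e-10)

    def test_empty_bag_rejected(self, params):
        with pytest.raises(EmptyBagError):
            attention_scores(np.zeros((0, 4)), params)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(1, 12), seed=st.integers(0, 1000))
    def test_simplex_and_permutation_equivariance(self, n, seed):
        r = np.random.default_rng(seed)
        p = make_attention(4, 3, r)
        H = r.standard_normal((n, 4))
        w = attention_scores(H, p)
        assert np.all(w >= 0)
        assert np.isclose(w.sum(), 1.0, atol=1e-6)
        perm = r.permutation(n)
        np.testing.assert_allclose(attention_scores(H[perm], p), w[perm],
                                   atol=1e-12)


class TestAggregateBag:
    def test_single_tile_identity(self, rng):
        h = rng.standard_normal((1, 4))
        np.testing.assert_allclose(aggregate_bag(h, np.array([1.0])).z, h[0])

    def test_permutation_invariant(self, params, rng):
        H = rng.standard_normal((6, 4))
        w = attention_scores(H, params)
        perm = rng.permutation(6)
        np.testing.assert_allclose(aggregate_bag(H[perm], w[perm]).z,
                                   aggregate_bag(H, w).z, atol=1e-12)

    def test_duplication_invariant_through_attention(self, params, rng):
        H = rng.standard_normal((5, 4))
        z1 = aggregate_bag(H, attention_scores(H, params)).z
        H2 = np.vstack([H, H])
        z2 = aggregate_bag(H2, attention_scores(H2, params)).z
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate_bag(rng.standard_normal((3, 4)), np.ones(2) / 2)


class TestMilForward:
    def _setup(self, rng, zero_head=False):
        enc = IdentityEncoder()
        attn = make_attention(4, 3, rng)
        head = make_head(4, 3, rng, init="zero" if zero_head else "he")
        return enc, attn, head

    def test_zero_head_gives_uniform_probabilities(self, rng):
        enc, attn, head = self._setup(rng, zero_head=True)
        probs, _ = mil_forward(rng.standard_normal((5, 4)), enc, attn, head)
        np.testing.assert_allclose(probs, 1 / 3)

    def test_probabilities_sum_to_one(self, rng):
        enc, attn, head = self._setup(rng)
        probs, a = mil_forward(rng.standard_normal((7, 4)), enc, attn, head)
        assert np.isclose(probs.sum(), 1.0)
        assert np.isclose(a.sum(), 1.0)

    def test_duplicated_bag_matches_single(self, rng):
        enc, attn, head = self._setup(rng)
        h = rng.standard_normal((1, 4))
        p1, _ = mil_forward(h, enc, attn, head)
        p2, _ = mil_forward(np.tile(h, (6, 1)), enc, attn, head)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_tile_order_irrelevant(self, rng):
        enc, attn, head = self._setup(rng)
        H = rng.standard_normal((6, 4))
        p1, _ = mil_forward(H, enc, attn, head)
        p2, _ = mil_forward(H[::-1].copy(), enc, attn, head)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_nan_embedding_diagnosed_with_stage_name(self, rng):
        enc, attn, head = self._setup(rng)
        H = rng.standard_normal((3, 4))
        H[1, 2] = np.nan
        with pytest.raises(FloatingPointError, match="encoder"):
            mil_forward(H, enc, attn, head)

    def test_empty_bag_rejected(self, rng):
        enc, attn, head = self._setup(rng)
        with pytest.raises(EmptyBagError):
            mil_forward(np.zeros((0, 4)), enc, attn, head)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Finite-difference check of the full bag loss gradient (encoder,
        attention and head parameters) on a tiny bag."""
        rng = np.random.default_rng(0)
        clf = AttentionMILClassifier()
        enc = ConvTileEncoder(tile_size=8, embed_dim=4, channels=(4,), rng=rng)
        attn = make_attention(4, 3, rng)
        head = make_head(4, 2, rng)
        x = rng.integers(0, 256, (3, 8, 8, 3)).astype(np.uint8)

        def loss_fn():
            probs, _ = mil_forward(x, enc, attn, head)
            return cross_entropy(probs, 1)

        _, dV, dw = clf._forward_backward(x, 1, enc, attn, head)
        analytic = {"attn.V": dV, "attn.w": dw}
        params = {"attn.V": attn.V, "attn.w": attn.w}
        for k, g in enc.grads().items():
            analytic[f"enc.{k}"] = g.copy()
        for k, v in enc.params().items():
            params[f"enc.{k}"] = v
        for k, g in head.grads().items():
            analytic[f"head.{k}"] = g.copy()
        for k, v in head.params().items():
            params[f"head.{k}"] = v

        eps = 1e-6
        for key, p in params.items():
            flat_indices = rng.choice(p.size, size=min(8, p.size), replace=False)
            for fi in flat_indices:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss_fn()
                p[idx] = orig - eps
                lm = loss_fn()
                p[idx] = orig
                fd = (lp - lm) / (2 * eps)
                g = analytic[key][idx]
                denom = max(abs(fd), abs(g), 1e-6)
                assert abs(fd - g) / denom < 1e-4, f"{key}{idx}: {fd} vs {g}"


class TestEstimator:
    def test_fits_separable_identity_embeddings(self, rng):
        # bags of embeddings whose mean differs by class: trivially separable
        bags, y = [], []
        for i in range(30):
            label = i % 2
            center = np.full(8, 2.0 * label)
            bags.append(center + 0.1 * rng.standard_normal((rng.integers(3, 7), 8)))
            y.append(label)
        clf = AttentionMILClassifier(encoder="identity", embed_dim=8,
                                     attention_dim=4, max_epochs=20,
                                     learning_rate=1e-2,
                                     augment=False, random_state=0)
        clf.fit(bags, y)
        assert clf.best_val_balanced_accuracy_ == 1.0
        assert (clf.predict(bags) == np.array(y)).mean() > 0.9

    def test_attention_weights_align_with_bag(self, rng):
        bags = [rng.standard_normal((4, 8)) for _ in range(12)]
        y = [i % 2 for i in range(12)]
        clf = AttentionMILClassifier(encoder="identity", embed_dim=8,
                                     attention_dim=4, max_epochs=2,
                                     augment=False, random_state=0)
        clf.fit(bags, y)
        a = clf.attention_weights(bags[0])
        assert a.shape == (4,)
        assert np.isclose(a.sum(), 1.0)

    def test_zero_learning_rate_is_null_update(self, rng):
        bags = [rng.standard_normal((3, 8)) for _ in range(10)]
        y = [i % 2 for i in range(10)]
        clf = AttentionMILClassifier(encoder="identity", embed_dim=8,
                                     attention_dim=4, max_epochs=1,
                                     learning_rate=0.0, weight_decay=0.0,
                                     augment=False, random_state=3)
        rng_check = np.random.default_rng(3)
        from her2mil.mil import make_attention as ma
        ref = ma(8, 4, rng_check)
        clf.fit(bags, y)
        np.testing.assert_allclose(clf.attention_.V, ref.V)
        np.testing.assert_allclose(clf.attention_.w, ref.w)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        bags = [rng.integers(0, 256, (4, 8, 8, 3)).astype(np.uint8)
                for _ in range(10)]
        y = [i % 2 for i in range(10)]
        clf = AttentionMILClassifier(tile_size=8, embed_dim=4, attention_dim=3,
                                     conv_channels=(4,), max_epochs=2,
                                     random_state=1).fit(bags, y)
        path = tmp_path / "model.npz"
        clf.save(path)
        loaded = AttentionMILClassifier.load(path)
        np.testing.assert_array_equal(loaded.classes_, clf.classes_)
        np.testing.assert_allclose(loaded.predict_proba(bags),
                                   clf.predict_proba(bags), atol=1e-12)

    def test_reproducible_history_with_fixed_seed(self, rng):
        bags = [rng.standard_normal((3, 8)) for _ in range(10)]
        y = [i % 2 for i in range(10)]
        h = []
        for _ in range(2):
            clf = AttentionMILClassifier(encoder="identity", embed_dim=8,
                                         attention_dim=4, max_epochs=3,
                                         augment=False, random_state=7)
            clf.fit(bags, y)
            h.append([e["train_loss"] for e in clf.history_])
        assert h[0] == h[1]
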