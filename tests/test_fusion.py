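"""Dual-stage gating, routing, attention fusion, classifier and loss."""

import numpy as np
import pytest

from idfnet.autograd import Tensor
from idfnet.fusion import (
    IDFNet,
    ModelConfig,
    dynamic_route,
    load_checkpoint,
    pre_modality_gate,
    routing_entropy,
    save_checkpoint,
    total_loss,
    weighted_sum_fuse,
)
from idfnet.layers import MultiHeadAttention


class TestGate:
    def test_zero_logit_gives_half(self):
        g, gated = pre_modality_gate(np.ones((1, 4)), np.zeros(4), 0.0)
        assert np.allclose(g, 0.5)
        assert np.allclose(gated, 0.5 * np.ones((1, 4)))

    def test_zero_embedding_gives_sigmoid_bias(self):
        g, gated = pre_modality_gate(np.zeros((2, 4)), np.ones(4), 1.0)
        assert np.allclose(g, 1 / (1 + np.exp(-1.0)))
        assert np.allclose(gated, 0.0)

    def test_logit_four(self):
        f = np.ones((1, 1)) * 4.0
        g, _ = pre_modality_gate(f, np.ones(1), 0.0)
        assert np.isclose(g[0], 0.98201379, atol=1e-6)


class TestRouting:
    def test_equal_logits_uniform(self):
        f = [np.zeros((2, 4))] * 3
        w = dynamic_route(f, [np.zeros(4)] * 3, [0.0, 0.0, 0.0])
        assert np.allclose(w, 1 / 3)

    def test_softmax_arithmetic(self):
        f = [np.ones((1, 1))] * 3
        w = dynamic_route(f, [np.ones(1), np.zeros(1), np.zeros(1)],
                          [np.log(2.0) - 1.0, 0.0, 0.0])
        assert np.allclose(w, [[0.5, 0.25, 0.25]])

    def test_huge_logits_no_overflow(self):
        f = [np.ones((1, 1))] * 3
        w = dynamic_route(f, [np.ones(1) * 1000, np.zeros(1), np.zeros(1)], [0.0, 0.0, 0.0])
        assert np.all(np.isfinite(w))
        assert np.allclose(w, [[1.0, 0.0, 0.0]])

    def test_entropy_values(self):
        assert np.isclose(routing_entropy([1 / 3, 1 / 3, 1 / 3]), np.log(3))
        assert np.isclose(routing_entropy([1.0, 0.0, 0.0]), 0.0)
        assert np.isclose(routing_entropy([0.5, 0.25, 0.25]), 1.5 * np.log(2))
        with pytest.raises(ValueError):
            routing_entropy([1.2, -0.2, 0.0])


class TestWeightedSum:
    def test_one_hot_selects_embedding(self):
        embs = [np.full((1, 3), v) for v in (1.0, 2.0, 3.0)]
        out = weighted_sum_fuse(embs, np.array([[1.0, 0.0, 0.0]]))
        assert np.allclose(out, 1.0)

    def test_identical_embeddings_convexity(self):
        v = np.arange(4.0)[None]
        out = weighted_sum_fuse([v, v, v], np.array([[0.2, 0.5, 0.3]]))
        assert np.allclose(out, v)

    def test_hand_arithmetic(self):
        embs = [np.array([[2.0, 0.0]]), np.array([[0.0, 4.0]]), np.array([[1.0, 1.0]])]
        out = weighted_sum_fuse(embs, np.array([[0.5, 0.25, 0.25]]))
        assert np.allclose(out, [[1.25, 1.25]])

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            weighted_sum_fuse([np.ones((1, 2))] * 3, np.array([[0.5, 0.5, 0.5]]))


class TestCrossModalAttention:
    def test_rows_sum_to_one(self, rng):
        mha = MultiHeadAttention(8, 2, rng)
        mha(Tensor(rng.standard_normal((4, 3, 8))))
        assert np.allclose(mha.last_attention.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_tokens_identical_outputs(self, rng):
        mha = MultiHeadAttention(8, 2, rng)
        tok = rng.standard_normal((1, 1, 8))
        out = mha(Tensor(np.tile(tok, (1, 3, 1)))).data
        assert np.allclose(out[0, 0], out[0, 1])
        assert np.allclose(out[0, 1], out[0, 2])

    def test_single_head_matches_hand_computation(self, rng):
        mha = MultiHeadAttention(2, 1, rng)
        # hand-set parameters: Q = x, K = x, V = x, output identity
        for lin in (mha.wq, mha.wk, mha.wv, mha.wo):
            lin.weight.data = np.eye(2)
            lin.bias.data = np.zeros(2)
        x = np.array([[[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]])
        out = mha(Tensor(x)).data[0]
        # oracle: softmax(x x^T / sqrt(2)) x computed directly
        scores = x[0] @ x[0].T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(out, attn @ x[0], atol=1e-12)

    def test_head_count_must_divide_width(self, rng):
        with pytest.raises(ValueError):
            MultiHeadAttention(10, 3, rng)
        with pytest.raises(ValueError):
            ModelConfig(d_latent=10, n_heads=3)


class TestClassifierHead:
    def test_output_in_open_unit_interval(self, untrained_model, small_dataset):
        rec = untrained_model.predict(small_dataset.cases[:8])
        assert np.all(rec.probability > 0) and np.all(rec.probability < 1)

    def test_eval_mode_repeatable(self, untrained_model, small_dataset):
        a = untrained_model.predict(small_dataset.cases[:4]).probability
        b = untrained_model.predict(small_dataset.cases[:4]).probability
        assert np.array_equal(a, b)

    def test_zero_head_gives_half(self, untrained_model, small_dataset):
        m = untrained_model
        saved = m.state_dict()
        m.head2.weight.data = np.zeros_like(m.head2.weight.data)
        m.head2.bias.data = np.zeros_like(m.head2.bias.data)
        try:
            rec = m.predict(small_dataset.cases[:4])
            assert np.allclose(rec.probability, 0.5)
        finally:
            m.load_state_dict(saved)


class TestTotalLoss:
    def test_perfect_predictions_near_zero_bce(self):
        prob = Tensor(np.array([1 - 1e-9, 1e-9]))
        ent = Tensor(np.array([0.0, 0.0]))
        _, bd = total_loss(prob, [1, 0], ent, [], lam=0.0, beta=0.0)
        assert bd.bce < 1e-6

    def test_half_probability_gives_log_two(self):
        prob = Tensor(np.full(10, 0.5))
        ent = Tensor(np.zeros(10))
        _, bd = total_loss(prob, [1, 0] * 5, ent, [], lam=0.01, beta=0.001)
        assert np.isclose(bd.bce, np.log(2), atol=1e-12)

    def test_logit_path_matches_probability_path(self, rng):
        logit = Tensor(rng.standard_normal(16))
        prob = logit.sigmoid()
        y = rng.integers(0, 2, size=16)
        ent = Tensor(np.zeros(16))
        _, bd_p = total_loss(prob, y, ent, [], lam=0.0, beta=0.0)
        _, bd_l = total_loss(prob, y, ent, [], lam=0.0, beta=0.0, logit=logit)
        assert np.isclose(bd_p.bce, bd_l.bce, atol=1e-9)

    def test_breakdown_identity(self, rng):
        prob = Tensor(rng.uniform(0.1, 0.9, size=8))
        ent = Tensor(rng.uniform(0, np.log(3), size=8))
        params = [Tensor(rng.standard_normal((3, 3)), requires_grad=True)]
        total, bd = total_loss(prob, rng.integers(0, 2, size=8), ent, params, lam=0.01, beta=0.001)
        assert np.isclose(bd.total, bd.bce + bd.lam * bd.entropy_term + bd.beta * bd.l2, atol=1e-6)
        assert bd.bce >= 0 and bd.l2 >= 0

    def test_uniform_routing_beats_one_hot_by_lambda_log_three(self):
        prob = Tensor(np.full(4, 0.5))
        y = [0, 1, 0, 1]
        uniform_ent = Tensor(np.full(4, np.log(3)))
        onehot_ent = Tensor(np.zeros(4))
        t_uni, _ = total_loss(prob, y, uniform_ent, [], lam=0.01, beta=0.0)
        t_hot, _ = total_loss(prob, y, onehot_ent, [], lam=0.01, beta=0.0)
        assert np.isclose(float(t_hot.data) - float(t_uni.data), 0.01 * np.log(3), atol=1e-12)

    def test_literal_sign_flips_preference(self):
        prob = Tensor(np.full(2, 0.5))
        uniform_ent = Tensor(np.full(2, np.log(3)))
        onehot_ent = Tensor(np.zeros(2))
        t_uni, _ = total_loss(prob, [0, 1], uniform_ent, [], 0.01, 0.0, entropy_sign="literal")
        t_hot, _ = total_loss(prob, [0, 1], onehot_ent, [], 0.01, 0.0, entropy_sign="literal")
        assert float(t_uni.data) > float(t_hot.data)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            total_loss(Tensor(np.array([0.5])), [2], Tensor(np.array([0.0])), [], 0.01, 0.0)


class TestForward:
    def test_batch_size_invariance(self, untrained_model, small_dataset):
        cases = small_dataset.cases[:8]
        one_by_one = np.concatenate(
            [untrained_model.predict([c]).probability for c in cases]
        )
        batched = untrained_model.predict(cases).probability
        assert np.allclose(one_by_one, batched, atol=1e-10)

    def test_simplex_and_entropy_invariants(self, untrained_model, small_dataset):
        rec = untrained_model.predict(small_dataset.cases[:8])
        gs = rec.gate_state
        assert np.allclose(gs.routing_weights.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(gs.routing_weights >= 0)
        assert np.all(gs.entropy >= -1e-9) and np.all(gs.entropy <= np.log(3) + 1e-9)
        assert np.all((gs.reliability_gates > 0) & (gs.reliability_gates < 1))

    def test_zero_filled_modalities_finite(self, untrained_model, small_dataset):
        from idfnet.training import simulate_missing

        case = small_dataset.cases[0]
        for m in ("endoscopy", "ct", "histology"):
            case = simulate_missing(case, m)
        rec = untrained_model.predict([case])
        assert np.all(np.isfinite(rec.probability))
        assert np.all(np.isfinite(rec.fused))

    def test_gradients_finite_for_all_parameters(self, untrained_model, small_dataset):
        m = untrained_model
        m.set_training(True)
        try:
            out = m.forward_tensors(m.batch_inputs(small_dataset.cases[:6]))
            labels = [c.label for c in small_dataset.cases[:6]]
            loss, _ = total_loss(
                out["prob"], labels, out["entropy"], m.regularized_parameters(),
                lam=0.01, beta=0.001, logit=out["logit"],
            )
            m.zero_grad()
            loss.backward()
            grads = [p.grad for p in m.parameters() if p.grad is not None]
            assert grads, "no gradients flowed"
            assert all(np.all(np.isfinite(g)) for g in grads)
        finally:
            m.set_training(False)
            m.zero_grad()

    @pytest.mark.parametrize("mode", ["attention", "weighted_sum", "concat"])
    def test_all_fusion_modes_share_record_contract(self, small_dataset, mode):
        model = IDFNet(ModelConfig(image_size=32, d_latent=16, d_fused=32, n_heads=4,
                                   seed=2, fusion_mode=mode))
        rec = model.predict(small_dataset.cases[:4])
        assert rec.probability.shape == (4,)
        assert rec.fused.shape == (4, 32)
        assert rec.gate_state.routing_weights.shape == (4, 3)


def test_checkpoint_round_trip(tmp_path, untrained_model, small_dataset):
    path = tmp_path / "model.npz"
    untrained_model.fit_preprocessing(small_dataset.cases[:10])
    save_checkpoint(untrained_model, path)
    loaded = load_checkpoint(path)
    a = untrained_model.predict(small_dataset.cases[:4]).probability
    b = loaded.predict(small_dataset.cases[:4]).probability
    assert np.array_equal(a, b)
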