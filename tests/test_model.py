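"""Architecture contracts: shapes, analytic identities, variants, training
dynamics on single batches."""

import numpy as np
import pytest

from sleepstager import autodiff as ad
from sleepstager.autodiff import Tensor
from sleepstager.model import (VARIANTS, ModelConfig, SleepStageNet,
                               attention_pool, build_variant,
                               cross_entropy_loss, inverse_frequency_weights,
                               se_layer)
from sleepstager.nn import Adam, DTYPE


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(4, 4, 3000)).astype(DTYPE)
    y = np.array([0, 1, 2, 3])
    return x, y


class TestShapes:
    def test_branch_output_lengths_follow_conv_arithmetic(self):
        cfg = ModelConfig()
        # small: floor((3000-50)/6)+1 = 492 -> pool 8 -> 61
        assert cfg.branch_length(50, 6, 8) == 61
        # large: floor((3000-400)/50)+1 = 53 -> pool 4 -> 13
        assert cfg.branch_length(400, 50, 4) == 13
        assert cfg.seq_length == 74

    def test_mfem_output_shape(self, batch):
        x, _ = batch
        model = SleepStageNet(ModelConfig(seed=0)).eval()
        seq = model.mfem(Tensor(x[:2]))
        assert seq.shape == (2, 74, 192)

    def test_classifier_output_shape_and_simplex(self, batch):
        x, _ = batch
        model = SleepStageNet(ModelConfig(seed=0)).eval()
        probs = model.predict_proba(x)
        assert probs.shape == (4, 5)
        assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6

    def test_single_scale_variant_has_61_steps(self, batch):
        x, _ = batch
        model = build_variant("no_msconv", ModelConfig(seed=0)).eval()
        seq = model.mfem(Tensor(x[:2]))
        assert seq.shape == (2, 61, 192)

    def test_wrong_channel_count_rejected(self):
        model = SleepStageNet(ModelConfig(seed=0)).eval()
        with pytest.raises(ValueError, match="channels"):
            model.forward(np.zeros((1, 3, 3000), dtype=DTYPE))


class TestSqueezeExcitation:
    def test_zero_weights_halve_features(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.normal(size=(3, 8, 11)))
        w1 = Tensor(np.zeros((8, 2)))
        w2 = Tensor(np.zeros((2, 8)))
        out = se_layer(x, w1, w2)
        assert np.abs(out.data - 0.5 * x.data).max() < 1e-6

    def test_matches_per_channel_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 8, 13))
        w1 = rng.normal(size=(8, 2))
        w2 = rng.normal(size=(2, 8))
        out = se_layer(Tensor(x), Tensor(w1), Tensor(w2)).data
        for b in range(2):
            z = np.array([x[b, c].mean() for c in range(8)])
            s = 1 / (1 + np.exp(-(np.maximum(z @ w1, 0) @ w2)))
            for c in range(8):
                assert np.abs(out[b, c] - x[b, c] * s[c]).max() < 1e-6
            assert ((s > 0) & (s < 1)).all()

    def test_squeeze_is_linear_in_input_scale(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 4, 9))
        z1 = x.mean(axis=2)
        z2 = (2 * x).mean(axis=2)
        assert np.allclose(z2, 2 * z1)


class TestAttentionPool:
    def params(self, d, a=6, seed=4):
        rng = np.random.default_rng(seed)
        return (Tensor(rng.normal(size=(d, a))), Tensor(rng.normal(size=a)),
                Tensor(rng.normal(size=a)))

    def test_single_step_returns_h1(self):
        rng = np.random.default_rng(5)
        h = rng.normal(size=(3, 1, 7))
        c, alpha = attention_pool(Tensor(h), *self.params(7))
        assert np.allclose(alpha, 1.0)
        assert np.abs(c.data - h[:, 0, :]).max() < 1e-7

    def test_identical_states_ignore_parameters(self):
        h1 = np.random.default_rng(6).normal(size=(2, 7))
        h = np.repeat(h1[:, None, :], 5, axis=1)
        c, alpha = attention_pool(Tensor(h), *self.params(7, seed=8))
        assert np.abs(c.data - h1).max() < 1e-6

    def test_weights_sum_to_one_and_match_brute_force(self):
        rng = np.random.default_rng(7)
        h = rng.normal(size=(2, 9, 5))
        w, b, v = self.params(5)
        c, alpha = attention_pool(Tensor(h), w, b, v)
        assert np.abs(alpha.sum(axis=1) - 1).max() < 1e-6
        for i in range(2):
            scores = np.array([v.data @ np.tanh(w.data.T @ h[i, t] + b.data)
                               for t in range(9)])
            e = np.exp(scores - scores.max())
            ref = e / e.sum()
            assert np.abs(alpha[i] - ref).max() < 1e-6
            assert np.abs(c.data[i] - (ref[:, None] * h[i]).sum(0)).max() < 1e-6


class TestClassifierAndLoss:
    def test_zero_weight_classifier_is_uniform(self):
        model = SleepStageNet(ModelConfig(seed=0)).eval()
        model.classifier.weight.data[:] = 0
        model.classifier.bias.data[:] = 0
        probs = model.predict_proba(
            np.random.default_rng(0).normal(size=(2, 4, 3000)).astype(DTYPE))
        assert np.abs(probs - 0.2).max() < 1e-6

    def test_softmax_shift_invariance_and_argmax(self):
        rng = np.random.default_rng(8)
        logits = rng.normal(size=(6, 5))
        p1 = ad.softmax(logits)
        p2 = ad.softmax(logits + 13.7)
        assert np.abs(p1 - p2).max() < 1e-6
        assert (p1.argmax(1) == logits.argmax(1)).all()

    def test_perfect_prediction_loss_zero(self):
        logits = np.full((3, 5), -1e4)
        labels = np.array([0, 3, 4])
        logits[np.arange(3), labels] = 1e4
        loss = cross_entropy_loss(Tensor(logits.astype(np.float64)), labels)
        assert float(loss.data) < 1e-12

    def test_uniform_prediction_loss_is_ln5(self):
        loss = cross_entropy_loss(Tensor(np.zeros((4, 5))),
                                  np.array([0, 1, 2, 3]))
        assert abs(float(loss.data) - np.log(5)) < 1e-6

    def test_matches_brute_force_cross_entropy(self):
        rng = np.random.default_rng(9)
        logits = rng.normal(size=(10, 5))
        labels = rng.integers(0, 5, 10)
        loss = float(cross_entropy_loss(Tensor(logits), labels).data)
        p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        ref = -np.mean([np.log(p[i, l]) for i, l in enumerate(labels)])
        assert abs(loss - ref) < 1e-6

    def test_inverse_frequency_weights(self):
        labels = np.array([0] * 50 + [1] * 10 + [2] * 40)
        w = inverse_frequency_weights(labels, 5)
        assert np.isclose(w[0], 100 / (5 * 50))
        assert np.isclose(w[1], 100 / (5 * 10))
        assert w[3] == 0.0  # absent class


class TestVariants:
    def test_unknown_variant_lists_valid_names(self):
        with pytest.raises(ValueError, match="no_msconv"):
            build_variant("bogus")

    def test_all_variants_emit_probabilities(self, batch):
        x, _ = batch
        for name in VARIANTS:
            model = build_variant(name, ModelConfig(seed=0)).eval()
            xin = x[:, :model.n_input_channels, :]
            probs = model.predict_proba(xin)
            assert probs.shape == (len(x), 5)
            assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6

    def test_parameter_count_ordering(self):
        full = build_variant("full").n_parameters()
        assert build_variant("eeg_only").n_parameters() < full
        assert build_variant("no_se").n_parameters() < full
        assert build_variant("no_lstm").n_parameters() < full

    def test_no_attn_shares_shapes_except_attention(self):
        full = build_variant("full", ModelConfig(seed=0))
        noat = build_variant("no_attn", ModelConfig(seed=0))
        full_shapes = {k: v.shape for k, v in full.state_dict().items()}
        noat_shapes = {k: v.shape for k, v in noat.state_dict().items()}
        only_in_full = set(full_shapes) - set(noat_shapes)
        assert only_in_full == {"attn_w", "attn_b", "attn_v"}
        for k, shape in noat_shapes.items():
            assert full_shapes[k] == shape


class TestDeterminismAndTraining:
    def test_eval_forward_is_deterministic(self, batch):
        x, _ = batch
        model = SleepStageNet(ModelConfig(seed=0)).eval()
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_permuting_eeg_channels_changes_output(self, batch):
        x, _ = batch
        model = SleepStageNet(ModelConfig(seed=0)).eval()
        swapped = x.copy()
        swapped[:, [0, 1], :] = swapped[:, [1, 0], :]
        assert not np.allclose(model.predict_proba(x),
                               model.predict_proba(swapped))

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_single_adam_step_decreases_batch_loss(self, batch, variant):
        x, y = batch
        model = build_variant(variant, ModelConfig(seed=1))
        xin = x[:, :model.n_input_channels, :]
        model.eval()  # isolate the optimization effect from dropout noise
        opt = Adam(model.parameters(), lr=1e-3)
        model.zero_grad()
        before = cross_entropy_loss(model.forward(xin), y)
        before.backward()
        opt.step()
        after = cross_entropy_loss(model.forward(xin), y)
        assert float(after.data) < float(before.data)

    def test_save_load_round_trip(self, tmp_path, batch):
        x, _ = batch
        model = SleepStageNet(ModelConfig(seed=2)).eval()
        ref = model.predict_proba(x)
        model.save(tmp_path / "ckpt.npz")
        back = SleepStageNet.load(tmp_path / "ckpt.npz")
        assert np.allclose(back.predict_proba(x), ref, atol=1e-7)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelConfig.from_dict({"filters": 64, "bogus_key": 1})
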