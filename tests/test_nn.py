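"""Classifier architecture: preprocessing, relative bias, training mechanics."""

import numpy as np
import pytest

from nmrphaser import Spectrum1D
from nmrphaser.nn import (
    NetConfig,
    TrainConfig,
    build_model,
    load_checkpoint,
    predict,
    preprocess_input,
    relative_position_bias,
    save_checkpoint,
    train,
)
from nmrphaser.nn.layers import relative_bucket_index, softmax_cross_entropy
from nmrphaser.nn.model import PhaseClassifier
from nmrphaser.synth import scaled_training_sets

TINY = NetConfig(
    downsample_factor=4,
    embed_dim=8,
    n_layers=2,
    n_heads=2,
    rel_bias_buckets=4,
    max_field_of_view=4096,
    conv_channels=(4, 8),
    conv_kernels=(3, 3),
    conv_strides=(2, 2),
    ffn_mult=2,
)


class TestPreprocess:
    def test_scale_invariance(self, lorentzian_spec):
        a = preprocess_input(lorentzian_spec)
        b = preprocess_input(
            lorentzian_spec.copy_with(lorentzian_spec.points * 10.0)
        )
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_real_channel_max_is_one(self, dense_spec):
        x = preprocess_input(dense_spec)
        assert np.max(np.abs(x[0])) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            preprocess_input(Spectrum1D(points=np.zeros(64, complex) + 1j * 0))

    def test_too_long_rejected_naming_limit(self, rng):
        cfg = NetConfig(max_field_of_view=1024)
        spec = Spectrum1D(points=rng.standard_normal(2048) + 0j)
        with pytest.raises(ValueError, match="1024"):
            preprocess_input(spec, cfg)


class TestRelativeBias:
    def test_shift_invariance(self):
        table = np.random.default_rng(0).standard_normal((2 * 4 + 1, 2))
        bias = relative_position_bias(16, TINY, table)
        for h in range(2):
            assert np.allclose(bias[h, :-1, :-1], bias[h, 1:, 1:])

    def test_order_sensitivity_representable(self):
        idx = relative_bucket_index(16, 4, 64)
        # offset +3 and -3 land in different buckets
        assert idx[5, 2] != idx[2, 5]

    def test_distinct_scalar_count(self):
        idx = relative_bucket_index(1024, 32, 1024)
        assert len(np.unique(idx)) == 2 * 32 + 1

    def test_bucket_index_depends_only_on_offset(self):
        idx = relative_bucket_index(32, 8, 128)
        i, j = np.indices(idx.shape)
        for d in range(-31, 32):
            vals = idx[i - j == d]
            assert len(np.unique(vals)) == 1


class TestModel:
    def test_variable_length_forward(self):
        model = PhaseClassifier(
            NetConfig(max_field_of_view=131072), seed=0
        )
        for n in (4096, 8192):
            x = np.random.default_rng(1).standard_normal((1, 2, n)).astype(np.float32)
            logits = model.forward(x)
            assert logits.shape == (1, 3)

    def test_probs_sum_to_one(self, dense_spec):
        model = PhaseClassifier(TINY, seed=0)
        out = predict(model, dense_spec)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(out.probs >= 0)

    def test_parameter_count_scaled_down(self):
        model = build_model(NetConfig(), verbose=False)
        assert 0 < model.n_params() < 10**6

    def test_prediction_invariant_to_intensity_scaling(self, dense_spec):
        model = PhaseClassifier(TINY, seed=0)
        a = predict(model, dense_spec)
        b = predict(model, dense_spec.copy_with(dense_spec.points * 100.0))
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-5)

    def test_gradients_match_numerical(self):
        """Backprop oracle: central finite differences on the loss."""
        cfg = NetConfig(
            downsample_factor=4,
            embed_dim=8,
            n_layers=1,
            n_heads=2,
            rel_bias_buckets=4,
            max_field_of_view=64,
            conv_channels=(4, 8),
            conv_kernels=(3, 3),
            conv_strides=(2, 2),
            ffn_mult=2,
            dtype="float64",
        )
        model = PhaseClassifier(cfg, seed=3)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2, 16))
        y = np.array([0, 2])

        logits = model.forward(x)
        _, g = softmax_cross_entropy(logits, y)
        model.zero_grad()
        model.backward(g)

        eps = 1e-6
        for name, layer, k in model.parameters():
            flat = layer.params[k].ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp, _ = softmax_cross_entropy(model.forward(x), y)
                flat[i] = old - eps
                lm, _ = softmax_cross_entropy(model.forward(x), y)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = layer.grads[k].ravel()[i]
                assert ana == pytest.approx(num, abs=1e-7, rel=1e-4), name


class TestAttentionMaps:
    def test_row_stochastic_and_shapes(self, dense_spec):
        model = PhaseClassifier(TINY, seed=0)
        x = preprocess_input(dense_spec, TINY)
        maps = model.attention_maps(x)
        n_tokens = 4096 // TINY.downsample_factor
        assert maps.shape == (2, 2, n_tokens, n_tokens)
        np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)

    def test_token_count_tracks_length(self, rng):
        model = PhaseClassifier(TINY, seed=0)
        m1 = model.attention_maps(
            rng.standard_normal((2, 256)).astype(np.float32)
        )
        m2 = model.attention_maps(
            rng.standard_normal((2, 512)).astype(np.float32)
        )
        assert m1.shape[-1] == 64 and m2.shape[-1] == 128


def _toy_sets(n=60):
    sets = scaled_training_sets("ph0", 123, n_train=n, n_val=0, n_points=512)
    return sets["train"]


class TestTraining:
    def test_loss_decreases_on_toy_set(self):
        samples = _toy_sets(60)
        model = PhaseClassifier(TINY, seed=0)
        tcfg = TrainConfig(epochs=20, seed=0, curriculum="finetune")
        _, hist = train(model, samples, None, tcfg)
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_seeded_determinism(self):
        samples = _toy_sets(24)
        losses = []
        for _ in range(2):
            model = PhaseClassifier(TINY, seed=5)
            tcfg = TrainConfig(epochs=3, seed=5, curriculum="finetune")
            _, hist = train(model, samples, None, tcfg)
            losses.append(hist[-1]["loss"])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_empty_dataset_rejected(self):
        model = PhaseClassifier(TINY, seed=0)
        with pytest.raises(ValueError):
            train(model, [], None, TrainConfig(epochs=1, curriculum="finetune"))

    def test_curriculum_requires_pretrain_set(self):
        model = PhaseClassifier(TINY, seed=0)
        with pytest.raises(ValueError, match="pretrain"):
            train(model, _toy_sets(6), None, TrainConfig(epochs=1, curriculum="both"))


class TestCheckpoint:
    def test_round_trip(self, tmp_path, dense_spec):
        model = PhaseClassifier(TINY, seed=9)
        model.task = "ph0"
        before = predict(model, dense_spec).probs
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, task="ph0", synth_config_hash="abc")
        loaded = load_checkpoint(path, expect_task="ph0")
        after = predict(loaded, dense_spec).probs
        np.testing.assert_allclose(before, after, atol=1e-7)
        assert loaded.synth_config_hash == "abc"

    def test_wrong_task_refused(self, tmp_path):
        model = PhaseClassifier(TINY, seed=9)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, task="ph1")
        with pytest.raises(ValueError, match="ph1"):
            load_checkpoint(path, expect_task="ph0")

    def test_non_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, a=np.arange(3))
        with pytest.raises(ValueError):
            load_checkpoint(path)


def test_netconfig_validation():
    with pytest.raises(ValueError):
        NetConfig(n_classes=2)
    with pytest.raises(ValueError):
        NetConfig(conv_strides=(2, 2, 2, 2))  # product != downsample_factor
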