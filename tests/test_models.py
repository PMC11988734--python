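"""Backbone registry, parameter accounting, freeze laws, and training."""

import numpy as np
import pytest

from afview import (
    ModelSpec,
    TrainConfig,
    build_classifier,
    count_trainable_params,
    fine_tune,
    load_classifier,
    retrain,
    save_classifier,
)
from afview.architectures import LAYER_TABLES, layer_table
from afview.registry import BACKBONES
from afview import nn

# Published parameter totals (in M, two decimals) of the feature extractors,
# and the trainable counts of their fine-tuned adaptations with frozen BN.
PUBLISHED_M = {
    "mobilenetv2_035": (0.41, 0.38),
    "mobilenetv2_100": (2.26, 2.19),
    "mobilenetv2_140": (4.37, 4.27),
    "vgg16": (14.72, 14.72),
    "densenet121": (7.04, 6.87),
    "densenet169": (12.64, 12.33),
    "densenet201": (18.32, 17.87),
    "resnet50": (23.59, 23.48),
    "resnet50v2": (23.57, 23.48),
}


class TestParameterAccounting:
    def test_head_parameter_law_all_backbones(self):
        for bid, info in BACKBONES.items():
            assert count_trainable_params(bid, "retrain") == info.feature_dim + 1

    def test_layer_tables_agree_with_registry_feature_dims(self):
        for key in LAYER_TABLES:
            table = layer_table(key)
            assert table.feature_dim == BACKBONES[key].feature_dim

    def test_retrained_head_range_513_to_2049(self):
        counts = {count_trainable_params(b, "retrain") for b in BACKBONES if b != "tinycnn"}
        assert min(counts) == 513  # 512-feature backbone
        assert max(counts) == 2049  # 2048-feature backbones

    @pytest.mark.parametrize("key,expected", sorted(PUBLISHED_M.items()))
    def test_shape_tables_reproduce_published_sizes(self, key, expected):
        table = layer_table(key)
        total_m, finetune_m = expected
        # totals describe the full modified model: feature extractor + binary head
        assert round((table.total_params + table.head_params()) / 1e6, 2) == total_m
        assert round(table.finetune_trainable() / 1e6, 2) == finetune_m

    def test_known_exact_totals(self):
        assert layer_table("vgg16").total_params == 14_714_688
        assert layer_table("resnet50").total_params == 23_587_712
        assert layer_table("densenet121").total_params == 7_037_504
        assert layer_table("mobilenetv2_100").total_params == 2_257_984

    def test_finetune_count_monotone_over_retrain(self):
        for key in LAYER_TABLES:
            table = layer_table(key)
            assert table.finetune_trainable() >= table.retrain_trainable()

    def test_tinycnn_counts_by_hand(self):
        # conv1 3x3x3x8+8, conv2 3x3x8x16+16, conv3 3x3x16x64+64, head 64+1
        model = build_classifier(ModelSpec())
        assert count_trainable_params(model, "retrain") == 64 + 1
        assert count_trainable_params(model, "fine_tune") == 224 + 1168 + 9280 + 65
        # model-derived and shape-table counts agree
        assert count_trainable_params(model, "fine_tune") == count_trainable_params(
            "tinycnn", "fine_tune"
        )

    def test_unknown_backbone_and_phase_rejected(self):
        with pytest.raises(KeyError, match="registered"):
            count_trainable_params("resnext", "retrain")
        with pytest.raises(ValueError, match="phase"):
            count_trainable_params("tinycnn", "train")

    def test_finetune_count_unavailable_without_table(self):
        with pytest.raises(NotImplementedError, match="layer table"):
            count_trainable_params("nasnetmobile", "fine_tune")


class TestBuildClassifier:
    def test_named_backbones_are_shape_only(self):
        with pytest.raises(NotImplementedError, match="shape-only"):
            build_classifier(ModelSpec(backbone_id="vgg16"))

    def test_input_size_contract_enforced(self):
        with pytest.raises(ValueError, match="expects D=240"):
            ModelSpec(backbone_id="efficientnetv2b1", input_size=224).D

    def test_sigmoid_output_range(self, rng):
        model = build_classifier(ModelSpec(seed=1))
        probs = model.predict(rng.random((4, 64, 64, 3)))
        assert np.all((probs >= 0) & (probs <= 1))

    def test_zero_head_outputs_half(self, rng):
        model = build_classifier(ModelSpec())
        model.network.head.params["W"][:] = 0.0
        model.network.head.params["b"][:] = 0.0
        np.testing.assert_allclose(model.predict(rng.random((3, 64, 64, 3))), 0.5)

    def test_duplicate_inputs_identical_probs(self, rng):
        model = build_classifier(ModelSpec(seed=2))
        img = rng.random((64, 64, 3))
        probs = model.predict(np.stack([img, img]))
        assert probs[0] == probs[1]

    def test_shape_mismatch_rejected(self, rng):
        model = build_classifier(ModelSpec())
        with pytest.raises(ValueError, match="expected"):
            model.predict(rng.random((2, 32, 32, 3)))


def toy_data(rng, n=24, d=16):
    """Linearly separable image classes: dim vs bright textures."""
    y = np.repeat([0, 1], n // 2)
    X = rng.random((n, d, d, 3)) * 0.2 + y[:, None, None, None] * 0.6
    return X, y


class TestTrainingProtocol:
    def test_retrain_freezes_base_bit_identical(self, rng):
        model = build_classifier(ModelSpec(input_size=16, seed=3))
        X, y = toy_data(rng)
        before = {
            k: v.copy() for k, v in model.network.get_state().items() if "head" not in k
        }
        retrain(model, (X, y), (X, y), TrainConfig(phase="retrain", max_epochs=3, seed=0))
        after = model.network.get_state()
        for k, v in before.items():
            np.testing.assert_array_equal(after[k], v)
        assert model.phase == "retrained"

    def test_loss_decreases_on_separable_toy(self, rng):
        model = build_classifier(ModelSpec(input_size=16, seed=3))
        X, y = toy_data(rng, n=32)
        _, history = retrain(
            model, (X, y), (X, y), TrainConfig(phase="retrain", max_epochs=6, seed=0)
        )
        losses = [h["train_loss"] for h in history[:4]]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_retrain_deterministic_under_seed(self, rng):
        X, y = toy_data(rng)
        heads = []
        for _ in range(2):
            m = build_classifier(ModelSpec(input_size=16, seed=3))
            retrain(m, (X, y), (X, y), TrainConfig(phase="retrain", max_epochs=3, seed=5))
            heads.append(m.network.head.params["W"].copy())
        np.testing.assert_array_equal(heads[0], heads[1])

    def test_finetune_freezes_batchnorm(self, rng):
        model = build_classifier(ModelSpec(input_size=16, seed=3))
        X, y = toy_data(rng)
        retrain(model, (X, y), (X, y), TrainConfig(phase="retrain", max_epochs=2, seed=0))
        bn = [l for l in model.network.layers if isinstance(l, nn.BatchNorm)][0]
        before = (bn.params["gamma"].copy(), bn.params["beta"].copy(),
                  bn.running_mean.copy(), bn.running_var.copy())
        fine_tune(model, (X, y), (X, y),
                  TrainConfig(phase="fine_tune", max_epochs=2, learning_rate=1e-3, seed=0))
        np.testing.assert_array_equal(bn.params["gamma"], before[0])
        np.testing.assert_array_equal(bn.params["beta"], before[1])
        np.testing.assert_array_equal(bn.running_mean, before[2])
        np.testing.assert_array_equal(bn.running_var, before[3])
        assert model.phase == "fine_tuned"

    def test_checkpoint_is_max_validation_accuracy(self, rng):
        model = build_classifier(ModelSpec(input_size=16, seed=4))
        X, y = toy_data(rng, n=32)
        _, history = retrain(
            model, (X, y), (X, y), TrainConfig(phase="retrain", max_epochs=8, seed=0)
        )
        best = max(h["val_acc"] for h in history)
        logits = model.network.head.forward(model.network.features(X))
        acc = np.mean((nn.sigmoid(logits.ravel()) >= 0.5) == (y == 1))
        assert acc == pytest.approx(best)

    def test_finetune_without_retrain_warns(self, rng):
        model = build_classifier(ModelSpec(input_size=16, seed=3))
        X, y = toy_data(rng)
        with pytest.warns(UserWarning, match="not retrained"):
            fine_tune(model, (X, y), (X, y),
                      TrainConfig(phase="fine_tune", max_epochs=1, seed=0))

    def test_empty_data_rejected(self):
        model = build_classifier(ModelSpec(input_size=16))
        empty = (np.empty((0, 16, 16, 3)), np.empty(0, int))
        with pytest.raises(ValueError, match="empty"):
            retrain(model, empty, empty, TrainConfig(phase="retrain"))

    def test_config_defaults_follow_protocol(self):
        re_cfg, ft_cfg = TrainConfig(phase="retrain"), TrainConfig(phase="fine_tune")
        assert re_cfg.learning_rate == 1e-3 and re_cfg.batch_size == 64
        assert ft_cfg.learning_rate == 1e-5 and ft_cfg.batch_size == 32
        assert ft_cfg.learning_rate < re_cfg.learning_rate
        assert re_cfg.max_epochs == 450

    def test_save_load_roundtrip(self, rng, tmp_path):
        model = build_classifier(ModelSpec(input_size=16, seed=3))
        X, y = toy_data(rng)
        retrain(model, (X, y), (X, y), TrainConfig(phase="retrain", max_epochs=2, seed=0))
        path = tmp_path / "clf.npz"
        save_classifier(model, path)
        back = load_classifier(path)
        assert back.phase == "retrained"
        np.testing.assert_array_equal(back.predict(X), model.predict(X))


class TestEngineGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Central-difference check of the full layer stack's gradients."""
        net = nn.Network([
            nn.Conv2D(2, 3, k=3, name="c1", rng=rng),
            nn.BatchNorm(3, frozen=True),
            nn.ReLU(),
            nn.MaxPool2D(2),
            nn.Conv2D(3, 4, k=3, name="c2", rng=rng),
            nn.ReLU(),
            nn.GlobalAvgPool(),
            nn.Dense(4, 1, rng=rng),
        ])
        # randomize BN stats so the normalization path is non-trivial
        bn = net.layers[1]
        bn.running_mean = rng.normal(size=3) * 0.1
        bn.running_var = 1.0 + rng.random(3)
        x = rng.normal(size=(2, 6, 6, 2))
        y = np.array([1.0, 0.0])

        def loss_fn():
            logits = net.forward(x)
            return nn.bce_loss_and_grad(logits, y)[0]

        logits = net.forward(x)
        _, dz = nn.bce_loss_and_grad(logits, y)
        net.backward(dz)
        h = 1e-6
        for _, layer, key, val in net.named_params():
            flat = val.ravel()
            for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = loss_fn()
                flat[idx] = orig - h
                lm = loss_fn()
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                an = layer.grads[key].ravel()[idx]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-7)
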