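import numpy as np
import pytest

from srsplan.models import ModelConfig, TrainConfig, attention_fuse, build_model, train
from srsplan.nn import MultiHeadAttention3d
from srsplan.preprocess import TensorCase


class TestArchitecture:
    def test_full_scale_preset_bottleneck_is_512(self):
        cfg = ModelConfig.paper_preset("unet")
        model = build_model(cfg)
        assert model.bottleneck_filters == 512
        assert model.channel_schedule() == [32, 64, 128, 256, 512]

    def test_attention_preset_heads_and_dims(self):
        cfg = ModelConfig.paper_preset("attunet")
        model = build_model(cfg)
        assert model.attention.h == 8
        assert model.attention.d == 64
        assert model.attention.embed_dim == 512

    def test_channel_schedule_doubles_per_level(self):
        model = build_model(ModelConfig(variant="unet", depth=3, base_filters=16))
        assert model.channel_schedule() == [16 * 2**l for l in range(4)]

    def test_parameter_count_grows_with_base_filters(self):
        small = build_model(ModelConfig(variant="unet", depth=2, base_filters=4))
        big = build_model(ModelConfig(variant="unet", depth=2, base_filters=8))
        assert big.n_parameters() > small.n_parameters()

    @pytest.mark.parametrize("variant", ["unet", "attunet"])
    def test_output_preserves_spatial_shape(self, variant):
        cfg = ModelConfig.smoke_preset(variant)
        model = build_model(cfg)
        cin = 1 if variant == "unet" else 2
        x = np.random.default_rng(0).normal(size=(cin, 16, 16, 8)).astype(np.float32)
        assert model.forward(x).shape == (16, 16, 8)

    def test_indivisible_shape_raises_clear_error(self):
        model = build_model(ModelConfig.smoke_preset("unet"))
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 15, 16, 8)))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(variant="resnet"))


class TestAttention:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        layer = MultiHeadAttention3d(4, 4, n_heads=2, head_dim=3, rng=rng)
        layer.forward(rng.normal(size=(4, 2, 2, 2)), rng.normal(size=(4, 2, 2, 2)))
        p = layer.attention_weights()
        assert np.allclose(p.sum(axis=2), 1.0)

    def test_constant_ct_gives_uniform_weights_and_mean_value(self):
        rng = np.random.default_rng(1)
        layer = MultiHeadAttention3d(3, 3, n_heads=2, head_dim=4, rng=rng)
        xs = rng.normal(size=(3, 2, 2, 1))
        xc = np.ones((3, 2, 2, 1)) * 0.7  # spatially constant CT features
        out = layer.forward(xs, xc)
        p = layer.attention_weights()
        assert np.allclose(p, 1.0 / 4)
        # every output position equals the projected mean value
        flat = out.reshape(3, -1)
        assert np.allclose(flat - flat.mean(axis=1, keepdims=True), 0.0, atol=1e-6)

    def test_single_position_is_projected_value(self):
        rng = np.random.default_rng(2)
        layer = MultiHeadAttention3d(3, 3, n_heads=1, head_dim=4, rng=rng)
        xs = rng.normal(size=(3, 1, 1, 1))
        xc = rng.normal(size=(3, 1, 1, 1))
        out = layer.forward(xs, xc)
        v = layer.params["Wv"] @ xc.reshape(3, 1)
        expected = layer.params["Wo"] @ v + layer.params["bo"][:, None]
        assert np.allclose(out.reshape(3, 1), expected, atol=1e-6)

    def test_two_token_hand_computed_example(self):
        # 1 head, 2 dims, 2 tokens; identity projections, no scaling
        layer = MultiHeadAttention3d(2, 2, n_heads=1, head_dim=2, scale=False)
        layer.params["Wq"] = np.eye(2, dtype=np.float32)
        layer.params["Wk"] = np.eye(2, dtype=np.float32)
        layer.params["Wv"] = np.eye(2, dtype=np.float32)
        layer.params["Wo"] = np.eye(2, dtype=np.float32)
        layer.params["bo"] = np.zeros(2, dtype=np.float32)
        xs = np.array([[1.0, 0.0], [0.0, 1.0]]).reshape(2, 2, 1, 1)  # Q = tokens (1,0), (0,1)
        xc = np.array([[2.0, 0.0], [0.0, 2.0]]).reshape(2, 2, 1, 1)  # K = V = (2,0), (0,2)
        out = layer.forward(xs, xc).reshape(2, 2)
        # token 1: scores (2, 0) -> softmax (e^2, 1)/(e^2+1); out = [2a, 2(1-a)]
        a = np.exp(2) / (np.exp(2) + 1)
        expected = np.array([[2 * a, 2 * (1 - a)], [2 * (1 - a), 2 * a]])
        assert np.allclose(out, expected.T.reshape(2, 2), atol=1e-6)

    def test_functional_wrapper_shape(self):
        rng = np.random.default_rng(3)
        out = attention_fuse(
            rng.normal(size=(4, 2, 2, 2)), rng.normal(size=(4, 2, 2, 2)), n_heads=2, head_dim=4
        )
        assert out.shape == (4, 2, 2, 2)

    def test_shape_mismatch_rejected(self):
        layer = MultiHeadAttention3d(2, 2)
        with pytest.raises(ValueError):
            layer.forward(np.zeros((2, 2, 2, 2)), np.zeros((2, 2, 2, 1)))


def _toy_dataset(n=1, shape=(16, 16, 8), seed=0):
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        inputs = rng.uniform(-1, 1, size=(2, *shape)).astype(np.float32)
        x, y, z = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
        target = np.exp(-(x**2 + y**2 + z**2) * 4).astype(np.float32) * 2 - 1
        cases.append(TensorCase(inputs=inputs, target=target, meta={"dose_ref_max": 42.0}))
    return cases


class TestTraining:
    def test_same_seed_reproduces_history(self):
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=5, early_stop_patience=4, seed=1)
        runs = []
        for _ in range(2):
            model = build_model(ModelConfig.smoke_preset("unet"))
            runs.append(train(model, _toy_dataset(), cfg)["train_loss"])
        assert runs[0] == runs[1]

    def test_early_stop_on_flat_validation(self):
        # constant target reached immediately: validation cannot improve
        ds = _toy_dataset()
        ds[0].target = np.zeros_like(ds[0].target)
        cfg = TrainConfig(learning_rate=0.0 + 1e-12, max_epochs=50, early_stop_patience=5,
                          plateau_patience=3, seed=0)
        model = build_model(ModelConfig.smoke_preset("unet"))
        history = train(model, ds, cfg)
        assert len(history["train_loss"]) < 50

    def test_plateau_reduces_learning_rate(self):
        ds = _toy_dataset()
        cfg = TrainConfig(learning_rate=1e-12, max_epochs=12, early_stop_patience=11,
                          plateau_patience=3, plateau_factor=10, seed=0)
        model = build_model(ModelConfig.smoke_preset("unet"))
        history = train(model, ds, cfg)
        assert min(history["lr"]) < 1e-12

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(ModelConfig.smoke_preset("unet")), [], TrainConfig())

    def test_loss_decreases_on_memorizable_task(self):
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=40, early_stop_patience=39, seed=0)
        model = build_model(ModelConfig.smoke_preset("unet"))
        history = train(model, _toy_dataset(), cfg)
        assert history["train_loss"][-1] < history["train_loss"][0] * 0.5
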