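import numpy as np
import pytest

from diffdot import nn
from diffdot.cafnet import (
    CAFNet,
    NetworkConfig,
    TrainConfig,
    VARIANTS,
    count_parameters,
)

TINY = NetworkConfig(automap_hidden_width=32, n_fusion_blocks=1)


# ---------------------------------------------------------------------------
# domain transform

def test_automap_output_shape_and_zero_map(rng):
    model = CAFNet(TINY, seed=0)
    x = rng.random((2, 16, 15, 2)).astype(np.float32)
    out = model.automap_transform(x)
    assert out.shape == (2, 64, 64, 1)
    # zero input with zero biases stays zero through tanh layers
    stage = dict(model.stages)["automap"]
    for layer in stage.layers:
        if isinstance(layer, nn.Dense):
            layer.b.value[...] = 0.0
    assert np.allclose(model.automap_transform(np.zeros((1, 16, 15, 2))), 0.0)
    with pytest.raises(ValueError):
        model.automap_transform(np.zeros((2, 15, 16, 2)))


def test_automap_equals_dense_matrix_arithmetic(rng):
    model = CAFNet(TINY, seed=3)
    stage = dict(model.stages)["automap"]
    d1, d2 = [l for l in stage.layers if isinstance(l, nn.Dense)]
    x = rng.random((3, 16, 15, 2)).astype(np.float32)
    flat = x.reshape(3, 480)
    manual = np.tanh(
        np.tanh(flat @ d1.w.value + d1.b.value) @ d2.w.value + d2.b.value
    ).reshape(3, 64, 64, 1)
    assert np.allclose(model.automap_transform(x), manual, atol=1e-6)


# ---------------------------------------------------------------------------
# blocks

def test_feb_shapes_and_constant_bias_case(rng):
    from diffdot.cafnet import _feb

    cfg = NetworkConfig(use_batchnorm=False)
    for k in (1, 3, 5):
        feb = _feb(rng, 1, cfg, kernel=k)
        y = feb.forward(np.zeros((1, 64, 64, 1), dtype=np.float32), False)
        assert y.shape == (1, 64, 64, 8)
    feb = _feb(rng, 1, cfg, kernel=3)
    # zero conv weights, bias b, BN bypassed -> ReLU(b) everywhere
    convs = [l for l in feb.layers if isinstance(l, nn.Conv2D)]
    for conv in convs:
        conv.w.value[...] = 0.0
    convs[0].b.value[...] = -1.0  # killed by the inner ReLU
    convs[1].b.value[...] = np.linspace(-1, 1, 8)
    out = feb.forward(rng.random((1, 64, 64, 1)).astype(np.float32), False)
    expected = np.maximum(np.linspace(-1, 1, 8), 0.0)
    assert np.allclose(out[0, 0, 0], expected)


def test_fusion_block_channels_and_pool_branch(rng):
    from diffdot.cafnet import _fusion

    cfg = NetworkConfig()
    fusion = _fusion(rng, 8, cfg)
    x = rng.random((1, 32, 32, 8)).astype(np.float32)
    y = fusion.forward(x, False)
    assert y.shape == (1, 32, 32, 8 + 8 + 8 + 8)
    # max pooling of a constant image is the identity before the 1x1 conv
    pool = fusion.branches[-1].layers[0]
    const = np.full((1, 16, 16, 8), 2.5, dtype=np.float32)
    assert np.allclose(pool.forward(const, False), const)


def test_channel_attention_zero_mlp_gives_half(rng):
    cab = nn.ChannelAttention(rng, 8, 4)
    for p in cab.params():
        p.value[...] = 0.0
    out = cab.forward(rng.standard_normal((2, 16, 16, 8)).astype(np.float32), False)
    assert np.allclose(cab.last_weights, 0.5)
    with pytest.raises(ValueError):
        nn.ChannelAttention(rng, 10, 4)  # ratio must divide channels


def test_channel_attention_summaries_and_identity_rescale(rng):
    cab = nn.ChannelAttention(rng, 3, 3)
    x = np.zeros((1, 4, 4, 3), dtype=np.float32)
    x[..., 0] = 2.0
    x[..., 1] = -1.0
    x[..., 2] = 0.5
    z_avg, z_max, _ = cab.summaries(x)
    assert np.allclose(z_avg, [[2.0, -1.0, 0.5]])
    assert np.allclose(z_max, [[2.0, -1.0, 0.5]])
    # saturating the gate to w ~= 1 leaves the input unchanged
    cab.w1.value[...] = 0.0
    cab.w2.value[...] = 0.0
    cab.b1.value[...] = 0.0
    cab.b2.value[...] = 50.0
    y = cab.forward(x, False)
    assert np.allclose(y, x, atol=1e-5)
    # with finite (unsaturated) logits the gate stays strictly inside (0, 1)
    cab2 = nn.ChannelAttention(rng, 3, 3)
    cab2.forward(rng.standard_normal((4, 6, 6, 3)).astype(np.float32), False)
    w = cab2.last_weights
    assert (w > 0).all() and (w < 1).all()


def test_gap_suppresses_noise_variance(rng):
    # spatial averaging of iid noise shrinks its variance by H*W
    sigma = 0.7
    maps = sigma * rng.standard_normal((1000, 64, 64, 1)).astype(np.float32)
    z_avg = maps.mean(axis=(1, 2))
    expected = sigma**2 / (64 * 64)
    assert abs(z_avg.var() - expected) / expected < 0.2


def test_rescale_preserves_argmax_location(rng):
    cab = nn.ChannelAttention(rng, 4, 2)
    x = rng.standard_normal((3, 8, 8, 4)).astype(np.float32)
    y = cab.forward(x, False)
    for c in range(4):
        before = [np.argmax(x[i, ..., c]) for i in range(3)]
        after = [np.argmax(y[i, ..., c]) for i in range(3)]
        assert before == after


# ---------------------------------------------------------------------------
# whole model

def test_all_variants_build_and_run(rng):
    x = rng.random((1, 16, 15, 2)).astype(np.float32)
    for variant in VARIANTS:
        cfg = NetworkConfig(
            automap_hidden_width=32, n_fusion_blocks=1, variant=variant
        )
        model = CAFNet(cfg, seed=1)
        out = model.forward(x)
        assert out.shape == (1, 64, 64, 2)
    with pytest.raises(ValueError):
        NetworkConfig(variant="bogus")


def test_parameter_count_stable_and_manifest(tmp_path, rng):
    a = CAFNet(TINY, seed=5)
    b = CAFNet(TINY, seed=5)
    assert a.count_parameters() == b.count_parameters() > 0
    assert count_parameters(a) == a.count_parameters()
    a.save(str(tmp_path / "model"))
    loaded = CAFNet.load(str(tmp_path / "model"))
    x = rng.random((2, 16, 15, 2)).astype(np.float32)
    assert np.allclose(loaded.forward(x), a.forward(x))


def test_training_deterministic_and_learns(small_dataset):
    tc = TrainConfig(epochs=2, seed=9, batch_size=8)
    r1 = CAFNet(TINY, seed=4).fit(small_dataset, tc)
    r2 = CAFNet(TINY, seed=4).fit(small_dataset, tc)
    assert r1.history["train_loss"][0] == r2.history["train_loss"][0]
    assert r1.history["train_loss"][-1] < r1.history["train_loss"][0]
    assert "variant" in r1.summary()


def test_single_batch_overfit_capacity(small_dataset):
    x = small_dataset["train"]["inputs"][:16].astype(np.float32)
    y = small_dataset.normalize_targets(
        small_dataset["train"]["targets"][:16]
    ).astype(np.float32)
    model = CAFNet(TINY, seed=2)
    opt = nn.Adam(model.params(), lr=1e-3, beta1=0.5)
    first = None
    for _ in range(200):
        opt.zero_grad()
        pred = model.net.forward(x, training=True)
        loss, grad = model._loss_and_grad(pred, y, (0.5, 0.5))
        model.net.backward(grad)
        opt.step()
        if first is None:
            first = loss
    assert loss < 0.1 * first  # strong memorization of a single batch


def test_predict_batch_consistency_and_units(small_dataset):
    model = CAFNet(TINY, seed=8)
    model.fit(small_dataset, TrainConfig(epochs=1, seed=1, batch_size=8))
    xs = small_dataset["test"]["inputs"].astype(np.float32)
    stats = small_dataset.normalization_statistics
    batch = model.predict(xs, stats)
    singles = np.stack([model.predict(xs[i], stats) for i in range(len(xs))])
    assert np.allclose(batch, singles, atol=1e-5)
    # permutation invariance in eval mode
    perm = np.random.default_rng(0).permutation(len(xs))
    assert np.allclose(model.predict(xs[perm], stats), batch[perm], atol=1e-5)
    assert (batch > 0).all()  # positive physical-unit outputs
    with pytest.raises(ValueError):
        model.predict(xs, None)


def test_attention_reduces_feature_entropy_on_trained_model(small_dataset):
    from diffdot.resolution import attention_diagnostics

    model = CAFNet(TINY, seed=6)
    model.fit(small_dataset, TrainConfig(epochs=2, seed=3, batch_size=8))
    x = small_dataset["test"]["inputs"].astype(np.float32)
    _, before, after = model.forward_with_cab_maps(x)
    diag = attention_diagnostics(before, after)
    assert diag.entropy_after <= diag.entropy_before
    assert (model.cab.last_weights > 0).all()
    assert (model.cab.last_weights < 1).all()


def test_epoch_callback_sees_snapshots(small_dataset):
    seen = []
    CAFNet(TINY, seed=0).fit(
        small_dataset,
        TrainConfig(epochs=3, seed=0, batch_size=8),
        epoch_callback=lambda epoch, model: seen.append(epoch),
    )
    assert seen == [1, 2, 3]
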