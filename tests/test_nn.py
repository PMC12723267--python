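"""Layer-level checks: the FFT convolution against the im2col reference,
adjoint (dot-product) identities, and optimizer behaviour."""

import numpy as np
import pytest

from diffdot import nn


def adjoint_gap(layer, xshape, rng):
    """<J dx, w> vs <dx, J^T w> for a (locally) linear layer."""
    x = rng.standard_normal(xshape).astype(np.float32)
    dx = rng.standard_normal(xshape).astype(np.float32)
    y0 = layer.forward(x, True)
    y1 = layer.forward(x + dx, True)
    jdx = (y1 - y0).astype(np.float64)
    w = rng.standard_normal(y0.shape).astype(np.float32)
    layer.forward(x, True)
    for p in layer.params():
        p.grad[...] = 0
    jtw = layer.backward(w).astype(np.float64)
    lhs = (jdx * w).sum()
    rhs = (jtw * dx.astype(np.float64)).sum()
    return abs(lhs - rhs) / abs(lhs)


@pytest.mark.parametrize("kernel", [3, 5])
def test_fft_conv_matches_im2col(kernel, rng):
    fft = nn.Conv2D(rng, kernel, 4, 6)
    ref = nn.Conv2D(rng, kernel, 4, 6, method="im2col")
    ref.w.value[...] = fft.w.value
    ref.b.value[...] = fft.b.value
    x = rng.standard_normal((3, 12, 17, 4)).astype(np.float32)
    y_fft = fft.forward(x, True)
    y_ref = ref.forward(x, True)
    assert np.abs(y_fft - y_ref).max() < 1e-4
    g = rng.standard_normal(y_fft.shape).astype(np.float32)
    for layer in (fft, ref):
        for p in layer.params():
            p.grad[...] = 0
    dx_fft = fft.backward(g)
    dx_ref = ref.backward(g)
    assert np.abs(dx_fft - dx_ref).max() < 1e-4
    scale = np.abs(ref.w.grad).max()
    assert np.abs(fft.w.grad - ref.w.grad).max() < 1e-5 * scale


@pytest.mark.parametrize(
    "make",
    [
        lambda r: nn.Conv2D(r, 5, 3, 4, bias=False),
        lambda r: nn.Conv2D(r, 1, 3, 4, bias=False),
        lambda r: nn.Dense(r, 30, 11),
        lambda r: nn.Sequential(
            [nn.Conv2D(r, 3, 3, 4, bias=False), nn.Conv2D(r, 5, 4, 2, bias=False)]
        ),
    ],
)
def test_linear_layers_satisfy_adjoint_identity(make, rng):
    layer = make(rng)
    shape = (2, 30) if isinstance(layer, nn.Dense) else (2, 10, 10, 3)
    assert adjoint_gap(layer, shape, rng) < 1e-5


def test_maxpool_forward_and_gradient(rng):
    pool = nn.MaxPool3x3()
    x = rng.standard_normal((2, 6, 6, 3)).astype(np.float32)
    y = pool.forward(x, True)
    # each output is the max over the 3x3 neighbourhood
    pad = np.full((2, 8, 8, 3), -np.inf)
    pad[:, 1:7, 1:7, :] = x
    for i in (0, 3, 5):
        for j in (0, 2, 5):
            ref = pad[:, i : i + 3, j : j + 3, :].max(axis=(1, 2))
            assert np.allclose(y[:, i, j, :], ref)
    # gradient routes to the argmax position only
    g = np.ones_like(y)
    gin = pool.backward(g)
    assert gin.sum() == pytest.approx(g.sum())
    assert (gin >= 0).all()


def test_constant_input_maxpool_is_identity(rng):
    pool = nn.MaxPool3x3()
    x = np.full((1, 5, 5, 2), 3.25, dtype=np.float32)
    assert np.allclose(pool.forward(x, True), 3.25)


def test_batchnorm_normalizes_and_tracks_running_stats(rng):
    bn = nn.BatchNorm2D(4, momentum=0.5)
    x = (rng.standard_normal((8, 6, 6, 4)) * 3 + 1).astype(np.float32)
    y = bn.forward(x, training=True)
    assert np.allclose(y.mean(axis=(0, 1, 2)), 0.0, atol=1e-4)
    assert np.allclose(y.std(axis=(0, 1, 2)), 1.0, atol=1e-3)
    for _ in range(30):
        bn.forward(x, training=True)
    y_eval = bn.forward(x, training=False)
    # running stats converge to the batch stats, so eval ~ train output
    assert np.allclose(y_eval, y, atol=1e-2)


def test_batchnorm_backward_matches_numeric(rng):
    bn = nn.BatchNorm2D(2)
    x = rng.standard_normal((3, 4, 4, 2)).astype(np.float64).astype(np.float32)
    w = rng.standard_normal((3, 4, 4, 2)).astype(np.float32)
    bn.forward(x, True)
    gin = bn.backward(w)
    eps = 1e-3
    errs = []
    flat = x.reshape(-1)
    gflat = gin.reshape(-1)
    for j in rng.choice(flat.size, 20, replace=False):
        old = flat[j]
        flat[j] = old + eps
        fp = float((bn.forward(x, True) * w).sum())
        flat[j] = old - eps
        fm = float((bn.forward(x, True) * w).sum())
        flat[j] = old
        num = (fp - fm) / (2 * eps)
        errs.append(abs(num - gflat[j]) / (abs(num) + 1e-3))
    assert max(errs) < 2e-2


def test_channel_attention_gradients_numeric(rng):
    cab = nn.ChannelAttention(rng, 4, 2)
    x = rng.standard_normal((2, 5, 5, 4)).astype(np.float32)
    w = rng.standard_normal((2, 5, 5, 4)).astype(np.float32)
    cab.forward(x, True)
    for p in cab.params():
        p.grad[...] = 0
    cab.backward(w)
    eps = 1e-2  # large enough to clear float32 rounding of the loss sum

    def loss():
        return float((cab.forward(x, True).astype(np.float64) * w).sum())

    for p in cab.params():
        flat = p.value.reshape(-1)
        gflat = p.grad.reshape(-1)
        for j in rng.choice(flat.size, min(6, flat.size), replace=False):
            old = flat[j]
            flat[j] = old + eps
            fp = loss()
            flat[j] = old - eps
            fm = loss()
            flat[j] = old
            num = (fp - fm) / (2 * eps)
            assert abs(num - gflat[j]) / (abs(num) + 1e-2) < 2e-2


def test_adam_minimizes_quadratic():
    target = np.array([1.0, -2.0, 0.5], dtype=np.float32)
    p = nn.Param(np.zeros(3))
    opt = nn.Adam([p], lr=0.05, beta1=0.5)
    for _ in range(500):
        opt.zero_grad()
        p.grad += 2 * (p.value - target)
        opt.step()
    assert np.allclose(p.value, target, atol=1e-3)


def test_count_parameters_closed_form(rng):
    dense = nn.Dense(rng, 480, 4096)
    assert nn.count_parameters(dense) == 480 * 4096 + 4096 == 1_970_176
    conv = nn.Conv2D(rng, 3, 1, 8)
    assert nn.count_parameters(conv) == 9 * 8 + 8 == 80
    seq = nn.Sequential([dense, conv])
    assert nn.count_parameters(seq) == 1_970_176 + 80
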