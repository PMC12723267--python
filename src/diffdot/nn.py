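"""Minimal NHWC neural-network layers with manual backpropagation.

Only what the channel-attention fusion reconstructor needs: dense layers,
2-D convolutions (im2col), batch normalization, ReLU/tanh activations,
3x3 stride-1 max pooling and the Adam optimizer.  Everything is float32
and deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base class; layers cache what backward needs during forward."""

    def params(self):
        return []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, rng, n_in, n_out):
        self.w = Param(glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class Tanh(Layer):
    def forward(self, x, training=False):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class ReLU(Layer):
    def forward(self, x, training=False):
        y = np.maximum(x, 0.0)
        self._mask = y > 0
        return y

    def backward(self, grad):
        return grad * self._mask


class Reshape(Layer):
    def __init__(self, shape_out):
        self.shape_out = shape_out

    def forward(self, x, training=False):
        self._shape_in = x.shape
        return x.reshape((x.shape[0],) + tuple(self.shape_out))

    def backward(self, grad):
        return grad.reshape(self._shape_in)


def _corr_same_freq(xf, wk, fs, h, w):
    """Same-padded correlation given the input's 2-D spectrum.

    ``xf``: (N, C, fs, fs//2+1) rfft2 of the zero-padded NCHW input;
    ``wk``: (k, k, C, F) kernel.  Returns the NHWC result.
    """
    k = wk.shape[0]
    p = k // 2
    wf = sfft.rfft2(wk[::-1, ::-1].transpose(2, 3, 0, 1), s=(fs, fs))
    yf = np.einsum("ncij,cfij->nfij", xf, wf, optimize=True)
    y = sfft.irfft2(yf, s=(fs, fs))
    off = k - 1 - p
    return np.ascontiguousarray(
        y[:, :, off : off + h, off : off + w].transpose(0, 2, 3, 1)
    )


class Conv2D(Layer):
    """Same-padded k x k convolution on NHWC tensors.

    Kernels > 1 run through FFTs (the channel counts here are too small
    for im2col GEMMs to be efficient); 1x1 kernels are plain GEMMs.  The
    ``method`` flag forces the im2col path, kept as an independent
    reference implementation.
    """

    def __init__(self, rng, kernel, c_in, c_out, method="auto", bias=True):
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.method = method
        fan_in = kernel * kernel * c_in
        self.w = Param(
            glorot(rng, (kernel * kernel * c_in, c_out), fan_in, c_out)
        )
        self.b = Param(np.zeros(c_out)) if bias else None

    def params(self):
        return [self.w, self.b] if self.b is not None else [self.w]

    def _use_fft(self):
        return self.kernel > 1 and self.method != "im2col"

    @staticmethod
    def _im2col_of(x, k):
        p = k // 2
        x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(x, (k, k), axis=(1, 2))  # N,H,W,C,k,k
        return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, h, w, _ = x.shape
        self._shape = (n, h, w)
        k = self.kernel
        if self._use_fft():
            fs = sfft.next_fast_len(max(h, w) + k - 1)
            self._fs = fs
            self._xf = sfft.rfft2(x.transpose(0, 3, 1, 2), s=(fs, fs))
            wk = self.w.value.reshape(k, k, self.c_in, self.c_out)
            out = _corr_same_freq(self._xf, wk, fs, h, w)
            if self.b is not None:
                out += self.b.value
            return out
        if k == 1:
            col = x.reshape(-1, self.c_in)
        else:
            col = self._im2col_of(x, k).reshape(n * h * w, -1)
        self._col = col
        out = col @ self.w.value
        if self.b is not None:
            out += self.b.value
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad):
        n, h, w = self._shape
        k = self.kernel
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        if self.b is not None:
            self.b.grad += grad.reshape(-1, self.c_out).sum(axis=0)
        if self._use_fft():
            fs = self._fs
            gf = sfft.rfft2(grad.transpose(0, 3, 1, 2), s=(fs, fs))
            # weight gradient: correlation of input with grad at the k x k
            # displacements around zero (negative lags wrap around)
            cf = np.einsum("ncij,nfij->cfij", self._xf, np.conj(gf), optimize=True)
            cc = sfft.irfft2(cf, s=(fs, fs))
            p = k // 2
            lags = (np.arange(k) - p) % fs
            dwk = cc[:, :, lags[:, None], lags[None, :]]  # C,F,k,k
            self.w.grad += dwk.transpose(2, 3, 0, 1).reshape(
                k * k * self.c_in, self.c_out
            )
            # input gradient: correlation with the flipped, transposed kernel
            wk = self.w.value.reshape(k, k, self.c_in, self.c_out)
            wback = wk[::-1, ::-1].transpose(0, 1, 3, 2)
            return _corr_same_freq(gf, wback, fs, h, w)
        gflat = grad.reshape(n * h * w, self.c_out)
        self.w.grad += self._col.T @ gflat
        if k == 1:
            return (gflat @ self.w.value.T).reshape(n, h, w, self.c_in)
        wk = self.w.value.reshape(k, k, self.c_in, self.c_out)
        wk_flip = wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(
            k * k * self.c_out, self.c_in
        )
        gcol = self._im2col_of(grad, k).reshape(n * h * w, -1)
        return (gcol @ np.ascontiguousarray(wk_flip)).reshape(
            n, h, w, self.c_in
        )


class BatchNorm2D(Layer):
    """Channelwise batch normalization over (N, H, W)."""

    def __init__(self, channels, momentum=0.99, eps=1e-5, enabled=True):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.enabled = enabled

    def params(self):
        return [self.gamma, self.beta] if self.enabled else []

    def forward(self, x, training=False):
        if not self.enabled:
            return x
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = np.einsum(
                "nhwc,nhwc->c", x, x, optimize=True
            ) / (x.shape[0] * x.shape[1] * x.shape[2]) - mean**2
            var = np.maximum(var, 0.0)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        if not self.enabled:
            return grad
        xhat = self._xhat
        s1 = np.einsum("nhwc->c", grad, optimize=True)
        s2 = np.einsum("nhwc,nhwc->c", grad, xhat, optimize=True)
        self.beta.grad += s1
        self.gamma.grad += s2
        scale = self.gamma.value / self._std
        if not self._training:
            return grad * scale
        m = grad.shape[0] * grad.shape[1] * grad.shape[2]
        return scale * (grad - s1 / m - xhat * (s2 / m))


class MaxPool3x3(Layer):
    """3x3, stride-1, same-padded spatial max pooling."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        pad = np.full((n, h + 2, w + 2, c), -np.inf, dtype=np.float32)
        pad[:, 1 : 1 + h, 1 : 1 + w, :] = x
        out = pad[:, 0:h, 0:w, :].copy()
        arg = np.zeros((n, h, w, c), dtype=np.int8)
        for t in range(1, 9):
            ki, kj = divmod(t, 3)
            cand = pad[:, ki : ki + h, kj : kj + w, :]
            better = cand > out
            np.maximum(out, cand, out=out)
            arg = np.where(better, np.int8(t), arg)
        self._arg = arg
        self._pad_shape = (n, h + 2, w + 2, c)
        return out

    def backward(self, grad):
        n, hp, wp, c = self._pad_shape
        h, w = hp - 2, wp - 2
        dpad = np.zeros(self._pad_shape, dtype=np.float32)
        for t in range(9):
            ki, kj = divmod(t, 3)
            mask = self._arg == t
            if mask.any():
                dpad[:, ki : ki + h, kj : kj + w, :] += np.where(mask, grad, 0.0)
        return dpad[:, 1 : 1 + h, 1 : 1 + w, :]


class ChannelAttention(Layer):
    """Squeeze-style channel gate from pooled summaries.

    Per channel, the spatial mean (GAP) and maximum (GMP) are added and
    passed through a shared two-layer MLP (C -> C/ratio -> C, ReLU between
    the layers); a sigmoid yields a weight in (0, 1) that rescales the
    channel.  Averaging over the H x W extent suppresses the variance of
    i.i.d. pixel noise by a factor H*W.
    """

    def __init__(self, rng, channels, reduction_ratio=4):
        if channels % reduction_ratio:
            raise ValueError(
                f"reduction ratio {reduction_ratio} does not divide "
                f"{channels} channels"
            )
        hidden = channels // reduction_ratio
        self.w1 = Param(glorot(rng, (channels, hidden), channels, hidden))
        self.b1 = Param(np.zeros(hidden))
        self.w2 = Param(glorot(rng, (hidden, channels), hidden, channels))
        # open-gate initialization (sigmoid(2) ~ 0.88): the block starts
        # close to pass-through and learns to close gates, instead of
        # halving every feature map from step one
        self.b2 = Param(np.full(channels, 2.0))
        self.last_weights = None

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def summaries(self, x):
        n, h, w, c = x.shape
        z_avg = x.mean(axis=(1, 2))
        flat = x.reshape(n, h * w, c)
        arg = flat.argmax(axis=1)
        z_max = np.take_along_axis(flat, arg[:, None, :], axis=1)[:, 0, :]
        return z_avg, z_max, arg

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        z_avg, z_max, arg = self.summaries(x)
        z = z_avg + z_max
        h1 = z @ self.w1.value + self.b1.value
        h1r = np.maximum(h1, 0.0)
        logits = h1r @ self.w2.value + self.b2.value
        wgt = 1.0 / (1.0 + np.exp(-logits))
        self._cache = (x, z, h1, h1r, wgt, arg)
        self.last_weights = wgt
        return x * wgt[:, None, None, :]

    def backward(self, grad):
        x, z, h1, h1r, wgt, arg = self._cache
        n, h, w, c = x.shape
        dx = grad * wgt[:, None, None, :]
        dw = (grad * x).sum(axis=(1, 2))
        dlogits = dw * wgt * (1.0 - wgt)
        self.w2.grad += h1r.T @ dlogits
        self.b2.grad += dlogits.sum(axis=0)
        dh1 = (dlogits @ self.w2.value.T) * (h1 > 0)
        self.w1.grad += z.T @ dh1
        self.b1.grad += dh1.sum(axis=0)
        dz = dh1 @ self.w1.value.T
        dx += dz[:, None, None, :] / (h * w)
        dflat = np.zeros((n, h * w, c), dtype=np.float32)
        np.put_along_axis(dflat, arg[:, None, :], dz[:, None, :], axis=1)
        return dx + dflat.reshape(n, h, w, c)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Parallel(Layer):
    """Apply branches to one input and concatenate along channels."""

    def __init__(self, branches):
        self.branches = list(branches)

    def params(self):
        out = []
        for branch in self.branches:
            out.extend(branch.params())
        return out

    def forward(self, x, training=False):
        outs = [b.forward(x, training) for b in self.branches]
        self._widths = [o.shape[-1] for o in outs]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        splits = np.cumsum(self._widths)[:-1]
        parts = np.split(grad, splits, axis=-1)
        total = None
        for branch, part in zip(self.branches, parts):
            g = branch.backward(np.ascontiguousarray(part))
            total = g if total is None else total + g
        return total


class Adam:
    """Adam with configurable beta1 (0.5 for this reconstruction task)."""

    def __init__(self, params, lr=1e-3, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def count_parameters(layer: Layer) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.value.size for p in layer.params()))
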