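"""Minimal numpy CNN engine backing the UNet segmentation model.

Implements exactly the layers the encoder-decoder needs — 3x3 same-padding
convolution, ReLU, 2x2 max pooling, nearest-neighbour 2x upsampling, channel
concatenation, inverted dropout, 1x1 convolution, sigmoid — each with a
hand-written backward pass, plus the Adam optimizer.  Arrays are NCHW
float32; convolutions are evaluated as nine shifted tensor contractions,
which keeps everything inside BLAS-backed numpy calls.

The backward passes are validated against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "Adam", "soft_dice_loss_and_grad"]


def conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (N,C,H,W), W (O,C,3,3), b (O,) -> out (N,O,H,W), cache."""
    N, C, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.broadcast_to(b[None, :, None, None], (N, W.shape[0], H, Wd)).copy()
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy : dy + H, dx : dx + Wd]
            out += np.tensordot(patch, W[:, :, dy, dx], axes=([1], [1])).transpose(0, 3, 1, 2)
    return out, (xp, W, x.shape)


def conv3x3_backward(dout: np.ndarray, cache):
    xp, W, xshape = cache
    N, C, H, Wd = xshape
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    db = dout.sum(axis=(0, 2, 3))
    for dy in range(3):
        for dx in range(3):
            patch = xp[:, :, dy : dy + H, dx : dx + Wd]
            dW[:, :, dy, dx] = np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
            dxp[:, :, dy : dy + H, dx : dx + Wd] += np.tensordot(
                dout, W[:, :, dy, dx], axes=([1], [0])
            ).transpose(0, 3, 1, 2)
    return dxp[:, :, 1 : H + 1, 1 : Wd + 1], dW, db


def conv1x1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (N,C,H,W), W (O,C), b (O,)."""
    out = np.tensordot(x, W, axes=([1], [1])).transpose(0, 3, 1, 2) + b[None, :, None, None]
    return out, (x, W)


def conv1x1_backward(dout: np.ndarray, cache):
    x, W = cache
    dW = np.tensordot(dout, x, axes=([0, 2, 3], [0, 2, 3]))
    db = dout.sum(axis=(0, 2, 3))
    dx = np.tensordot(dout, W, axes=([1], [0])).transpose(0, 3, 1, 2)
    return dx, dW, db


def relu_forward(x: np.ndarray):
    pos = x > 0
    return x * pos, pos


def relu_backward(dout: np.ndarray, pos: np.ndarray):
    return dout * pos


def maxpool2_forward(x: np.ndarray):
    """2x2 max pool, stride 2; H and W must be even."""
    N, C, H, W = x.shape
    win = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        N, C, H // 2, W // 2, 4
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, xshape = cache
    N, C, H, W = xshape
    dwin = np.zeros((N, C, H // 2, W // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    return dwin.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(xshape)


def upsample2_forward(x: np.ndarray):
    """Nearest-neighbour 2x upsampling."""
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray):
    N, C, H, W = dout.shape
    return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when rng is None (inference)."""
    if rng is None or rate <= 0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


def dropout_backward(dout: np.ndarray, keep):
    return dout if keep is None else dout * keep


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def soft_dice_loss_and_grad(p: np.ndarray, t: np.ndarray, smoothing: float):
    """Soft Dice loss over a batch and its gradient with respect to ``p``.

    loss = 1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s), sums over the whole
    batch; probabilities generalise the hard-set intersection.
    """
    p64 = p.astype(np.float64)
    t64 = t.astype(np.float64)
    inter = float((p64 * t64).sum())
    num = 2.0 * inter + smoothing
    den = float(p64.sum() + t64.sum()) + smoothing
    loss = 1.0 - num / den
    grad = -((2.0 * t64 * den - num) / den**2)
    return loss, grad.astype(p.dtype)


class _ConvBlock:
    """Two 3x3 conv + ReLU stages at one resolution level."""

    def __init__(self, name: str, c_in: int, c_out: int):
        self.name = name
        self.c_in, self.c_out = c_in, c_out

    def init_params(self, params: dict, rng: np.random.Generator) -> None:
        for j, (ci, co) in enumerate([(self.c_in, self.c_out), (self.c_out, self.c_out)]):
            scale = np.sqrt(2.0 / (ci * 9))
            params[f"{self.name}_W{j}"] = (rng.standard_normal((co, ci, 3, 3)) * scale).astype(
                np.float32
            )
            params[f"{self.name}_b{j}"] = np.zeros(co, dtype=np.float32)

    def forward(self, x, params):
        caches = []
        for j in range(2):
            x, c_conv = conv3x3_forward(x, params[f"{self.name}_W{j}"], params[f"{self.name}_b{j}"])
            x, c_relu = relu_forward(x)
            caches.append((c_conv, c_relu))
        return x, caches

    def backward(self, dout, caches, grads):
        for j in (1, 0):
            c_conv, c_relu = caches[j]
            dout = relu_backward(dout, c_relu)
            dout, dW, db = conv3x3_backward(dout, c_conv)
            grads[f"{self.name}_W{j}"] = dW
            grads[f"{self.name}_b{j}"] = db
        return dout


class UNet:
    """Encoder-decoder segmentation network with skip connections.

    ``depth`` resolution levels with channel doubling per level
    (``base_channels * 2**level``); each level is two 3x3 convolutions with
    ReLU; 2x2 max pooling down, nearest-neighbour upsampling followed by skip
    concatenation up; inverted dropout before a final 1x1 convolution and
    sigmoid producing a single-channel probability map.  ``depth=1`` is the
    degenerate no-pooling convolutional stack.

    Input spatial dimensions must be divisible by ``2**(depth-1)``.
    """

    def __init__(
        self,
        depth: int,
        base_channels: int = 8,
        in_channels: int = 1,
        dropout_rate: float = 0.5,
        seed: int = 0,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.depth = depth
        self.base_channels = base_channels
        self.in_channels = in_channels
        self.dropout_rate = float(dropout_rate)
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)

        ch = [base_channels * 2**i for i in range(depth)]
        self.enc = [_ConvBlock(f"enc{i}", in_channels if i == 0 else ch[i - 1], ch[i]) for i in range(depth - 1)]
        bot_in = in_channels if depth == 1 else ch[depth - 2]
        self.bottleneck = _ConvBlock("bot", bot_in, ch[depth - 1])
        self.dec = [_ConvBlock(f"dec{i}", ch[i] + ch[i + 1], ch[i]) for i in range(depth - 2, -1, -1)]
        for block in [*self.enc, self.bottleneck, *self.dec]:
            block.init_params(self.params, rng)
        scale = np.sqrt(2.0 / ch[0])
        self.params["out_W"] = (rng.standard_normal((1, ch[0])) * scale).astype(np.float32)
        self.params["out_b"] = np.zeros(1, dtype=np.float32)

    def check_input(self, shape: tuple[int, ...]) -> None:
        div = 2 ** (self.depth - 1)
        h, w = shape[-2], shape[-1]
        if h % div or w % div:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by {div} for depth "
                f"{self.depth}; pad to {-(-h // div) * div}x{-(-w // div) * div}"
            )

    def forward(self, x: np.ndarray, train: bool = False, drop_rng: np.random.Generator | None = None):
        """Return (probability map (N,1,H,W), cache for backward)."""
        self.check_input(x.shape)
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips, enc_caches, pool_caches = [], [], []
        for block in self.enc:
            x, c = block.forward(x, self.params)
            enc_caches.append(c)
            skips.append(x)
            x, pc = maxpool2_forward(x)
            pool_caches.append(pc)
        x, bot_cache = self.bottleneck.forward(x, self.params)
        dec_caches, concat_channels = [], []
        for block, skip in zip(self.dec, reversed(skips)):
            x = upsample2_forward(x)
            concat_channels.append((skip.shape[1], x.shape[1]))
            x = np.concatenate([skip, x], axis=1)
            x, c = block.forward(x, self.params)
            dec_caches.append(c)
        x, drop_keep = dropout_forward(x, self.dropout_rate, drop_rng if train else None)
        z, out_cache = conv1x1_forward(x, self.params["out_W"], self.params["out_b"])
        p = sigmoid(z)
        cache = (enc_caches, pool_caches, bot_cache, dec_caches, concat_channels, drop_keep, out_cache, p)
        return p, cache

    def backward(self, cache, dp: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given dL/dp (p the sigmoid output)."""
        enc_caches, pool_caches, bot_cache, dec_caches, concat_channels, drop_keep, out_cache, p = cache
        grads: dict[str, np.ndarray] = {}
        dz = (dp * p * (1.0 - p)).astype(np.float32)
        dx, grads["out_W"], grads["out_b"] = conv1x1_backward(dz, out_cache)
        dx = dropout_backward(dx, drop_keep)
        dskips = []
        for block, c, (c_skip, _) in zip(reversed(self.dec), reversed(dec_caches), reversed(concat_channels)):
            dcat = block.backward(dx, c, grads)
            dskips.append(dcat[:, :c_skip])
            dx = upsample2_backward(dcat[:, c_skip:])
        dx = self.bottleneck.backward(dx, bot_cache, grads)
        for block, c, pc, dskip in zip(
            reversed(self.enc), reversed(enc_caches), reversed(pool_caches), reversed(dskips)
        ):
            dx = maxpool2_backward(dx, pc)
            dx = dx + dskip
            dx = block.backward(dx, c, grads)
        return grads

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)


class Adam:
    """Adaptive-moment optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
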