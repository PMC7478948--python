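"""Minimal CPU neural-network core for 2D patch segmentation.

Implements exactly what the residual U-shaped segmentation network
needs: 2D convolutions via im2col, ReLU, 2x2 max pooling, nearest
up-sampling, residual blocks, sigmoid/binary-cross-entropy, and Adam.
Forward passes cache what backward needs; forward/backward alternate
strictly, one batch at a time.

Arrays are (N, C, H, W) float32 throughout.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def _conv_fwd(xp, Wt, b, h_out, w_out):
    n_b, c_in = xp.shape[0], xp.shape[1]
    k = Wt.shape[1]
    c_out = Wt.shape[3]
    out = np.empty((n_b, c_out, h_out, w_out), dtype=np.float32)
    for n in range(n_b):
        for f in range(c_out):
            for h in range(h_out):
                row = out[n, f, h]
                row[:] = b[f]
                for c in range(c_in):
                    for i in range(k):
                        src = xp[n, c, h + i]
                        for j in range(k):
                            wv = Wt[c, i, j, f]
                            for w in range(w_out):
                                row[w] += wv * src[w + j]
    return out


@njit(fastmath=True, cache=True)
def _conv_bwd(xp, g, Wt):
    n_b, c_in = xp.shape[0], xp.shape[1]
    k = Wt.shape[1]
    c_out, h_out, w_out = g.shape[1], g.shape[2], g.shape[3]
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(Wt)
    db = np.zeros(c_out, dtype=np.float32)
    for n in range(n_b):
        for f in range(c_out):
            for h in range(h_out):
                grow = g[n, f, h]
                db[f] += grow.sum()
                for c in range(c_in):
                    for i in range(k):
                        dst = dxp[n, c, h + i]
                        src = xp[n, c, h + i]
                        for j in range(k):
                            wv = Wt[c, i, j, f]
                            acc = np.float32(0.0)
                            for w in range(w_out):
                                dst[w + j] += wv * grow[w]
                                acc += src[w + j] * grow[w]
                            dW[c, i, j, f] += acc
    return dxp, dW, db


class Conv2D:
    """k x k 'same' convolution with JIT-compiled inner loops.

    Weights (C_in, k, k, C_out), He init.  At the widths this network
    uses, fused scalar loops beat BLAS-backed im2col on one CPU.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_in, k, k, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        n, c, h, w = x.shape
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        out = _conv_fwd(xp, self.W, self.b, h, w)
        self._xp = xp
        self._hw = (h, w)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        pad = self.k // 2
        h, w = self._hw
        g = np.ascontiguousarray(g, dtype=np.float32)
        dxp, self.dW, self.db = _conv_bwd(self._xp, g, self.W)
        self._xp = None
        return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2:
    """2x2 max pooling; H and W must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, g):
        n, c, h, w = self._shape
        gr = g[:, :, :, None, :, None] * self._mask
        return gr.reshape(n, c, h, w)


class Up2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, g):
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ResBlock:
    """y = relu(x + conv(relu(conv(x)))), channel-preserving."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2D(channels, channels, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(channels, channels, 3, rng)
        self.relu_out = ReLU()

    def forward(self, x):
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu_out.forward(x + h)

    def backward(self, g):
        g0 = self.relu_out.backward(g)
        gb = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(g0)))
        return g0 + gb

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class UResNet2D:
    """Residual encoder-decoder over 2D patches, one logit per pixel.

    ``depth`` resolution levels with ``base_channels * 2**level``
    channels; ``blocks_per_level`` residual blocks at each level; skip
    connections added (not concatenated) across the U.
    """

    def __init__(self, depth: int = 3, base_channels: int = 8,
                 blocks_per_level: int = 1, seed: int = 0):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        rng = np.random.default_rng(seed)
        self.depth = depth
        ch = [base_channels * 2 ** l for l in range(depth)]
        self.stem = Conv2D(1, ch[0], 3, rng)
        self.stem_relu = ReLU()
        self.enc_blocks = [[ResBlock(ch[l], rng)
                            for _ in range(blocks_per_level)]
                           for l in range(depth - 1)]
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.down_convs = [Conv2D(ch[l], ch[l + 1], 3, rng)
                           for l in range(depth - 1)]
        self.down_relus = [ReLU() for _ in range(depth - 1)]
        self.bottleneck = [ResBlock(ch[-1], rng)
                           for _ in range(blocks_per_level)]
        self.ups = [Up2() for _ in range(depth - 1)]
        self.up_convs = [Conv2D(ch[l + 1], ch[l], 3, rng)
                         for l in range(depth - 1)]
        self.up_relus = [ReLU() for _ in range(depth - 1)]
        self.dec_blocks = [[ResBlock(ch[l], rng)
                            for _ in range(blocks_per_level)]
                           for l in range(depth - 1)]
        self.head = Conv2D(ch[0], 1, 1, rng)

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        mods = [self.stem]
        for blocks in self.enc_blocks:
            mods += blocks
        mods += self.down_convs + self.bottleneck + self.up_convs
        for blocks in self.dec_blocks:
            mods += blocks
        mods.append(self.head)
        return mods

    def parameters(self):
        out = []
        for m in self._modules():
            out += m.parameters()
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for (p, _), w in zip(params, weights):
            p[...] = w

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        step = 2 ** (self.depth - 1)
        if h % step or w % step:
            raise ValueError(f"input H,W must be multiples of {step}")
        h_ = self.stem_relu.forward(self.stem.forward(x))
        skips = []
        for l in range(self.depth - 1):
            for blk in self.enc_blocks[l]:
                h_ = blk.forward(h_)
            skips.append(h_)
            h_ = self.pools[l].forward(h_)
            h_ = self.down_relus[l].forward(self.down_convs[l].forward(h_))
        for blk in self.bottleneck:
            h_ = blk.forward(h_)
        for l in reversed(range(self.depth - 1)):
            h_ = self.ups[l].forward(h_)
            h_ = self.up_relus[l].forward(self.up_convs[l].forward(h_))
            h_ = h_ + skips[l]
            for blk in self.dec_blocks[l]:
                h_ = blk.forward(h_)
        return self.head.forward(h_)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        skip_grads = [None] * (self.depth - 1)
        for l in range(self.depth - 1):
            for blk in reversed(self.dec_blocks[l]):
                g = blk.backward(g)
            skip_grads[l] = g
            g = self.up_convs[l].backward(self.up_relus[l].backward(g))
            g = self.ups[l].backward(g)
        for blk in reversed(self.bottleneck):
            g = blk.backward(g)
        for l in reversed(range(self.depth - 1)):
            g = self.down_convs[l].backward(self.down_relus[l].backward(g))
            g = self.pools[l].backward(g)
            g = g + skip_grads[l]
            for blk in reversed(self.enc_blocks[l]):
                g = blk.backward(g)
        self.stem.backward(self.stem_relu.backward(g))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def bce_with_logits(logits: np.ndarray,
                    targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient wrt the logits."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(logits) - targets.astype(np.float32)) / logits.size
    return float(loss.mean()), grad.astype(np.float32)


class Adam:
    def __init__(self, net: UResNet2D, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.net.parameters()):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
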