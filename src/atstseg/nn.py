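"""A small U-Net implemented directly in NumPy, with explicit backpropagation.

The backbone is the classic contracting/expanding encoder-decoder: repeated
3x3 conv + ReLU pairs, 2x2 max-pooling on the way down, nearest-neighbour
upsampling with skip concatenation on the way up, and a 1x1 sigmoid head
producing a single foreground-probability channel.  Both training branches
share this architecture.

Data layout is NHWC (batch, height, width, channels) in float32.
Convolutions are lowered to a single matrix product per layer (im2col), and
the column matrices built on the forward pass are reused for the weight
gradients, which keeps the whole step inside BLAS and fast enough for
desk-scale slice sizes on one CPU.  All randomness comes from an explicit
``numpy.random.Generator``, so initialisation and training are bit-for-bit
reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg.blas import sgemm

__all__ = ["BackboneConfig", "UNet", "SGD", "build_backbone"]


def _gemm_acc(out: np.ndarray, a: np.ndarray, b: np.ndarray) -> None:
    """out += a @ b without a temporary.

    ``out`` (m, n) and ``a`` (m, k) must be C-contiguous, ``b`` (k, n) a
    C-contiguous array or a transpose view; computed as the equivalent
    Fortran-order product out.T = b.T @ a.T with BLAS beta = 1.
    """
    sgemm(1.0, b.T, a.T, beta=1.0, c=out.T, overwrite_c=True)


@dataclass(frozen=True)
class BackboneConfig:
    """U-Net shape: input side length, first-level width, number of poolings.

    ``norm="group"`` inserts group normalisation between every convolution
    and its ReLU (4 channels per group, fewer if the layer is narrower),
    which stabilises small-batch training; ``norm="none"`` gives the plain
    conv-ReLU backbone.
    """

    side: int = 64
    base_width: int = 8
    depth: int = 3
    in_channels: int = 1
    norm: str = "group"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.side % (2 ** self.depth) != 0:
            raise ValueError(f"side {self.side} not divisible by 2^{self.depth}")
        if self.norm not in ("group", "none"):
            raise ValueError(f"unknown norm: {self.norm}")


def _norm_groups(c: int) -> int:
    g = min(4, c)
    while c % g:
        g -= 1
    return g


def _conv3_forward(x: np.ndarray, w2: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution as nine shifted contiguous GEMMs.

    On the zero-padded NHWC array each kernel offset is a constant shift in
    flat index space, so every offset contributes one fully contiguous
    matrix product — no patch gather is ever built.  Values accumulated in
    the padding fringe are cropped away.  ``w2`` is the (9*Cin, Cout) kernel
    matrix (rows ordered offset-major); returns ``(z, xp)`` where ``xp`` is
    the padded input kept for the backward pass.
    """
    n, h, w, c = x.shape
    cout = w2.shape[1]
    W = w2.reshape(3, 3, c, cout)
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    m = n * (h + 2) * (w + 2)
    x2 = xp.reshape(m, c)
    y = np.zeros((m, cout), dtype=np.float32)
    wp = w + 2
    for i in range(3):
        for j in range(3):
            shift = (i - 1) * wp + (j - 1)
            lo = max(0, -shift)
            hi = m - max(0, shift)
            _gemm_acc(y[lo:hi], x2[lo + shift:hi + shift], W[i, j])
    z = y.reshape(n, h + 2, w + 2, cout)[:, 1:-1, 1:-1, :] + b
    return z, xp


def _conv3_backward(xp: np.ndarray, w2: np.ndarray, dz: np.ndarray,
                    need_dx: bool = True):
    """Gradients of :func:`_conv3_forward` w.r.t. input, kernel and bias.

    ``need_dx=False`` skips the input gradient (for the first layer).
    """
    n, hp, wp, c = xp.shape
    h, w = hp - 2, wp - 2
    cout = w2.shape[1]
    W = w2.reshape(3, 3, c, cout)
    m = n * hp * wp
    x2 = xp.reshape(m, c)
    dzp = np.zeros((n, hp, wp, cout), dtype=np.float32)
    dzp[:, 1:-1, 1:-1, :] = dz
    dz2 = dzp.reshape(m, cout)
    dx2 = np.zeros((m, c), dtype=np.float32) if need_dx else None
    dw = np.empty_like(w2)
    for i in range(3):
        for j in range(3):
            shift = (i - 1) * wp + (j - 1)
            lo = max(0, -shift)
            hi = m - max(0, shift)
            if need_dx:
                _gemm_acc(dx2[lo + shift:hi + shift], dz2[lo:hi], W[i, j].T)
            dw[(3 * i + j) * c:(3 * i + j + 1) * c] = (
                x2[lo + shift:hi + shift].T @ dz2[lo:hi])
    db = dz2.sum(axis=0)
    dx = dx2.reshape(n, hp, wp, c)[:, 1:-1, 1:-1, :] if need_dx else None
    return dx, dw, db


GN_EPS = 1e-5


def _groupnorm_forward(z: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                       groups: int):
    """Group normalisation over (H, W, channels-per-group), per sample.

    Moment reductions go through fused einsum calls, which on strided
    group-reshaped views are considerably faster than ufunc reductions.
    """
    n, h, w, c = z.shape
    g = groups
    zg = z.reshape(n, h, w, g, c // g)
    m = h * w * (c // g)
    s1 = np.einsum("nhwgc->ng", zg, optimize=True)
    s2 = np.einsum("nhwgc,nhwgc->ng", zg, zg, optimize=True)
    mean = s1 / m
    var = s2 / m - mean * mean
    inv_std = (1.0 / np.sqrt(var + GN_EPS)).astype(np.float32)
    mb = mean.astype(np.float32)[:, None, None, :, None]
    ib = inv_std[:, None, None, :, None]
    y = zg - mb
    y *= ib
    y = y.reshape(n, h, w, c)
    out = y * gamma
    out += beta
    return out, y, inv_std


def _groupnorm_backward(dout: np.ndarray, y: np.ndarray, inv_std: np.ndarray,
                        gamma: np.ndarray, groups: int):
    n, h, w, c = dout.shape
    g = groups
    cg = c // g
    dgamma = np.einsum("nhwc,nhwc->c", dout, y, optimize=True)
    dbeta = np.einsum("nhwc->c", dout, optimize=True)
    dy = (dout * gamma).reshape(n, h, w, g, cg)
    yg = y.reshape(n, h, w, g, cg)
    m = h * w * cg
    m1 = (np.einsum("nhwgc->ng", dy, optimize=True) / m).astype(np.float32)
    m2 = (np.einsum("nhwgc,nhwgc->ng", dy, yg, optimize=True) / m).astype(np.float32)
    dy -= m1[:, None, None, :, None]
    dy -= yg * m2[:, None, None, :, None]
    dy *= inv_std[:, None, None, :, None]
    return (dy.reshape(n, h, w, c), dgamma.astype(np.float32),
            dbeta.astype(np.float32))


def _maxpool_forward(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    flat = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, c, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool_backward(dy: np.ndarray, idx: np.ndarray, in_shape):
    n, h, w, c = in_shape
    dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
    np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
    dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return np.ascontiguousarray(dx).reshape(n, h, w, c)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, h, w, c = dy.shape
    return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class UNet:
    """Encoder-decoder segmentation network with a sigmoid foreground head.

    Parameters live in ``self.params``, an ordered list of float32 arrays
    (alternating 3x3 kernels stored as (9*Cin, Cout) matrices and biases;
    the head kernel is (Cin, 1)).  ``get_weights``/``set_weights`` expose
    them as a flat list for EMA blending and checkpointing.
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.use_norm = cfg.norm == "group"
        self.params: list[np.ndarray] = []

        def add_conv(cin: int, cout: int, k: int = 3) -> None:
            fan_in = k * k * cin
            std = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, size=(fan_in, cout)).astype(np.float32)
            self.params.append(w)
            self.params.append(np.zeros(cout, dtype=np.float32))
            if self.use_norm and k == 3:  # affine group-norm parameters
                self.params.append(np.ones(cout, dtype=np.float32))
                self.params.append(np.zeros(cout, dtype=np.float32))

        d, bw = cfg.depth, cfg.base_width
        widths = [bw * 2 ** k for k in range(d + 1)]
        cin = cfg.in_channels
        for k in range(d):  # encoder
            add_conv(cin, widths[k]); add_conv(widths[k], widths[k])
            cin = widths[k]
        add_conv(cin, widths[d]); add_conv(widths[d], widths[d])  # bottleneck
        cin = widths[d]
        for k in reversed(range(d)):  # decoder (after skip concat)
            add_conv(cin + widths[k], widths[k]); add_conv(widths[k], widths[k])
            cin = widths[k]
        add_conv(cin, 1, k=1)  # head

    # ---- weight access -------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, want_grad: bool = False):
        """x: (N, H, W) or (N, H, W, C) in [0, 1] -> probabilities (N, H, W).

        With ``want_grad`` a cache is returned for :meth:`backward`.
        """
        if x.ndim == 3:
            x = x[..., None]
        x = np.ascontiguousarray(x, dtype=np.float32)
        d = self.cfg.depth
        pi = 0  # param index
        step = 4 if self.use_norm else 2
        cache: dict = {"xps": [], "relu": [], "gn": [], "pool": [],
                       "concat_split": []}
        skips = []

        def conv_relu(h):
            nonlocal pi
            w, b = self.params[pi], self.params[pi + 1]
            z, xp = _conv3_forward(h, w, b)
            if self.use_norm:
                gamma, beta = self.params[pi + 2], self.params[pi + 3]
                z, y, inv_std = _groupnorm_forward(z, gamma, beta,
                                                   _norm_groups(w.shape[1]))
                if want_grad:
                    cache["gn"].append((y, inv_std))
            pi += step
            r = z > 0
            if want_grad:
                cache["xps"].append(xp)
                cache["relu"].append(r)
            np.maximum(z, np.float32(0.0), out=z)
            return z

        h = x
        for _ in range(d):
            h = conv_relu(h); h = conv_relu(h)
            skips.append(h)
            h, idx = _maxpool_forward(h)
            if want_grad:
                cache["pool"].append((idx, skips[-1].shape))
        h = conv_relu(h); h = conv_relu(h)
        for k in reversed(range(d)):
            h = _upsample2(h)
            up_c = h.shape[-1]
            h = np.concatenate([h, skips[k]], axis=-1)
            if want_grad:
                cache["concat_split"].append(up_c)
            h = conv_relu(h); h = conv_relu(h)
        # 1x1 head
        w, b = self.params[pi], self.params[pi + 1]
        z = (h @ w) + b
        if want_grad:
            cache["head_in"] = h
        # clip logits: avoids exp overflow, saturation is far beyond EPS_P anyway
        zc = np.clip(z[..., 0].astype(np.float64), -60.0, 60.0)
        probs = 1.0 / (1.0 + np.exp(-zc))
        if want_grad:
            cache["probs"] = probs
            return probs, cache
        return probs

    def backward(self, cache: dict, grad: np.ndarray,
                 wrt: str = "probs") -> list[np.ndarray]:
        """Gradient of a scalar loss w.r.t. every parameter.

        ``grad`` has shape (N, H, W): dLoss/dprobabilities (``wrt="probs"``,
        chained through the sigmoid here) or dLoss/dlogits
        (``wrt="logits"``).  Returns a list aligned with ``self.params``.
        """
        d = self.cfg.depth
        grads: list[np.ndarray] = [None] * len(self.params)  # type: ignore[list-item]
        probs = cache["probs"]
        if wrt == "probs":
            dz = (grad * probs * (1.0 - probs)).astype(np.float32)[..., None]
        elif wrt == "logits":
            dz = np.asarray(grad, dtype=np.float32)[..., None]
        else:
            raise ValueError(f"unknown wrt: {wrt}")

        xps = cache["xps"]
        relu = cache["relu"]
        step = 4 if self.use_norm else 2
        ci = len(xps) - 1
        ri = len(relu) - 1
        pi = len(self.params) - 2

        # head (1x1)
        h_in = cache["head_in"]
        w = self.params[pi]
        dz_mat = dz.reshape(-1, 1)
        grads[pi] = h_in.reshape(-1, h_in.shape[-1]).T @ dz_mat
        grads[pi + 1] = dz_mat.sum(axis=0)
        dh = dz @ w.T
        pi -= step

        def conv_relu_back(dh):
            nonlocal ci, ri, pi
            dzl = np.where(relu[ri], dh, np.float32(0.0))
            ri -= 1
            if self.use_norm:
                gamma = self.params[pi + 2]
                y, inv_std = cache["gn"][ci]
                dzl, dgamma, dbeta = _groupnorm_backward(
                    dzl, y, inv_std, gamma, _norm_groups(gamma.shape[0]))
                grads[pi + 2] = dgamma
                grads[pi + 3] = dbeta
            xp = xps[ci]; ci -= 1
            dx, dw, db = _conv3_backward(xp, self.params[pi], dzl,
                                         need_dx=pi > 0)
            grads[pi] = dw
            grads[pi + 1] = db
            pi -= step
            return dx

        dskips = [None] * d
        for k in range(d):  # decoder blocks, reverse build order (level k)
            dh = conv_relu_back(dh)
            dh = conv_relu_back(dh)
            up_c = cache["concat_split"][d - 1 - k]
            dskips[k] = dh[..., up_c:]
            dh = _upsample2_backward(dh[..., :up_c])
        dh = conv_relu_back(dh)  # bottleneck
        dh = conv_relu_back(dh)
        for k in reversed(range(d)):  # encoder blocks in reverse
            idx, in_shape = cache["pool"][k]
            dh = _maxpool_backward(dh, idx, in_shape)
            dh = dh + dskips[k]
            dh = conv_relu_back(dh)
            dh = conv_relu_back(dh)
        return grads


class SGD:
    """Plain stochastic gradient descent with momentum."""

    def __init__(self, params: list[np.ndarray], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        for p, g, v in zip(self.params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g.astype(p.dtype).reshape(p.shape)
            p += v


def build_backbone(cfg: BackboneConfig, seed: int | np.random.SeedSequence) -> UNet:
    """Deterministically initialised U-Net; same seed, bitwise-same weights."""
    rng = np.random.default_rng(seed)
    return UNet(cfg, rng)
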