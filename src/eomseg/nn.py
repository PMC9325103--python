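"""Minimal CPU neural-network primitives (numpy, explicit backprop).

Implements exactly what the segmentation U-net needs: 3×3 same-padding
convolution, 1×1 convolution, ReLU, 2×2 max-pooling, 2×2 stride-2 transposed
convolution, channel concatenation, inverted dropout, per-pixel softmax, and
an Adam optimizer.  Convolutions are lowered to BLAS matmuls via im2col;
tensors are NHWC float32 throughout.

The backward functions each take the upstream gradient and return the
gradient with respect to the layer input; parameter gradients are accumulated
into a dict keyed like the parameter dict.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot_normal",
    "conv3x3_forward",
    "conv3x3_backward",
    "conv1x1_forward",
    "conv1x1_backward",
    "relu_forward",
    "relu_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "upconv2_forward",
    "upconv2_backward",
    "dropout_forward",
    "dropout_backward",
    "softmax",
    "softmax_backward",
    "Adam",
]


def glorot_normal(
    rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int
) -> np.ndarray:
    """Truncated (±2 sd) normal with sd = sqrt(2/(fan_in+fan_out))."""
    sd = np.sqrt(2.0 / (fan_in + fan_out))
    w = rng.normal(0.0, sd, size=shape)
    # resample the tails (truncated-normal initialisation)
    for _ in range(8):
        bad = np.abs(w) > 2.0 * sd
        if not bad.any():
            break
        w[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
    return np.clip(w, -2.0 * sd, 2.0 * sd).astype(np.float32)


class Workspace:
    """Reusable buffers for the training hot path.

    Repeated steps touch identical array shapes; reusing buffers avoids large
    allocations (and the page faults that dominate fresh-memory writes).
    ``get`` returns a per-tag buffer that persists until the same tag asks
    again (safe across a forward/backward pair); ``shared`` returns a
    transient buffer keyed by role+shape only, reused freely between layers —
    callers must consume it before the next request for the same role/shape.
    """

    def __init__(self) -> None:
        self._bufs: dict = {}
        self._arenas: dict = {}

    def get(self, tag: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
        key = (tag, shape, np.dtype(dtype))
        buf = self._bufs.get(key)
        if buf is None:
            buf = np.empty(shape, dtype=dtype)
            self._bufs[key] = buf
        return buf

    def shared(self, role: str, shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
        """View into a per-role flat arena sized to the largest request."""
        dtype = np.dtype(dtype)
        n = int(np.prod(shape))
        key = (role, dtype)
        arena = self._arenas.get(key)
        if arena is None or arena.size < n:
            arena = np.empty(n, dtype=dtype)
            self._arenas[key] = arena
        return arena[:n].reshape(shape)


def _im2col3(x: np.ndarray, ws: Workspace | None = None) -> np.ndarray:
    """(N,H,W,C) → (N·H·W, 9·C) patch matrix of the zero-padded input.

    The returned matrix lives in transient shared scratch when a workspace is
    given: it is valid only until the next im2col of the same shape.
    """
    n, h, w, c = x.shape
    if ws is not None:
        xp = ws.shared("pad", (n, h + 2, w + 2, c), x.dtype)
        xp[:] = 0.0
    else:
        xp = np.zeros((n, h + 2, w + 2, c), dtype=x.dtype)
    xp[:, 1:-1, 1:-1, :] = x
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # (N, H, W, C, 3, 3) → contiguous (N, H, W, 3, 3, C)
    if ws is not None:
        cols = ws.shared("cols", (n, h, w, 3, 3, c), x.dtype)
        np.copyto(cols, win.transpose(0, 1, 2, 4, 5, 3))
    else:
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    return cols.reshape(n * h * w, 9 * c)


def conv3x3_forward(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray,
    ws: Workspace | None = None,
    tag: str = "",
):
    """Same-padding 3×3 convolution.  w: (9·Cin, Cout), b: (Cout,).

    Caches the input tensor (9× smaller than its im2col matrix); the column
    matrix is rebuilt in the backward pass from shared scratch.
    """
    n, h, wd, c = x.shape
    cout = w.shape[1]
    cols = _im2col3(x, ws)
    if ws is not None:
        out = ws.get(tag + ".out", (n * h * wd, cout), np.float32)
        np.dot(cols, w, out=out)
        out += b
    else:
        out = cols @ w + b
    return out.reshape(n, h, wd, cout), (x, None if ws is not None else cols)


def conv3x3_backward(
    dout: np.ndarray,
    cache,
    w: np.ndarray,
    ws: Workspace | None = None,
    tag: str = "",
    need_dx: bool = True,
):
    x, cols = cache
    n, h, wd, c = x.shape
    cout = dout.shape[-1]
    dmat = np.ascontiguousarray(dout, dtype=np.float32).reshape(-1, cout)
    if cols is None:
        cols = _im2col3(x, ws)
    dw = cols.T @ dmat
    db = dmat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    if ws is not None:
        dcols = ws.shared("dcols", (n * h * wd, 9 * c), np.float32)
        np.dot(dmat, w.T, out=dcols)
        dxp = ws.shared("dxp", (n, h + 2, wd + 2, c), np.float32)
        dxp[:] = 0.0
    else:
        dcols = dmat @ w.T  # (N·H·W, 9·C)
        dxp = np.zeros((n, h + 2, wd + 2, c), dtype=np.float32)
    dcols = dcols.reshape(n, h, wd, 3, 3, c)
    for ki in range(3):
        for kj in range(3):
            dxp[:, ki : ki + h, kj : kj + wd, :] += dcols[:, :, :, ki, kj, :]
    return dxp[:, 1:-1, 1:-1, :], dw, db


def conv1x1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Pointwise convolution.  w: (Cin, Cout)."""
    out = x @ w + b
    return out, x


def conv1x1_backward(dout: np.ndarray, cache, w: np.ndarray):
    x = cache
    cin, cout = w.shape
    dmat = dout.reshape(-1, cout)
    xmat = x.reshape(-1, cin)
    dw = xmat.T @ dmat
    db = dmat.sum(axis=0)
    dx = (dmat @ w.T).reshape(x.shape)
    return dx, dw, db


def relu_forward(x: np.ndarray, inplace: bool = False):
    mask = x > 0.0
    out = np.maximum(x, 0.0, out=x) if inplace else np.maximum(x, 0.0)
    return out, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dout * mask


def maxpool2_forward(x: np.ndarray):
    """2×2 max pooling, stride 2; input dims must be even."""
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    xr = xr.transpose(0, 1, 3, 2, 4, 5).reshape(n, h // 2, w // 2, 4, c)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, (x.shape, idx)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    (n, h, w, c), idx = cache
    dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return dx.reshape(n, h, w, c)


def upconv2_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """2×2 stride-2 transposed convolution.  w: (2, 2, Cin, Cout)."""
    n, h, wd, cin = x.shape
    cout = w.shape[-1]
    xmat = x.reshape(-1, cin)
    out = np.empty((n, 2 * h, 2 * wd, cout), dtype=x.dtype)
    for di in range(2):
        for dj in range(2):
            out[:, di::2, dj::2, :] = (xmat @ w[di, dj] + b).reshape(n, h, wd, cout)
    return out, x


def upconv2_backward(dout: np.ndarray, cache, w: np.ndarray):
    x = cache
    n, h, wd, cin = x.shape
    cout = w.shape[-1]
    xmat = x.reshape(-1, cin)
    dw = np.zeros_like(w)
    db = np.zeros(cout, dtype=dout.dtype)
    dx = np.zeros_like(x)
    dxmat = dx.reshape(-1, cin)
    for di in range(2):
        for dj in range(2):
            dsub = np.ascontiguousarray(dout[:, di::2, dj::2, :]).reshape(-1, cout)
            dw[di, dj] = xmat.T @ dsub
            db += dsub.sum(axis=0)
            dxmat += dsub @ w[di, dj].T
    return dx, dw, db


def instnorm_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-5):
    """Instance normalisation: per-(sample, channel) over the spatial axes.

    Keeps activations O(1) at every depth without running statistics, so
    training and inference behave identically (the standard small-batch
    choice for segmentation networks).
    """
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    out = (x - mu) * inv
    out *= gamma
    out += beta
    # cache the input reference plus the small statistics; xhat is rebuilt in
    # the backward pass to keep the persistent cache small
    return out, (x, mu, inv, gamma)


def instnorm_backward(dout: np.ndarray, cache):
    x, mu, inv, gamma = cache
    xhat = (x - mu) * inv
    m = xhat.shape[1] * xhat.shape[2]
    dgamma = (dout * xhat).sum(axis=(0, 1, 2))
    dbeta = dout.sum(axis=(0, 1, 2))
    dxhat = dout * gamma
    s1 = dxhat.sum(axis=(1, 2), keepdims=True)
    s2 = (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
    dx = (inv / m) * (m * dxhat - s1 - xhat * s2)
    return dx.astype(dout.dtype), dgamma, dbeta


def dropout_forward(x: np.ndarray, keep_p: float, rng: np.random.Generator):
    """Inverted dropout: active only when called (training); keep_p ∈ (0, 1]."""
    if keep_p >= 1.0:
        return x, None
    mask = (rng.random(x.shape) < keep_p).astype(x.dtype) / keep_p
    return x * mask, mask


def dropout_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout if mask is None else dout * mask


def softmax(x: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last (channel) axis."""
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_backward(dprobs: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Chain dL/dprobs through the softmax to get dL/dlogits."""
    inner = (dprobs * probs).sum(axis=-1, keepdims=True)
    return probs * (dprobs - inner)


class Adam:
    """Adam with bias correction; state keyed like the parameter dict."""

    def __init__(
        self,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
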