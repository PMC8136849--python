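"""A small numpy neural-network engine for masked 1-D sequence convnets.

Implements exactly the family of architectures this package needs: stacks of
same-length 1-D convolutions (with dilation and identity residual additions),
masked frame or global pooling, a ReLU dense layer with dropout, a scalar
linear output, and an optional per-library affine output scaling.  Forward,
backward (including gradients with respect to the input, used for
contribution scores) and Adam are written out explicitly.

Masking convention: padded positions carry all-zero input and are multiplied
back to zero after every convolution layer.  This makes the activations seen
by valid positions identical whether the surrounding zeros come from batch
padding or from the convolution's own zero same-padding, which in turn makes
predictions exactly invariant to the amount of 5' batch padding.  Pooling
additionally excludes invalid positions from both max and average statistics.
"""

from __future__ import annotations

import numpy as np

__all__ = ["glorot_uniform", "Conv1D", "Dense", "Adam"]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# Layers (pure functions with explicit caches)
# ---------------------------------------------------------------------------

class Conv1D:
    """Same-length 1-D convolution, kernel ``k``, dilation ``d``.

    Weight layout: ``W[k, C_in, F]``, bias ``b[F]``.  Zero same-padding keeps
    the position count unchanged (required by the frame-slicing arithmetic).
    """

    def __init__(self, W: np.ndarray, b: np.ndarray, dilation: int = 1):
        self.W = W
        self.b = b
        self.dilation = dilation

    @property
    def kernel_size(self) -> int:
        return self.W.shape[0]

    def forward(self, x: np.ndarray):
        """x: (B, L, Cin) -> y: (B, L, F); returns (y, cache)."""
        k, Cin, F = self.W.shape
        d = self.dilation
        B, L, _ = x.shape
        p = (k - 1) // 2 * d
        xp = np.zeros((B, L + 2 * p, Cin), dtype=x.dtype)
        xp[:, p : p + L] = x
        y = np.broadcast_to(self.b.astype(x.dtype), (B, L, F)).copy()
        for a in range(k):
            tap = xp[:, a * d : a * d + L, :]
            y += (tap.reshape(B * L, Cin) @ self.W[a]).reshape(B, L, F)
        return y, (xp, x.shape)

    def backward(self, dY: np.ndarray, cache):
        """Returns (dx, dW, db)."""
        xp, xshape = cache
        k, Cin, F = self.W.shape
        d = self.dilation
        B, L, _ = xshape
        p = (k - 1) // 2 * d
        dW = np.zeros_like(self.W)
        db = dY.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        dY2 = dY.reshape(B * L, F)
        for a in range(k):
            tap = xp[:, a * d : a * d + L, :]
            dW[a] = tap.reshape(B * L, Cin).T @ dY2
            dxp[:, a * d : a * d + L, :] += (dY2 @ self.W[a].T).reshape(B, L, Cin)
        dx = dxp[:, p : p + L]
        return dx, dW, db


class Dense:
    """Fully connected layer, weight ``W[in, out]``, bias ``b[out]``."""

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.W = W
        self.b = b

    def forward(self, x: np.ndarray):
        return x @ self.W + self.b, x

    def backward(self, dY: np.ndarray, cache):
        x = cache
        return dY @ self.W.T, x.T @ dY, dY.sum(axis=0)


def relu_forward(x):
    y = np.maximum(x, 0)
    return y, (x > 0)


def relu_backward(dY, cache):
    return dY * cache


def masked_pool_forward(h: np.ndarray, mask: np.ndarray, n_groups: int):
    """Masked max+average pooling over position groups.

    ``n_groups == 3``: frame pooling — the map is reversed along the position
    axis (3'-anchored) and group ``j`` takes reversed indices ``j::3``.
    ``n_groups == 1``: conventional global pooling over all valid positions.
    Output layout: ``[max g0..g{n-1} | avg g0..g{n-1}]``, width ``2 * n_groups * F``.
    Empty groups pool to 0 for both statistics.
    """
    B, L, F = h.shape
    if n_groups == 3:
        hv = h[:, ::-1, :]
        mv = mask[:, ::-1]
        groups = [(hv[:, j::3, :], mv[:, j::3]) for j in range(3)]
    elif n_groups == 1:
        groups = [(h, mask)]
    else:
        raise ValueError("n_groups must be 1 or 3")
    outs = []
    caches = []
    for sl, m in groups:
        mb = m.astype(bool)
        n_valid = mb.sum(axis=1)
        masked = np.where(mb[:, :, None], sl, np.array(-np.inf, dtype=sl.dtype))
        amax = masked.argmax(axis=1)  # (B, F)
        mx = np.take_along_axis(sl, amax[:, None, :], axis=1)[:, 0, :]
        mx = np.where(n_valid[:, None] > 0, mx, 0.0).astype(sl.dtype)
        sm = np.where(mb[:, :, None], sl, 0).sum(axis=1)
        denom = np.maximum(n_valid, 1)[:, None]
        av = (np.where(n_valid[:, None] > 0, sm / denom, 0.0)).astype(sl.dtype)
        outs.append((mx, av))
        caches.append((amax, mb, n_valid, sl.shape))
    pooled = np.concatenate(
        [mx for mx, _ in outs] + [av for _, av in outs], axis=1
    )
    return pooled, (caches, h.shape, n_groups)


def masked_pool_backward(dP: np.ndarray, cache):
    caches, hshape, n_groups = cache
    B, L, F = hshape
    dh = np.zeros(hshape, dtype=dP.dtype)
    if n_groups == 3:
        dhv = dh[:, ::-1, :]  # view; writes land in dh
        slices = [dhv[:, j::3, :] for j in range(3)]
    else:
        slices = [dh]
    for j, (amax, mb, n_valid, slshape) in enumerate(caches):
        dmx = dP[:, j * F : (j + 1) * F]
        dav = dP[:, (n_groups + j) * F : (n_groups + j + 1) * F]
        dsl = np.zeros(slshape, dtype=dP.dtype)
        # max: route to argmax position (only where the group is non-empty)
        route = np.where(n_valid[:, None] > 0, dmx, 0.0)
        np.put_along_axis(dsl, amax[:, None, :], route[:, None, :], axis=1)
        # avg: spread over valid members
        denom = np.maximum(n_valid, 1)[:, None]
        dsl += (np.where(n_valid[:, None] > 0, dav / denom, 0.0))[:, None, :] \
            * mb[:, :, None]
        slices[j][...] += dsl
    return dh


def dropout_forward(x, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when ``rng is None`` (inference)."""
    if rng is None or rate <= 0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


def dropout_backward(dY, cache):
    return dY if cache is None else dY * cache


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the conventional defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: dict, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
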