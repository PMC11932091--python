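"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the encoders and classifier need: dense and
indexed linear algebra (matmul, gather, segment-sum), pointwise nonlinearities,
concatenation, reductions, a masked max-pool, a same-padded 1-d convolution,
and two fused loss heads (sigmoid + binary cross-entropy on logits, and a
row-wise negative-cosine against a detached target).

Gradients accumulate into ``Tensor.grad`` after calling ``backward()`` on a
scalar-valued tensor. Non-differentiable inputs (indices, masks, adjacency
operators) are passed as plain NumPy arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "add",
    "matmul",
    "mul",
    "relu",
    "leaky_relu",
    "concat",
    "rows",
    "segment_sum",
    "mean_all",
    "sum_all",
    "masked_max",
    "conv1d_same",
    "embedding",
    "dropout",
    "bce_with_logits",
    "neg_cosine_rows",
]


class Tensor:
    """A node in the computation graph wrapping an ``ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        self._grad_shared = False

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None  # allocated lazily on first accumulation
            t._grad_shared = False
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def parameter(array, dtype=np.float64) -> Tensor:
    return Tensor(np.array(array, dtype=dtype), requires_grad=True)


def constant(array) -> Tensor:
    return Tensor(array, requires_grad=False)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def _accum(t: Tensor, g):
    """Lazy gradient accumulation.

    The first contribution is aliased (no copy) and marked shared; a second
    contribution replaces it with an out-of-place sum, so shared arrays are
    never mutated in place."""
    if t.requires_grad:
        if t.grad is None:
            t.grad = g
            t._grad_shared = True
        elif t._grad_shared:
            t.grad = t.grad + g
            t._grad_shared = False
        else:
            t.grad += g


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents if p.requires_grad),
                  backward=backward if req else None)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return _make(out_data, (x,), backward)


def leaky_relu(x, slope=0.01) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    scale = np.where(mask, 1.0, slope)
    out_data = x.data * scale

    def backward(g):
        _accum(x, g * scale)

    return _make(out_data, (x,), backward)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(out_data, tuple(tensors), backward)


def rows(x, idx) -> Tensor:
    """Gather rows ``x[idx]`` (idx is a constant integer array)."""
    x = _as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            _accum(x, acc)

    return _make(out_data, (x,), backward)


def segment_sum(x, seg_ids, num_segments) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given by ``seg_ids``."""
    x = _as_tensor(x)
    seg_ids = np.asarray(seg_ids, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:])
    np.add.at(out_data, seg_ids, x.data)

    def backward(g):
        _accum(x, g[seg_ids])

    return _make(out_data, (x,), backward)


def sum_all(x) -> Tensor:
    x = _as_tensor(x)
    out_data = np.asarray(x.data.sum())

    def backward(g):
        _accum(x, np.broadcast_to(g, x.data.shape))

    return _make(out_data, (x,), backward)


def mean_all(x) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size
    out_data = np.asarray(x.data.mean())

    def backward(g):
        _accum(x, np.broadcast_to(g / n, x.data.shape))

    return _make(out_data, (x,), backward)


def masked_max(x, mask) -> Tensor:
    """Max over axis 1 of ``x`` (B, L, C) restricted to positions where
    ``mask`` (B, L) is True; rows with an empty mask fall back to all
    positions. Gradient routes to the (first) argmax position."""
    x = _as_tensor(x)
    mask = np.asarray(mask, dtype=bool)
    eff_mask = mask.copy()
    empty = ~eff_mask.any(axis=1)
    eff_mask[empty, :] = True
    neg = np.where(eff_mask[:, :, None], x.data, -np.inf)
    arg = neg.argmax(axis=1)  # (B, C)
    B, L, C = x.data.shape
    bi = np.arange(B)[:, None]
    ci = np.arange(C)[None, :]
    out_data = x.data[bi, arg, ci]

    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, (bi, arg, ci), g)
            _accum(x, acc)

    return _make(out_data, (x,), backward)


def embedding(table, tokens) -> Tensor:
    """Look up rows of ``table`` (V, D) for integer ``tokens`` (B, L)."""
    table = _as_tensor(table)
    tokens = np.asarray(tokens, dtype=np.intp)
    out_data = table.data[tokens]

    def backward(g):
        if table.requires_grad:
            V = table.data.shape[0]
            flat = tokens.ravel()
            g2 = g.reshape(-1, g.shape[-1])
            if V <= 64:  # one-hot matmul beats np.add.at for small vocabularies
                onehot = (flat[:, None] == np.arange(V)[None, :]).astype(g2.dtype)
                _accum(table, onehot.T @ g2)
            else:
                acc = np.zeros_like(table.data)
                np.add.at(acc, flat, g2)
                _accum(table, acc)

    return _make(out_data, (table,), backward)


def conv1d_same(x, w, b) -> Tensor:
    """1-d convolution with 'same' zero padding and stride 1.

    x: (B, L, Cin), w: (K, Cin, Cout), b: (Cout,) -> (B, L, Cout).
    Implemented as an im2col matmul; K must be odd.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, L, Cin = x.data.shape
    K, Cin_w, Cout = w.data.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for 'same' padding")
    pad = K // 2
    xp = np.zeros((B, L + 2 * pad, Cin))
    xp[:, pad:pad + L, :] = x.data
    # (B, L, K, Cin) sliding windows
    stride_b, stride_l, stride_c = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(B, L, K, Cin), strides=(stride_b, stride_l, stride_l, stride_c))
    cols = windows.reshape(B * L, K * Cin)
    w_flat = w.data.reshape(K * Cin, Cout)
    out_data = (cols @ w_flat + b.data).reshape(B, L, Cout)

    def backward(g):
        g2 = g.reshape(B * L, Cout)
        if w.requires_grad:
            _accum(w, (cols.T @ g2).reshape(K, Cin, Cout))
        if b.requires_grad:
            _accum(b, g2.sum(axis=0))
        if x.requires_grad:
            gcols = (g2 @ w_flat.T).reshape(B, L, K, Cin)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k:k + L, :] += gcols[:, :, k, :]
            _accum(x, gxp[:, pad:pad + L, :])

    return _make(out_data, (x, w, b), backward)


def dropout(x, p, rng, active=True) -> Tensor:
    """Inverted dropout; a no-op when inactive or p == 0."""
    x = _as_tensor(x)
    if not active or p == 0.0:
        return x
    if not 0.0 <= p < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    mask = ((rng.random(x.data.shape) >= p) / (1.0 - p)).astype(x.data.dtype)
    return mul(x, constant(mask))


def bce_with_logits(logits, labels) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable fused form)."""
    logits = _as_tensor(logits)
    y = np.asarray(labels, dtype=np.float64)
    z = logits.data
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    loss = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y
    out_data = np.asarray(loss.mean())
    n = z.size

    def backward(g):
        p = 1.0 / (1.0 + np.exp(-z))
        _accum(logits, (g * (p - y) / n).astype(z.dtype, copy=False))

    return _make(out_data, (logits,), backward)


def neg_cosine_rows(z, h_target) -> Tensor:
    """Loss -(2/N) * sum_i cos(z_i, h_i) against a detached target matrix.

    Rows where either vector has zero norm contribute 0 (continuous limit).
    Gradient flows only through ``z``.
    """
    z = _as_tensor(z)
    h = np.asarray(h_target.data if isinstance(h_target, Tensor) else h_target)
    N = z.data.shape[0]
    zn = np.linalg.norm(z.data, axis=1)
    hn = np.linalg.norm(h, axis=1)
    ok = (zn > 0) & (hn > 0)
    cos = np.zeros(N)
    dots = (z.data * h).sum(axis=1)
    cos[ok] = dots[ok] / (zn[ok] * hn[ok])
    out_data = np.asarray(-(2.0 / N) * cos.sum())

    def backward(g):
        if z.requires_grad:
            grad = np.zeros_like(z.data)
            # d cos/dz = h/(|z||h|) - cos * z/|z|^2
            grad[ok] = (h[ok] / (zn[ok, None] * hn[ok, None])
                        - cos[ok, None] * z.data[ok] / (zn[ok, None] ** 2))
            _accum(z, g * (-(2.0 / N)) * grad)

    return _make(out_data, (z,), backward)
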