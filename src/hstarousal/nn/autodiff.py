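"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A tape-based engine sized for the arousal detector: broadcast-aware
elementwise ops, matrix products, 1-D convolution with stride and
asymmetric padding, batch normalization, and a fused
binary-cross-entropy-with-logits loss.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "batchnorm", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise arithmetic ---------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._coerce(other)

        def backward(g, out):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g, out: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._make(s, (self,), lambda g, out: (g * s * (1.0 - s),))

    def tanh(self):
        t = np.tanh(self.data)
        return Tensor._make(t, (self,), lambda g, out: (g * (1.0 - t * t),))

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g, out: (g.reshape(orig),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes),
            (self,),
            lambda g, out: (g.transpose(tuple(inv)),),
        )

    # -- backward pass -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g, node)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                elif parent._backward is None and parent._parents == ():
                    # accumulate directly into leaves that appear many times
                    grads[id(parent)] = pg
                else:
                    grads[id(parent)] = pg


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )


def conv1d(
    x: Tensor,
    w: Tensor,
    b: Tensor,
    stride: int = 1,
    pad_left: int = 0,
    pad_right: int = 0,
) -> Tensor:
    """1-D convolution (cross-correlation): ``x`` (N, C_in, L) -> (N, C_out, L_out)."""
    X = x.data
    N, C_in, L = X.shape
    C_out, _, K = w.data.shape
    Xp = np.pad(X, ((0, 0), (0, 0), (pad_left, pad_right)))
    Lp = Xp.shape[2]
    L_out = (Lp - K) // stride + 1

    # gather patches with strided slices (fast; no fancy indexing)
    cols = np.empty((N, L_out, C_in, K))
    for k in range(K):
        cols[:, :, :, k] = Xp[:, :, k : k + L_out * stride : stride].transpose(0, 2, 1)
    cols_flat = cols.reshape(N, L_out, C_in * K)
    Wmat = w.data.reshape(C_out, C_in * K)
    out = cols_flat @ Wmat.T + b.data  # (N, L_out, C_out)
    out = out.transpose(0, 2, 1)

    def backward(g, outT):
        gmat = g.transpose(0, 2, 1)  # (N, L_out, C_out)
        grad_b = gmat.sum(axis=(0, 1))
        grad_W = np.tensordot(gmat, cols_flat, axes=([0, 1], [0, 1]))  # (C_out, C_in*K)
        grad_w = grad_W.reshape(C_out, C_in, K)
        grad_cols = (gmat @ Wmat).reshape(N, L_out, C_in, K)
        grad_xp = np.zeros_like(Xp)
        for k in range(K):
            grad_xp[:, :, k : k + L_out * stride : stride] += grad_cols[
                :, :, :, k
            ].transpose(0, 2, 1)
        grad_x = grad_xp[:, :, pad_left : pad_left + L] if pad_left or pad_right else grad_xp
        return (grad_x, grad_w, grad_b)

    return Tensor._make(out, (x, w, b), backward)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, C, L), statistics per channel.

    In training mode the batch statistics are used and the running
    estimates updated in place; in eval mode the running estimates are
    used.
    """
    X = x.data
    axes = (0, 2)
    gam = gamma.data.reshape(1, -1, 1)
    bet = beta.data.reshape(1, -1, 1)
    if training:
        mu = X.mean(axis=axes, keepdims=True)
        var = X.var(axis=axes, keepdims=True)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu.ravel()
        running_var *= 1.0 - momentum
        running_var += momentum * var.ravel()
    else:
        mu = running_mean.reshape(1, -1, 1)
        var = running_var.reshape(1, -1, 1)
    std = np.sqrt(var + eps)
    xhat = (X - mu) / std
    out = gam * xhat + bet

    def backward(g, outT):
        grad_gamma = (g * xhat).sum(axis=axes)
        grad_beta = g.sum(axis=axes)
        dxhat = g * gam
        if training:
            m = X.shape[0] * X.shape[2]
            grad_x = (
                dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
            ) / std
            del m
        else:
            grad_x = dxhat / std
        return (grad_x, grad_gamma, grad_beta)

    return Tensor._make(out, (x, gamma, beta), backward)


def bce_with_logits(
    logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None
) -> Tensor:
    """Mean binary cross-entropy over (optionally masked) elements.

    Numerically stable: ``loss = max(z,0) - z*y + log(1+exp(-|z|))``.
    ``mask`` selects which elements contribute (1 = include).
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(z)
    else:
        mask = np.asarray(mask, dtype=np.float64)
    m = mask.sum()
    if m == 0:
        raise ValueError("bce_with_logits: empty mask")
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    val = (per * mask).sum() / m

    def backward(g, out):
        s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return (g * (s - y) * mask / m,)

    return Tensor._make(val, (logits,), backward)
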