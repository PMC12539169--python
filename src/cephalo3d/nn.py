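"""Minimal reverse-mode autodiff and neural-network primitives on numpy.

A small tape-based engine purpose-built for this package's convolutional
heatmap-regression networks.  Arrays carry an explicit channel-first layout
``(C, *spatial)`` with no batch axis (samples are processed one at a time,
which pairs naturally with instance normalization).  The op set is exactly
what the pseudo-3D architecture needs: same-padded correlation with odd
kernels (any spatial rank), bias, instance norm, relu/sigmoid, 2x average
pooling and nearest-neighbour upsampling, channel concatenation, per-axis
mean descriptors with their inverse broadcast, elementwise arithmetic and a
(masked) mean-squared-error loss.

Convolutions are evaluated as BLAS contractions over sliding windows
(``sliding_window_view`` + ``tensordot``), float32 throughout.  Gradients are
exact; ``gradient_check`` verifies any scalar-valued graph against central
finite differences and is exercised by the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "SGD", "gradient_check"]


class Tensor:
    """A node in the computation graph: float32 data, gradient, backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph walk ---------------------------------------------------------

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) node."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss node")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs are deep for big U-Nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        assert self.shape == other.shape, (self.shape, other.shape)

        def back(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=back)

    def __mul__(self, other: "Tensor") -> "Tensor":
        assert self.shape == other.shape, (self.shape, other.shape)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(g * b.data)
            if b.requires_grad:
                b._accum(g * a.data)

        return Tensor(a.data * b.data, parents=(a, b), backward=back)

    def scale(self, c: float) -> "Tensor":
        def back(g):
            if self.requires_grad:
                self._accum(g * c)

        return Tensor(self.data * c, parents=(self,), backward=back)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def back(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=back)

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))

        def back(g):
            if self.requires_grad:
                self._accum(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=back)

    # -- convolution --------------------------------------------------------

    def conv(self, weight: "Tensor") -> "Tensor":
        """Same-padded correlation; self ``(Cin, *S)``, weight ``(Cout, Cin, *k)``.

        All kernel extents must be odd so that 'same' padding is symmetric.
        """
        x, w = self.data, weight.data
        nd = x.ndim - 1
        k = w.shape[2:]
        assert len(k) == nd and all(ki % 2 == 1 for ki in k), k
        out = _corr(x, w)

        def back(g):
            if weight.requires_grad:
                win = _windows(x, k)
                # grad_w[o, c, *k] = sum_S g[o, S] * win[c, S, *k]
                gw = np.tensordot(g, win, axes=(range(1, 1 + nd), range(1, 1 + nd)))
                weight._accum(gw)
            if self.requires_grad:
                w2 = np.flip(w, axis=tuple(range(2, 2 + nd))).swapaxes(0, 1)
                self._accum(_corr(g, np.ascontiguousarray(w2)))

        return Tensor(out, parents=(self, weight), backward=back)

    def bias(self, b: "Tensor") -> "Tensor":
        """Add per-channel bias ``b`` of shape (C,)."""
        nd = self.data.ndim - 1
        shape = (-1,) + (1,) * nd

        def back(g):
            if self.requires_grad:
                self._accum(g)
            if b.requires_grad:
                b._accum(g.sum(axis=tuple(range(1, 1 + nd))))

        return Tensor(self.data + b.data.reshape(shape), parents=(self, b), backward=back)

    # -- normalization ------------------------------------------------------

    def instance_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-4) -> "Tensor":
        """Per-channel normalization over all spatial positions, with affine."""
        x = self.data
        nd = x.ndim - 1
        axes = tuple(range(1, 1 + nd))
        n = int(np.prod(x.shape[1:]))
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc ** 2).mean(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        cshape = (-1,) + (1,) * nd
        out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

        def back(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gx = g * gamma.data.reshape(cshape)
                s1 = gx.sum(axis=axes, keepdims=True)
                s2 = (gx * xhat).sum(axis=axes, keepdims=True)
                self._accum(inv * (gx - s1 / n - xhat * s2 / n))

        return Tensor(out, parents=(self, gamma, beta), backward=back)

    # -- resampling ---------------------------------------------------------

    def avgpool2(self) -> "Tensor":
        """2x average pooling on every spatial axis (dims must be even)."""
        x = self.data
        nd = x.ndim - 1
        assert all(s % 2 == 0 for s in x.shape[1:]), x.shape
        shp = [x.shape[0]]
        for s in x.shape[1:]:
            shp += [s // 2, 2]
        xr = x.reshape(shp)
        axes = tuple(range(2, 2 + 2 * nd, 2))
        out = xr.mean(axis=axes)
        scale = 1.0 / (2 ** nd)

        def back(g):
            if self.requires_grad:
                gg = g * scale
                for ax in range(1, 1 + nd):
                    gg = np.repeat(gg, 2, axis=ax)
                self._accum(gg)

        return Tensor(out, parents=(self,), backward=back)

    def upsample2(self) -> "Tensor":
        """2x nearest-neighbour upsampling on every spatial axis."""
        x = self.data
        nd = x.ndim - 1
        out = x
        for ax in range(1, 1 + nd):
            out = np.repeat(out, 2, axis=ax)

        def back(g):
            if self.requires_grad:
                shp = [g.shape[0]]
                for s in g.shape[1:]:
                    shp += [s // 2, 2]
                axes = tuple(range(2, 2 + 2 * nd, 2))
                self._accum(g.reshape(shp).sum(axis=axes))

        return Tensor(out, parents=(self,), backward=back)

    # -- shape ops ----------------------------------------------------------

    def concat(self, other: "Tensor") -> "Tensor":
        """Concatenate along the channel axis."""
        c = self.shape[0]

        def back(g):
            if self.requires_grad:
                self._accum(g[:c])
            if other.requires_grad:
                other._accum(g[c:])

        return Tensor(np.concatenate([self.data, other.data], axis=0),
                      parents=(self, other), backward=back)

    def mean_axis(self, spatial_axis: int) -> "Tensor":
        """Average over one spatial axis (0-based among spatial axes)."""
        ax = 1 + spatial_axis
        n = self.data.shape[ax]
        out = self.data.mean(axis=ax)

        def back(g):
            if self.requires_grad:
                self._accum(np.repeat(np.expand_dims(g / n, ax), n, axis=ax))

        return Tensor(out, parents=(self,), backward=back)

    def expand_axis(self, spatial_axis: int, size: int) -> "Tensor":
        """Broadcast along a new spatial axis (inverse of :meth:`mean_axis`)."""
        ax = 1 + spatial_axis
        out = np.repeat(np.expand_dims(self.data, ax), size, axis=ax)

        def back(g):
            if self.requires_grad:
                self._accum(g.sum(axis=ax))

        return Tensor(out, parents=(self,), backward=back)

    # -- losses -------------------------------------------------------------

    def mse(self, target: np.ndarray, mask: np.ndarray | None = None) -> "Tensor":
        """(Weighted) mean squared error against a constant target.

        ``mask`` is a broadcastable nonnegative weight field; the loss is
        ``sum(mask * diff^2) / sum(mask)``.  A 0/1 mask restricts supervision
        to selected entries (e.g. one channel); graded weights rebalance rare
        supervision such as absent-landmark channels.
        """
        target = np.asarray(target, dtype=np.float32)
        assert self.shape == target.shape, (self.shape, target.shape)
        diff = self.data - target
        if mask is not None:
            mask = np.broadcast_to(np.asarray(mask, dtype=np.float32), self.shape)
            n = float(mask.sum())
            out = np.array((mask * diff ** 2).sum() / n, dtype=np.float32)
        else:
            n = float(diff.size)
            out = np.array((diff ** 2).sum() / n, dtype=np.float32)

        def back(g):
            if self.requires_grad:
                grad = g * 2.0 * diff / n
                if mask is not None:
                    grad = grad * mask
                self._accum(grad)

        return Tensor(out, parents=(self,), backward=back)

    def mae(self, target: np.ndarray, mask: np.ndarray | None = None) -> "Tensor":
        """Mean absolute error against a constant target (subgradient at 0)."""
        target = np.asarray(target, dtype=np.float32)
        assert self.shape == target.shape, (self.shape, target.shape)
        diff = self.data - target
        if mask is not None:
            mask = np.broadcast_to(np.asarray(mask, dtype=np.float32), self.shape)
            n = float(mask.sum())
            diff = diff * mask
        else:
            n = float(diff.size)
        out = np.array(np.abs(diff).sum() / n, dtype=np.float32)

        def back(g):
            if self.requires_grad:
                self._accum(g * np.sign(diff) / n)

        return Tensor(out, parents=(self,), backward=back)


def _windows(x: np.ndarray, k: tuple[int, ...]) -> np.ndarray:
    pad = [(0, 0)] + [(ki // 2, ki // 2) for ki in k]
    xp = np.pad(x, pad)
    return sliding_window_view(xp, k, axis=tuple(range(1, x.ndim)))


def _corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlation of (Cin, *S) with (Cout, Cin, *k), same padding."""
    nd = x.ndim - 1
    win = _windows(x, w.shape[2:])
    out = np.tensordot(w, win, axes=([1] + list(range(2, 2 + nd)),
                                     [0] + list(range(1 + nd, 1 + 2 * nd))))
    return np.ascontiguousarray(out, dtype=np.float32)


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float | None = 10.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def gradient_check(build_loss: Callable[[], Tensor], params: Sequence[Tensor],
                   eps: float = 1e-3, atol: float = 1e-3, rtol: float = 5e-2) -> float:
    """Compare analytic gradients with central finite differences.

    ``build_loss`` must rebuild the graph from the (mutated) parameter data on
    every call.  Returns the worst relative discrepancy; raises AssertionError
    beyond tolerance.  Uses float64 differencing on a handful of entries per
    parameter to keep it fast.
    """
    loss = build_loss()
    for p in params:
        p.zero_grad()
    loss.backward()
    grads = [None if p.grad is None else p.grad.copy() for p in params]
    worst = 0.0
    rng = np.random.default_rng(0)
    for p, g in zip(params, grads):
        assert g is not None, "parameter received no gradient"
        flat = p.data.reshape(-1)
        idxs = rng.choice(flat.size, size=min(5, flat.size), replace=False)
        for i in idxs:
            old = flat[i]
            flat[i] = old + eps
            lp = float(build_loss().data)
            flat[i] = old - eps
            lm = float(build_loss().data)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = float(g.reshape(-1)[i])
            err = abs(num - ana) / max(abs(num), abs(ana), atol)
            worst = max(worst, err)
            assert err <= rtol, f"grad mismatch: numeric {num}, analytic {ana}"
    return worst
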