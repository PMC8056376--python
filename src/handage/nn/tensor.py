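"""A compact reverse-mode autodiff engine on numpy arrays.

Implements exactly the operations the package's networks need: broadcasted
arithmetic, matmul, 2-D (grouped/depthwise) convolution via im2col, batch
normalization, the MobileNetV3 nonlinearities, reductions, slicing,
concatenation and a fused softmax cross-entropy.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` in reverse topological order.

Float32 is the working precision; float64 is supported throughout so that
finite-difference gradient checks can run at full precision.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if not isinstance(data, np.ndarray):
            data = np.asarray(data)
            if not np.issubdtype(data.dtype, np.floating):
                data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x, dtype) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=dtype))

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad),
                      _backward=backward if req else None)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other, self.dtype))

    def __rsub__(self, other):
        return self._lift(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = self._lift(other, self.dtype)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    # ---------------------------------------------------------- element-wise
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def hswish(self):
        """h-swish(x) = x * clamp(x + 3, 0, 6) / 6."""
        inner = np.clip(self.data + 3.0, 0.0, 6.0)
        out_data = self.data * inner / 6.0

        def backward(g):
            if self.requires_grad:
                d = inner / 6.0 + self.data * ((self.data > -3.0) & (self.data < 3.0)) / 6.0
                self._accum(g * d)

        return self._make(out_data, (self,), backward)

    def hsigmoid(self):
        """h-sigmoid(x) = clamp(x + 3, 0, 6) / 6, the hard gate used in SE blocks."""
        out_data = np.clip(self.data + 3.0, 0.0, 6.0) / 6.0

        def backward(g):
            if self.requires_grad:
                self._accum(g * (((self.data > -3.0) & (self.data < 3.0)) / 6.0))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(np.abs(self.data), (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)

    @staticmethod
    def concat(tensors, axis: int = 0) -> "Tensor":
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        req = any(t.requires_grad for t in tensors)
        return Tensor(out_data, requires_grad=req,
                      _parents=tuple(t for t in tensors if t.requires_grad),
                      _backward=backward if req else None)

    # ---------------------------------------------------------- convolutions
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """Dense 2-D cross-correlation, NCHW input, (Cout, Cin, k, k) weight."""
        x, w = self.data, weight.data
        n, cin, _, _ = x.shape
        cout, _, kh, kw = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]            # (N, Cin, Ho, Wo, kh, kw)
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, cin * kh * kw)
        wmat = w.reshape(cout, cin * kh * kw)
        out = cols @ wmat.T
        if bias is not None:
            out += bias.data
        out_data = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)

        def backward(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
            if weight.requires_grad:
                weight._accum((gmat.T @ cols).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gmat.sum(axis=0))
            if self.requires_grad:
                dcols = (gmat @ wmat).reshape(n, ho, wo, cin, kh, kw)
                dxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += \
                            dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accum(dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    def depthwise_conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
                         stride: int = 1, padding: int = 0) -> "Tensor":
        """Per-channel 2-D cross-correlation; weight shape (C, kh, kw)."""
        x, w = self.data, weight.data
        n, c, _, _ = x.shape
        _, kh, kw = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x
        win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
        win = win[:, :, ::stride, ::stride]            # (N, C, Ho, Wo, kh, kw)
        ho, wo = win.shape[2], win.shape[3]
        out_data = np.einsum("nchwkl,ckl->nchw", win, w, optimize=True)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]

        def backward(g):
            if weight.requires_grad:
                weight._accum(np.einsum("nchw,nchwkl->ckl", g, win, optimize=True))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                dxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += \
                            g * w[None, :, ki, kj, None, None]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                self._accum(dxp)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return self._make(out_data, parents, backward)

    # ------------------------------------------------------------ batch norm
    def batch_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5,
                   mean: np.ndarray | None = None, var: np.ndarray | None = None) -> "Tensor":
        """Normalize per channel (axis 1) over all remaining axes.

        With ``mean``/``var`` given (inference), those fixed statistics are
        used; otherwise the batch's own statistics are used and gradients flow
        through them.
        """
        x = self.data
        axes = (0,) + tuple(range(2, x.ndim))
        shape = [1] * x.ndim
        shape[1] = x.shape[1]
        use_batch_stats = mean is None
        if use_batch_stats:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
        mu, v = mean.reshape(shape), var.reshape(shape)
        inv_std = 1.0 / np.sqrt(v + eps)
        xhat = (x - mu) * inv_std
        out_data = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)
        m = x.size // x.shape[1]

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accum(g.sum(axis=axes))
            if self.requires_grad:
                gs = g * gamma.data.reshape(shape)
                if use_batch_stats:
                    dx = inv_std * (gs - gs.mean(axis=axes, keepdims=True)
                                    - xhat * (gs * xhat).mean(axis=axes, keepdims=True))
                else:
                    dx = gs * inv_std
                self._accum(dx)

        return self._make(out_data, (self, gamma, beta), backward)

    # --------------------------------------------------------- fused losses
    def softmax_cross_entropy_sum(self, labels: np.ndarray) -> "Tensor":
        """Sum over rows of -log softmax(logits)[label]; logits shape (M, q)."""
        z = self.data
        zmax = z.max(axis=1, keepdims=True)
        ez = np.exp(z - zmax)
        sez = ez.sum(axis=1, keepdims=True)
        logp = (z - zmax) - np.log(sez)
        rows = np.arange(z.shape[0])
        out_data = np.asarray(-logp[rows, labels].sum(), dtype=z.dtype)

        def backward(g):
            if self.requires_grad:
                grad = ez / sez
                grad[rows, labels] -= 1.0
                self._accum(g * grad)

        return self._make(out_data, (self,), backward)
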