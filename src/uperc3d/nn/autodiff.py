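"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operator set the 3D denoising networks and
losses need: broadcasting arithmetic, reductions, reshaping, batched matmul,
ReLU-family nonlinearities, softmax building blocks, 3D convolution (GEMM via
im2col), 3D max-pooling, padding and slicing.  Convolutions hit BLAS through a
single large matrix product per layer, which is what makes CPU training of the
volumetric networks practical.

Gradients accumulate into ``Tensor.grad`` (a numpy array) after calling
``backward()`` on a scalar.  Tensors default to float32; individual ops may
carry float64 (e.g. the SSIM objective) and gradients are cast back at dtype
boundaries.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, np.generic):
            data = np.asarray(data)  # numpy scalar: keep its dtype
        elif not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order over the subgraph that requires grad
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- graph helper -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad) if req else (), _backward=backward if req else None)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other, self.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / (other.data * other.data), other.shape))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bwd(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other, self.dtype)
        out_data = self.data @ other.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    # -- elementwise ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g / (2.0 * out_data))

        return Tensor._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def astype(self, dtype):
        dtype = np.dtype(dtype)
        src = self.data.dtype

        def bwd(g):
            self._accumulate(g.astype(src))

        return Tensor._make(self.data.astype(dtype), (self,), bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape))
            else:
                ax = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, ax)
                self._accumulate(np.broadcast_to(g, shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        """Reduction max; gradient flows to (all) argmax positions equally split."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        counts = mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims or axis is None else np.squeeze(out_data, axis=axis)
        if axis is None and not keepdims:
            res = res.reshape(())

        def bwd(g):
            ga = np.asarray(g)
            if not keepdims and axis is not None:
                ga = np.expand_dims(ga, axis)
            self._accumulate(mask * (ga / counts))

        return Tensor._make(res, (self,), bwd)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape

        def bwd(g):
            self._accumulate(g.reshape(src))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape

        def bwd(g):
            full = np.zeros(shape, dtype=g.dtype)
            full[idx] = g
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)

    def pad(self, pad_width):
        """Zero padding; pad_width as for np.pad."""
        slices = tuple(slice(p[0], p[0] + s) for p, s in zip(pad_width, self.shape))

        def bwd(g):
            self._accumulate(g[slices])

        return Tensor._make(np.pad(self.data, pad_width), (self,), bwd)


def as_tensor(x, dtype=np.float32) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), bwd)
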