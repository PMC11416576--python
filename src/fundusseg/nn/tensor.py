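"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: tensors wrap a numpy array, operations
build a DAG, and :meth:`Tensor.backward` runs reverse-mode accumulation in
topological order.  Only the operations the segmentation networks need are
provided (see :mod:`fundusseg.nn.functional`).  Data layout is NHWC
throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """A numpy array plus gradient bookkeeping.

    Parameters
    ----------
    data : array-like
        Wrapped value.  The dtype is preserved (float32 for speed in
        training, float64 wherever gradients are checked numerically).
    requires_grad : bool
        Whether gradients should be accumulated for this tensor.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients of this tensor w.r.t. every ancestor.

        ``grad`` defaults to ones (scalar outputs are the usual case).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for the U-Nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            parent_grads = node._backward(node.grad)
            for parent, g in zip(node._parents, parent_grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self):
        self.grad = None

    # operator sugar (definitions live in functional to avoid cycles)
    def __add__(self, other):
        from . import functional as F

        return F.add(self, other)

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, other)

    def __sub__(self, other):
        from . import functional as F

        return F.sub(self, other)

    def __truediv__(self, other):
        from . import functional as F

        return F.div(self, other)


class Parameter(Tensor):
    """A trainable tensor (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
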