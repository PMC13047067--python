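"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the encoder/decoder needs: dense matrix
products, broadcast add/multiply, ReLU, logistic sigmoid, row softmax,
elementwise log/power/clip, row gathering, concatenation and reductions.
Gradients are accumulated by a topological sweep from the output scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "take_rows", "softmax_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    #: make numpy defer to Tensor.__r*__ in mixed ndarray-Tensor arithmetic
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _make(self, data, parents, backward):
        return Tensor(data, _parents=parents, _backward=backward)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    # -- nonlinearities --------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def pow_const(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the band."""
        mask = (self.data > lo) & (self.data < hi)
        return self._make(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    # -- reductions ------------------------------------------------------

    def sum(self):
        return self._make(self.data.sum(), (self,), lambda g: (np.full(self.shape, g),))

    def mean(self):
        n = self.data.size
        return self._make(self.data.mean(), (self,), lambda g: (np.full(self.shape, g / n),))

    # -- backward --------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))

        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] += pg
                    else:
                        grads[id(parent)] = pg
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors: list, axis: int = 1) -> Tensor:
    """Concatenate tensors along `axis`."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, _parents=tuple(tensors), _backward=backward)


def take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of a matrix; scatter-adds the gradient back.

    The scatter uses a sparse selection matrix, which is much faster than
    ``np.add.at`` when the same rows are gathered many times.
    """
    from scipy import sparse

    idx = np.asarray(idx, dtype=np.intp)
    out_data = t.data[idx]
    n_out, n_rows = len(idx), t.data.shape[0]

    def backward(g):
        sel = sparse.csr_matrix(
            (np.ones(n_out), (idx, np.arange(n_out))), shape=(n_rows, n_out))
        return (sel @ g,)

    return Tensor(out_data, _parents=(t,), _backward=backward)


def softmax_rows(t: Tensor) -> Tensor:
    """Row-wise softmax with the standard Jacobian-vector product."""
    z = t.data - t.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        return (out_data * (g - dot),)

    return Tensor(out_data, _parents=(t,), _backward=backward)


class Adam:
    """Adam optimizer over a list of parameter tensors (full-batch use)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
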