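"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The neural components of this package (message-passing network, transformer
encoder, contrastive projection head) are small enough that a compact
tape-based engine in float64 is sufficient and keeps the package free of a
deep-learning framework dependency.  Only the operations those models need
are implemented; all of them are exact (no fused approximations), so
gradients can be verified against finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "take_rows",
    "scatter_sum",
    "softmax",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "GRUCell",
    "MultiheadSelfAttention",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping ------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            self._accum(g)
            other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, (self, other))

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data**2))

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            a, b = self.data, other.data
            if a.ndim == 1:
                self._accum(g @ b.swapaxes(-1, -2))
            else:
                self._accum(_unbroadcast(g @ b.swapaxes(-1, -2), a.shape))
            if b.ndim == 1:
                other._accum(a.swapaxes(-1, -2) @ g)
            else:
                other._accum(_unbroadcast(a.swapaxes(-1, -2) @ g, b.shape))

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda g: self._accum(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), (self,))
        out._backward = lambda g: self._accum(g * (1.0 - out.data**2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), (self,))
        out._backward = lambda g: self._accum(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    # -- reductions / shape -----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bwd
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data)


# -- free functions --------------------------------------------------------


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bwd
    return out


def take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows along axis 0 (embedding lookup)."""
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], (t,))

    def bwd(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accum(full)

    out._backward = bwd
    return out


def scatter_sum(src: Tensor, index: np.ndarray, n: int) -> Tensor:
    """Sum rows of `src` into `n` output rows as given by `index` (axis 0)."""
    index = np.asarray(index)
    data = np.zeros((n,) + src.data.shape[1:])
    np.add.at(data, index, src.data)
    out = Tensor(data, (src,))
    out._backward = lambda g: src._accum(g[index])
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift treated as a constant: the softmax gradient is shift-invariant
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- layers ----------------------------------------------------------------


class Module:
    def parameters(self) -> list:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"parameter count mismatch: {len(arrays)} != {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias=True):
        self.W = Parameter(_glorot(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale=0.1):
        self.weight = Parameter(rng.normal(0.0, scale, size=(n, d)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return take_rows(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.gamma + self.beta


class GRUCell(Module):
    """Gated recurrent update shared across message-passing rounds."""

    def __init__(self, d: int, rng: np.random.Generator):
        self.Wz = Linear(d, d, rng)
        self.Uz = Linear(d, d, rng, bias=False)
        self.Wr = Linear(d, d, rng)
        self.Ur = Linear(d, d, rng, bias=False)
        self.Wh = Linear(d, d, rng)
        self.Uh = Linear(d, d, rng, bias=False)

    def __call__(self, m: Tensor, h: Tensor) -> Tensor:
        z = (self.Wz(m) + self.Uz(h)).sigmoid()
        r = (self.Wr(m) + self.Ur(h)).sigmoid()
        hc = (self.Wh(m) + self.Uh(r * h)).tanh()
        return (1.0 - z) * h + z * hc


class MultiheadSelfAttention(Module):
    """Masked multi-head self-attention over (B, T, d) inputs."""

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("hidden width must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """mask: (B, T) with 1 for real rows, 0 for padding."""
        B, T, d = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t):  # (B,T,d) -> (B,H,T,dh)
            return t.reshape(B, T, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        bias = np.where(mask[:, None, None, :] > 0, 0.0, -1e30)
        attn = softmax(logits + Tensor(bias), axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.out(ctx)


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
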