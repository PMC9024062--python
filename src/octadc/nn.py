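"""Minimal reverse-mode autodiff on NumPy arrays for small CNNs.

Provides exactly the operations the restoration network needs — 2-D
convolution (stride 1, 'same' padding, computed as k*k shifted GEMMs),
batch normalization, ReLU/sigmoid, 2x2 max pooling, 2x nearest-neighbour
upsampling, channel concatenation — plus the Adam optimizer.  Feature maps
are channels-last (N, H, W, C) float32, which keeps the inner GEMM operands
contiguous and is what makes CPU training tractable.  Everything is
deterministic given the initialization seed: no threading, no
nondeterministic kernels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Adam",
    "relu",
    "sigmoid",
    "maxpool2",
    "upsample2",
    "concat_channels",
]


class Tensor:
    """Node in the dynamically built computation graph."""

    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # single-use graph: release closures, edges and intermediate grads
        # immediately so activation memory is reclaimed deterministically
        for node in topo:
            if node._backward is not None:
                node._backward = None
                node._parents = ()
                node.grad = None

    # --- scalar-friendly arithmetic (used by losses) -------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, (self, other), back)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def back(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, (self, other), back)

    def __neg__(self):
        def back(g):
            self._accumulate(-g)

        return Tensor(-self.data, (self,), back)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def sum(self):
        def back(g):
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor(self.data.sum(), (self,), back)

    def reciprocal(self):
        inv = 1.0 / self.data

        def back(g):
            self._accumulate(-g * inv * inv)

        return Tensor(inv, (self,), back)


def _unbroadcast(g, shape):
    """Reduce a gradient back to the shape it was broadcast from."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data)


class Module:
    """Base class: parameter discovery + train/eval switching."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
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

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the module state (parameters + buffers)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        current = self.state_arrays()
        if len(current) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(current, state):
            if dst.shape != src.shape:
                raise ValueError("state shape mismatch")
            dst[...] = src


class Conv2d(Module):
    """Stride-1 same-padding convolution, He-normal init, weights (k,k,C,O)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Parameter(rng.normal(0.0, std, size=(k, k, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        n, h, w, c = x.shape
        k, pad = self.k, self.k // 2
        wt = self.weight.data
        if pad:
            xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        else:
            xp = x.data
        out = np.empty((n, h, w, self.c_out), dtype=np.float32)
        out[...] = self.bias.data
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ wt[i, j]
        weight, bias = self.weight, self.bias

        def back(g):
            gm = g.reshape(-1, self.c_out)
            bias._accumulate(gm.sum(axis=0))
            dw = np.empty_like(wt)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    sl = xp[:, i : i + h, j : j + w, :].reshape(-1, c)
                    dw[i, j] = sl.T @ gm
                    dxp[:, i : i + h, j : j + w, :] += g @ wt[i, j].T
            weight._accumulate(dw)
            x._accumulate(dxp[:, pad : pad + h, pad : pad + w, :] if pad else dxp)

        return Tensor(out, (x,), back)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0, 1, 2)
        if self.training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x.data - mean) / std
        out = self.gamma.data * xhat + self.beta.data
        gamma, beta = self.gamma, self.beta
        training = self.training

        def back(g):
            gamma._accumulate((g * xhat).sum(axis=axes))
            beta._accumulate(g.sum(axis=axes))
            gs = gamma.data / std
            if training:
                mean_g = g.mean(axis=axes)
                mean_gx = (g * xhat).mean(axis=axes)
                x._accumulate(gs * (g - mean_g - xhat * mean_gx))
            else:
                x._accumulate(gs * g)

        return Tensor(out, (x,), back)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        x._accumulate(g * mask)

    return Tensor(x.data * mask, (x,), back)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -30.0, 30.0)))

    def back(g):
        x._accumulate(g * y * (1.0 - y))

    return Tensor(y, (x,), back)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (spatial dims must be even)."""
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    xr = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    flat = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
    idx = flat.argmax(axis=3)
    out = np.take_along_axis(flat, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def back(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
        dx = dflat.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        x._accumulate(dx.reshape(n, h, w, c))

    return Tensor(out, (x,), back)


def upsample2(x: Tensor) -> Tensor:
    """2x nearest-neighbour upsampling."""
    out = x.data.repeat(2, axis=1).repeat(2, axis=2)

    def back(g):
        n, h2, w2, c = g.shape
        dx = g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))
        x._accumulate(dx)

    return Tensor(out, (x,), back)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    sizes = [t.shape[-1] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=-1)
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=-1)):
            t._accumulate(piece)

    return Tensor(out, tuple(tensors), back)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Parameter], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
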