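"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the small convolutional translation networks
on a CPU: a Tensor with a backward tape, 2-D convolution via im2col,
pointwise nonlinearities, reductions, and an Adam optimiser.  Kept
deliberately tiny — no broadcasting rules beyond what the networks use.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "leaky_relu", "relu", "tanh", "add", "sub", "scale", "abs_", "square", "mean", "add_scalar", "Adam"]


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into every ancestor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def build(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                build(p)
            topo.append(t)

        build(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def back():
        a.grad += out.grad
        b.grad += out.grad

    out._backward = back
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))

    def back():
        a.grad += out.grad
        b.grad -= out.grad

    out._backward = back
    return out


def scale(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * s, (a,))

    def back():
        a.grad += s * out.grad

    out._backward = back
    return out


def add_scalar(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data + s, (a,))

    def back():
        a.grad += out.grad

    out._backward = back
    return out


def abs_(a: Tensor) -> Tensor:
    out = Tensor(np.abs(a.data), (a,))

    def back():
        a.grad += np.sign(a.data) * out.grad

    out._backward = back
    return out


def square(a: Tensor) -> Tensor:
    out = Tensor(a.data**2, (a,))

    def back():
        a.grad += 2.0 * a.data * out.grad

    out._backward = back
    return out


def mean(a: Tensor) -> Tensor:
    out = Tensor(a.data.mean(), (a,))

    def back():
        a.grad += out.grad / a.data.size

    out._backward = back
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def back():
        a.grad += (a.data > 0) * out.grad

    out._backward = back
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    out = Tensor(np.where(a.data > 0, a.data, slope * a.data), (a,))

    def back():
        a.grad += np.where(a.data > 0, 1.0, slope) * out.grad

    out._backward = back
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))

    def back():
        a.grad += (1.0 - t * t) * out.grad

    out._backward = back
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation): x (N,C,H,W), w (F,C,k,k), b (F,)."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    F, _, k, _ = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xd
    OH = (H + 2 * pad - k) // stride + 1
    OW = (W + 2 * pad - k) // stride + 1
    sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    sw = sw[:, :, ::stride, ::stride]  # (N, C, OH, OW, k, k)
    cols = sw.transpose(0, 2, 3, 1, 4, 5).reshape(N, OH * OW, C * k * k)
    out_d = cols @ wd.reshape(F, -1).T + b.data  # (N, OH*OW, F)
    out = Tensor(out_d.transpose(0, 2, 1).reshape(N, F, OH, OW), (x, w, b))

    def back():
        g = out.grad.reshape(N, F, OH * OW).transpose(0, 2, 1)  # (N, OH*OW, F)
        w.grad += np.einsum("nif,nic->fc", g, cols).reshape(wd.shape)
        b.grad += g.sum(axis=(0, 1))
        dcols = g @ wd.reshape(F, -1)  # (N, OH*OW, C*k*k)
        dsw = dcols.reshape(N, OH, OW, C, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + stride * OH : stride, j : j + stride * OW : stride] += dsw[..., i, j]
        x.grad += dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp

    out._backward = back
    return out


class Adam:
    """Adam with the (0.5, 0.999) betas conventional for adversarial training."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
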