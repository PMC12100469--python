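"""A small reverse-mode autodiff engine for 3D convolutional networks.

Just enough machinery for the dose-conversion network: tensors with a
backward tape, 3D convolutions (stride 1 and 2), ReLU, 2x max-pooling,
nearest-neighbour 2x upsampling, channel concatenation, an MSE loss and an
Adam optimizer.  Layout is channels-last, ``(N, D, H, W, C)``, so every
convolution reduces to matrix multiplies over shifted views.

Everything is plain numpy and deterministic given the seeds handed to the
initialisers; gradients are exact (verified against finite differences in
the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "conv3d",
    "conv3d_stride2",
    "conv1x1",
    "relu",
    "maxpool2",
    "upsample2",
    "concat",
    "mse_loss",
    "Adam",
    "he_init",
]


class Tensor:
    """Array node in the backward tape."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Reverse-accumulate gradients from this (scalar) node."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t.backward_fn is not None and t.grad is not None:
                t.backward_fn(t.grad)

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad += g


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def he_init(rng: np.random.Generator, shape, fan_in, dtype=np.float32):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def _conv3d_core(x: Tensor, weight: Parameter, bias: Parameter,
                 stride: int) -> Tensor:
    """3x3x3 convolution (pad 1) as one GEMM on the padded volume.

    The padded input is multiplied once by all 27 taps stacked column-wise,
    then the 27 shifted views of the product are summed; this trades ~40%
    extra FLOPs (the padded border) for avoiding 27 sub-volume copies,
    which dominate on CPU.  ``weight`` has shape (27, Cin, Cout).
    """
    X = x.data
    N, D, H, W, C = X.shape
    K, Ci, Co = weight.data.shape
    assert K == 27 and Ci == C, (weight.data.shape, X.shape)
    if stride == 2 and (D % 2 or H % 2 or W % 2):
        raise ValueError(f"stride-2 conv needs even spatial dims, got {(D, H, W)}")
    Do, Ho, Wo = D // stride, H // stride, W // stride
    Xp = np.pad(X, ((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    P = Xp.reshape(-1, C)
    Wall = np.ascontiguousarray(weight.data.transpose(1, 0, 2)).reshape(C, 27 * Co)
    G = (P @ Wall).reshape(N, D + 2, H + 2, W + 2, 27, Co)
    out = np.broadcast_to(bias.data, (N, Do, Ho, Wo, Co)).copy()
    for k, (dz, dy, dx) in enumerate(_OFFSETS):
        out += G[:, dz:dz + stride * Do:stride, dy:dy + stride * Ho:stride,
                 dx:dx + stride * Wo:stride, k, :]

    def backward(g):
        gG = np.zeros((N, D + 2, H + 2, W + 2, 27, Co), dtype=g.dtype)
        for k, (dz, dy, dx) in enumerate(_OFFSETS):
            gG[:, dz:dz + stride * Do:stride, dy:dy + stride * Ho:stride,
               dx:dx + stride * Wo:stride, k, :] = g
        gG_flat = gG.reshape(-1, 27 * Co)
        if weight.requires_grad:
            gWall = P.T @ gG_flat
            weight.accumulate(gWall.reshape(C, 27, Co).transpose(1, 0, 2))
        if bias.requires_grad:
            bias.accumulate(g.reshape(-1, Co).sum(axis=0))
        if x.requires_grad or x.backward_fn is not None or x.parents:
            gXp = (gG_flat @ Wall.T).reshape(Xp.shape)
            x.accumulate(gXp[:, 1:-1, 1:-1, 1:-1, :])

    return Tensor(out, parents=(x, weight, bias), backward_fn=backward)


def conv3d(x: Tensor, weight: Parameter, bias: Parameter) -> Tensor:
    """3x3x3 same-padding convolution; ``weight`` has shape (27, Cin, Cout)."""
    return _conv3d_core(x, weight, bias, stride=1)


def conv3d_stride2(x: Tensor, weight: Parameter, bias: Parameter) -> Tensor:
    """3x3x3 convolution with stride 2 (pad 1); spatial dims must be even."""
    return _conv3d_core(x, weight, bias, stride=2)


def conv1x1(x: Tensor, weight: Parameter, bias: Parameter) -> Tensor:
    """Pointwise convolution; ``weight`` has shape (Cin, Cout)."""
    X = x.data
    C = X.shape[-1]
    Ci, Co = weight.data.shape
    assert Ci == C
    out = X.reshape(-1, C) @ weight.data + bias.data
    out = out.reshape(X.shape[:-1] + (Co,))

    def backward(g):
        gf = g.reshape(-1, Co)
        if weight.requires_grad:
            weight.accumulate(X.reshape(-1, C).T @ gf)
        if bias.requires_grad:
            bias.accumulate(gf.sum(axis=0))
        x.accumulate((gf @ weight.data.T).reshape(X.shape))

    return Tensor(out, parents=(x, weight, bias), backward_fn=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, 0)

    def backward(g):
        x.accumulate(g * mask)

    return Tensor(out, parents=(x,), backward_fn=backward)


def maxpool2(x: Tensor) -> Tensor:
    X = x.data
    N, D, H, W, C = X.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    r = X.reshape(N, D // 2, 2, H // 2, 2, W // 2, 2, C)
    out = r.max(axis=(2, 4, 6))

    def backward(g):
        mask = r == out[:, :, None, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4, 6), keepdims=True)
        gx = mask * (g[:, :, None, :, None, :, None, :] / counts)
        x.accumulate(gx.reshape(X.shape))

    return Tensor(out, parents=(x,), backward_fn=backward)


def upsample2(x: Tensor) -> Tensor:
    X = x.data
    out = X.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        N, D2, H2, W2, C = g.shape
        gx = g.reshape(N, D2 // 2, 2, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4, 6))
        x.accumulate(gx)

    return Tensor(out, parents=(x,), backward_fn=backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel (last) axis."""
    out = np.concatenate([t.data for t in tensors], axis=-1)
    splits = np.cumsum([t.data.shape[-1] for t in tensors])[:-1]

    def backward(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=-1)):
            t.accumulate(gpart)

    return Tensor(out, parents=tuple(tensors), backward_fn=backward)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    n = diff.size
    out = np.asarray((diff**2).sum() / n, dtype=np.float64)

    def backward(g):
        pred.accumulate((2.0 / n) * diff * g)

    return Tensor(out, parents=(pred,), backward_fn=backward)


class Adam:
    """Adam with the standard bias-corrected moments."""

    def __init__(self, params: list[Parameter], lr=1e-3, betas=(0.9, 0.999),
                 eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data = (
                p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
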