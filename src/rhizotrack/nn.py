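"""Minimal tape-based autograd on numpy arrays for the segmentation network.

Supports exactly the operations the encoder-decoder needs: 2-D convolution
with stride and dilation (same padding), ReLU, channel concatenation,
sub-pixel upsampling (pixel shuffle) and a combined cross-entropy + Dice
segmentation loss, plus an Adam optimizer.  Tensors record a backward
closure; ``backward()`` walks the tape in reverse topological order.

Array layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "conv2d", "relu", "concat", "pixel_shuffle",
    "bce_dice_loss", "sigmoid", "Adam", "he_init",
]


class Tensor:
    """An array plus an accumulated gradient and a backward closure."""

    __slots__ = ("data", "grad", "_backward", "_parents", "name")

    def __init__(self, data: np.ndarray, parents: tuple = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self._backward = lambda: None
        self._parents = parents
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def backward(self) -> None:
        """Reverse-mode sweep seeding d(self)/d(self) = 1."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            t._backward()


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col(xp: np.ndarray, k: int, stride: int, dilation: int) -> np.ndarray:
    keff = dilation * (k - 1) + 1
    v = sliding_window_view(xp, (keff, keff), axis=(2, 3))
    return v[:, :, ::stride, ::stride, ::dilation, ::dilation]


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, dilation: int = 1) -> Tensor:
    """Same-padded 2-D convolution; ``w`` has shape (C_out, C_in, k, k).

    With stride s the output is ceil(H/s) x ceil(W/s); H and W are assumed
    divisible by the stride (the training patches and padded tiles are).
    """
    n, c, h, wd = x.data.shape
    co, ci, k, _ = w.data.shape
    assert ci == c, f"channel mismatch {ci} != {c}"
    keff = dilation * (k - 1) + 1
    ho, wo = -(-h // stride), -(-wd // stride)
    pad_h = max((ho - 1) * stride + keff - h, 0)
    pad_w = max((wo - 1) * stride + keff - wd, 0)
    pt, pl = pad_h // 2, pad_w // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pad_h - pt), (pl, pad_w - pl)))
    cols = _im2col(xp, k, stride, dilation)[:, :, :ho, :wo]
    out_data = np.einsum("ncxyij,ocij->noxy", cols, w.data, optimize=True)
    out_data += b.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, w, b))

    def _backward() -> None:
        gy = out.grad
        w.grad += np.einsum("ncxyij,noxy->ocij", cols, gy, optimize=True)
        b.grad += gy.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gi = np.einsum("noxy,oc->ncxy", gy, w.data[:, :, i, j], optimize=True)
                gxp[
                    :, :,
                    i * dilation : i * dilation + stride * ho : stride,
                    j * dilation : j * dilation + stride * wo : stride,
                ] += gi
        x.grad += gxp[:, :, pt : pt + h, pl : pl + wd]

    out._backward = _backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def _backward() -> None:
        x.grad += out.grad * (x.data > 0)

    out._backward = _backward
    return out


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), parents=tuple(tensors))

    def _backward() -> None:
        i = 0
        for t in tensors:
            c = t.data.shape[1]
            t.grad += out.grad[:, i : i + c]
            i += c

    out._backward = _backward
    return out


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Sub-pixel upsampling: (N, r^2*C, H, W) -> (N, C, r*H, r*W).

    A pure reshape/transpose, so the upsampled map is built from learned
    channels instead of interpolation.
    """
    n, c2, h, w = x.data.shape
    assert c2 % (r * r) == 0, "channels must be divisible by r^2"
    c = c2 // (r * r)
    d = x.data.reshape(n, c, r, r, h, w)
    out_data = d.transpose(0, 1, 4, 2, 5, 3).reshape(n, c, h * r, w * r)
    out = Tensor(out_data, parents=(x,))

    def _backward() -> None:
        g = out.grad.reshape(n, c, h, r, w, r)
        x.grad += g.transpose(0, 1, 3, 5, 2, 4).reshape(n, c2, h, w)

    out._backward = _backward
    return out


def bce_dice_loss(
    logits: Tensor, target: np.ndarray, w_bce: float = 1.0, w_dice: float = 1.0
) -> Tensor:
    """Pixel-wise binary cross-entropy plus soft-Dice loss.

    ``target`` is a {0,1} array of the same shape as ``logits``.
    """
    z = logits.data
    y = np.asarray(target, dtype=np.float64)
    p = sigmoid(z)
    npix = z.size
    # numerically stable BCE on logits
    bce = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    eps = 1.0
    inter = float((p * y).sum())
    total = float(p.sum() + y.sum())
    dice = 1.0 - (2.0 * inter + eps) / (total + eps)
    out = Tensor(np.array(w_bce * bce + w_dice * dice), parents=(logits,))

    def _backward() -> None:
        g = float(out.grad)
        d_bce = (p - y) / npix
        d_dice_dp = -(2.0 * y * (total + eps) - (2.0 * inter + eps)) / (total + eps) ** 2
        d_dice = d_dice_dp * p * (1.0 - p)
        logits.grad += g * (w_bce * d_bce + w_dice * d_dice)

    out._backward = _backward
    return out


class Adam:
    """Standard Adam over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
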