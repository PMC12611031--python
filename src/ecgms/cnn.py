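"""A compact seeded NumPy convolutional network for raw ECG window classification.

Architecture (10 layers): input -> conv(100 filters, 5x5) -> ReLU -> 2-D max
pool -> conv(100 filters, 8x8) -> ReLU -> 2-D max pool -> fully connected ->
softmax -> 2-class output.  Each window is presented as a single-channel
(n_leads x window_length) matrix; convolution kernels and pool windows are
clipped to the input extent, so with 2-lead input the lead dimension
degenerates gracefully (effective kernels 2x5, then 1x8).

Training is plain stochastic gradient descent with momentum, a step
learning-rate schedule lr(e) = initial_lr * drop_factor^floor((e-1)/period),
L2 weight decay, fixed epoch budget and mini-batches — all defaults as in
:class:`CNNSpec`.  Weights use seeded He-style initialisation; given the same
seed, training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNSpec", "NumpyCNN"]


@dataclass(frozen=True)
class CNNSpec:
    """Hyperparameters of the window classifier network."""

    conv1_filters: int = 100
    conv1_kernel: tuple[int, int] = (5, 5)
    conv2_filters: int = 100
    conv2_kernel: tuple[int, int] = (8, 8)
    pool: tuple[int, int] = (2, 2)
    pool_stride: int = 2
    initial_lr: float = 1e-4
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 8
    l2: float = 4e-4
    max_epochs: int = 5
    batch_size: int = 30
    momentum: float = 0.9
    #: input presentation: windows are zero-centred with the training-set
    #: mean and expressed in ADC units (adu) at this gain, mirroring 16-bit
    #: acquisition front-ends; amplitude contrasts between groups are
    #: preserved (no per-window normalisation)
    input_gain: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "conv1_filters",
            "conv2_filters",
            "pool_stride",
            "initial_lr",
            "lr_drop_factor",
            "lr_drop_period",
            "l2",
            "max_epochs",
            "batch_size",
            "momentum",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return (
            "input",
            "conv1",
            "relu1",
            "maxpool1",
            "conv2",
            "relu2",
            "maxpool2",
            "fc",
            "softmax",
            "output",
        )

    def learning_rate(self, epoch: int) -> float:
        """lr for a 1-based epoch number under the step-drop schedule."""
        if epoch < 1:
            raise ValueError("epochs are 1-based")
        return self.initial_lr * self.lr_drop_factor ** ((epoch - 1) // self.lr_drop_period)


def _clip_kernel(kernel: tuple[int, int], shape: tuple[int, int]) -> tuple[int, int]:
    return (min(kernel[0], shape[0]), min(kernel[1], shape[1]))


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H2*W2, C*kh*kw) valid-convolution patches."""
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (N, C, H2, W2, kh, kw)
    n, c, h2, w2 = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h2 * w2, c * kh * kw), (h2, w2)


class _Conv:
    def __init__(self, c_in: int, filters: int, kernel: tuple[int, int], rng: np.random.Generator):
        kh, kw = kernel
        fan_in = c_in * kh * kw
        self.w = (rng.standard_normal((filters, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(filters, dtype=np.float32)
        self.kernel = kernel
        self.c_in = c_in

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x_shape = x.shape
        self.patches, (h2, w2) = _im2col(x, *self.kernel)
        out = self.patches @ self.w.T + self.b
        return out.transpose(0, 2, 1).reshape(x.shape[0], self.w.shape[0], h2, w2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, h2, w2 = dout.shape
        dflat = dout.reshape(n, f, h2 * w2).transpose(0, 2, 1)  # (N, L, F)
        self.dw = np.einsum("nlf,nlk->fk", dflat, self.patches, optimize=True)
        self.db = dflat.sum(axis=(0, 1))
        dpatch = dflat @ self.w  # (N, L, C*kh*kw)
        kh, kw = self.kernel
        dpr = dpatch.reshape(n, h2, w2, self.c_in, kh, kw)
        dx = np.zeros(self.x_shape, dtype=np.float32)
        for a in range(kh):
            for b in range(kw):
                dx[:, :, a : a + h2, b : b + w2] += dpr[:, :, :, :, a, b].transpose(0, 3, 1, 2)
        return dx


class _MaxPool:
    """2-D max pooling with windows clipped at the input boundary."""

    def __init__(self, pool: tuple[int, int], stride: int):
        self.pool = pool
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        ph, pw = self.pool
        s = self.stride
        h_out = max(1, -(-h // s))
        w_out = max(1, -(-w // s))
        out = np.empty((n, c, h_out, w_out), dtype=x.dtype)
        self.argmax = np.empty((n, c, h_out, w_out, 2), dtype=np.int32)
        self.x_shape = x.shape
        for i in range(h_out):
            for j in range(w_out):
                hi0, wj0 = i * s, j * s
                win = x[:, :, hi0 : min(h, hi0 + ph), wj0 : min(w, wj0 + pw)]
                wh, ww = win.shape[2], win.shape[3]
                flat = win.reshape(n, c, wh * ww)
                idx = flat.argmax(axis=2)
                out[:, :, i, j] = np.take_along_axis(flat, idx[:, :, None], axis=2)[:, :, 0]
                self.argmax[:, :, i, j, 0] = hi0 + idx // ww
                self.argmax[:, :, i, j, 1] = wj0 + idx % ww
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h_out, w_out = dout.shape
        dx = np.zeros(self.x_shape, dtype=np.float32)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        for i in range(h_out):
            for j in range(w_out):
                hi = self.argmax[:, :, i, j, 0]
                wj = self.argmax[:, :, i, j, 1]
                np.add.at(dx, (ni, ci, hi, wj), dout[:, :, i, j])
        return dx


class NumpyCNN:
    """The 10-layer window classifier; fit/predict over (N, H, W) arrays."""

    def __init__(self, spec: CNNSpec | None = None, seed: int = 0):
        self.spec = spec or CNNSpec()
        self.seed = int(seed)
        self._built = False

    def _build(self, h: int, w: int) -> None:
        rng = np.random.default_rng(self.seed)
        sp = self.spec
        k1 = _clip_kernel(sp.conv1_kernel, (h, w))
        self.conv1 = _Conv(1, sp.conv1_filters, k1, rng)
        h1, w1 = h - k1[0] + 1, w - k1[1] + 1
        self.pool1 = _MaxPool(sp.pool, sp.pool_stride)
        h1p, w1p = max(1, -(-h1 // sp.pool_stride)), max(1, -(-w1 // sp.pool_stride))
        k2 = _clip_kernel(sp.conv2_kernel, (h1p, w1p))
        self.conv2 = _Conv(sp.conv1_filters, sp.conv2_filters, k2, rng)
        h2, w2 = h1p - k2[0] + 1, w1p - k2[1] + 1
        self.pool2 = _MaxPool(sp.pool, sp.pool_stride)
        h2p, w2p = max(1, -(-h2 // sp.pool_stride)), max(1, -(-w2 // sp.pool_stride))
        n_flat = sp.conv2_filters * h2p * w2p
        self.fc_w = (rng.standard_normal((2, n_flat)) * np.sqrt(2.0 / n_flat)).astype(np.float32)
        self.fc_b = np.zeros(2, dtype=np.float32)
        self._vel = {k: 0.0 for k in ("c1w", "c1b", "c2w", "c2b", "fw", "fb")}
        self._built = True

    def _forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.conv1.forward(x)
        self._m1 = a > 0
        a = a * self._m1
        a = self.pool1.forward(a)
        a = self.conv2.forward(a)
        self._m2 = a > 0
        a = a * self._m2
        a = self.pool2.forward(a)
        self._flat_shape = a.shape
        flat = a.reshape(a.shape[0], -1)
        self._flat = flat
        logits = flat @ self.fc_w.T + self.fc_b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def _backward(self, probs: np.ndarray, y_onehot: np.ndarray) -> dict:
        n = probs.shape[0]
        dlogits = (probs - y_onehot) / n
        dfw = dlogits.T @ self._flat
        dfb = dlogits.sum(axis=0)
        dflat = (dlogits @ self.fc_w).reshape(self._flat_shape).astype(np.float32)
        da = self.pool2.backward(dflat)
        da = da * self._m2
        da = self.conv2.backward(da)
        da = self.pool1.backward(da)
        da = da * self._m1
        self.conv1.backward(da)
        return {
            "c1w": self.conv1.dw,
            "c1b": self.conv1.db,
            "c2w": self.conv2.dw,
            "c2b": self.conv2.db,
            "fw": dfw,
            "fb": dfb,
        }

    def _params(self) -> dict:
        return {
            "c1w": self.conv1.w,
            "c1b": self.conv1.b,
            "c2w": self.conv2.w,
            "c2b": self.conv2.b,
            "fw": self.fc_w,
            "fb": self.fc_b,
        }

    def fit(self, x: np.ndarray, y: np.ndarray) -> "NumpyCNN":
        """Train on windows ``x`` of shape (N, H, W) with binary labels."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3:
            raise ValueError("x must be (n_windows, n_leads, window_length)")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("need exactly 2 classes")
        yi = np.searchsorted(self.classes_, y)
        sp = self.spec
        self._mean = x.mean(axis=0, keepdims=True)
        xz = (x - self._mean) * sp.input_gain
        xz = xz[:, None, :, :]  # single channel
        n, _, h, w = xz.shape
        if not self._built:
            self._build(h, w)
        rng = np.random.default_rng(self.seed + 1)
        onehot = np.eye(2, dtype=np.float32)[yi]
        for epoch in range(1, sp.max_epochs + 1):
            lr = self.spec.learning_rate(epoch)
            order = rng.permutation(n)
            for start in range(0, n, sp.batch_size):
                sel = order[start : start + sp.batch_size]
                probs = self._forward(xz[sel], train=True)
                grads = self._backward(probs, onehot[sel])
                params = self._params()
                for key, g in grads.items():
                    g = g + sp.l2 * params[key]
                    self._vel[key] = sp.momentum * self._vel[key] - lr * g
                    params[key] += self._vel[key].astype(np.float32)
        return self

    def predict_proba(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        xz = ((x - self._mean) * self.spec.input_gain)[:, None, :, :]
        out = [self._forward(xz[i : i + batch]) for i in range(0, len(xz), batch)]
        return np.vstack(out) if out else np.empty((0, 2))

    def predict(self, x: np.ndarray) -> np.ndarray:
        if len(x) == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.classes_[self.predict_proba(x).argmax(axis=1)]
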