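"""Minimal deterministic neural-network layers (NumPy, float32).

Forward/backward passes are written out explicitly so that training is
bitwise-reproducible under a seed on any BLAS: all randomness flows through
one ``numpy.random.Generator`` and no threading-dependent reductions are
introduced beyond BLAS matmuls (which are deterministic for a fixed build).

Conventions: activations are ``(batch, length, channels)`` float32 arrays;
every layer owns its parameters/gradients in ``params``/``grads`` dicts and
caches whatever the backward pass needs on ``self``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base class: parameter-free layers leave ``params`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Conv1d(Layer):
    """Same-padded 1-D convolution via an im2col matmul.

    Weight layout is ``(kernel * c_in, c_out)`` with the kernel axis slowest,
    matching the ``(batch, length, kernel, c_in)`` window tensor.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("odd kernels only (same padding)")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params = {
            "W": _he_init(rng, kernel * c_in, (kernel * c_in, c_out)),
            "b": np.zeros(c_out, dtype=F32),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, _ = x.shape
        p = self.kernel // 2
        xpad = np.pad(x, ((0, 0), (p, p), (0, 0)))
        # windows: (n, length, c_in, kernel) -> (n, length, kernel, c_in)
        win = np.lib.stride_tricks.sliding_window_view(xpad, self.kernel, axis=1)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            n * length, self.kernel * self.c_in
        )
        self._cols, self._shape = cols, (n, length)
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(n, length, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length = self._shape
        p = self.kernel // 2
        dy_flat = dy.reshape(n * length, self.c_out)
        self.grads["W"] = self._cols.T @ dy_flat
        self.grads["b"] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.params["W"].T).reshape(n, length, self.kernel, self.c_in)
        dxpad = np.zeros((n, length + 2 * p, self.c_in), dtype=F32)
        for j in range(self.kernel):
            dxpad[:, j : j + length, :] += dcols[:, :, j, :]
        self._cols = None
        return dxpad[:, p : p + length, :]


class MaxPool1d(Layer):
    """Halving max pool (factor 2, no overlap)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        if length % 2:
            raise ValueError("length must be even for factor-2 pooling")
        xr = x.reshape(n, length // 2, 2, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length, c = self._in_shape
        dx = np.zeros((n, length // 2, 2, c), dtype=F32)
        np.put_along_axis(dx, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        return dx.reshape(n, length, c)


class ConvTranspose1d(Layer):
    """Stride-2, kernel-2 transposed convolution (exact x2 upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 2):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params = {
            "W": _he_init(rng, c_in, (c_in, kernel, c_out)),
            "b": np.zeros(c_out, dtype=F32),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, length, _ = x.shape
        self._x = x
        y = np.einsum("nlc,cjo->nljo", x, self.params["W"], optimize=True)
        return y.reshape(n, length * self.kernel, self.c_out) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length2, _ = dy.shape
        length = length2 // self.kernel
        dyr = dy.reshape(n, length, self.kernel, self.c_out)
        self.grads["W"] = np.einsum("nlc,nljo->cjo", self._x, dyr, optimize=True)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dx = np.einsum("nljo,cjo->nlc", dyr, self.params["W"], optimize=True)
        self._x = None
        return dx.astype(F32, copy=False)


class NearestUp(Layer):
    """Parameter-free nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, 2, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, length2, c = dy.shape
        return dy.reshape(n, length2 // 2, 2, c).sum(axis=2)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.params = {
            "W": _he_init(rng, d_in, (d_in, d_out)),
            "b": np.zeros(d_out, dtype=F32),
        }

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, F32(0))
        self._mask = None
        return dx


class LeakyReLU(Layer):
    """Rectifier with a small negative-side slope.

    Used at the dense bottleneck, whose inputs (pooled rectified maps) are
    all non-negative: with a hard rectifier the sign-coherent weight
    updates there can push every pre-activation negative within a few
    optimizer steps and the feature layer never recovers; the leak keeps a
    gradient path open.
    """

    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = F32(alpha)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.alpha * dy)
        self._mask = None
        return dx


class Adam:
    """Adaptive-moment optimizer with the standard defaults (step 1e-3,
    moment decays 0.9 / 0.999, epsilon 1e-8)."""

    def __init__(
        self,
        layers: list[Layer],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k].astype(F32, copy=False)
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= (self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)).astype(F32)


def get_state(layers: list[Layer]) -> list[dict[str, np.ndarray]]:
    return [{k: v.copy() for k, v in l.params.items()} for l in layers]


def set_state(layers: list[Layer], state: list[dict[str, np.ndarray]]) -> None:
    for layer, params in zip(layers, state):
        for k in layer.params:
            layer.params[k][...] = params[k]
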