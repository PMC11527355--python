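"""Minimal volumetric neural-network engine with explicit backward passes.

Every layer implements ``forward`` and ``backward`` by hand so that the
gradient of the scalar regression output with respect to the *input volume*
— the quantity every attribution method consumes — is available exactly,
and so that modified backward rules (guided backpropagation's ReLU gating,
Grad-CAM's layer-activation gradients) are first-class operations rather
than framework hooks.

Conventions
-----------
* Volumetric activations are ``(N, C, D, H, W)`` float64 arrays.
* Convolutions are stride-1 with 'same' zero padding (asymmetric for even
  kernels, smaller pad on the low side).
* ``Sequential.backward`` propagates an upstream gradient from the scalar
  head back to the input; with ``guided=True`` every ReLU additionally
  zeroes gradient entries that are negative or whose forward activation
  was non-positive.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

__all__ = [
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: a differentiable operation with optional parameters."""

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray, *, guided: bool = False) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> Dict[str, np.ndarray]:
        return {}

    def grads(self) -> Dict[str, np.ndarray]:
        return {}


@njit(cache=True, fastmath=True)
def _conv3d_correlate(xp, w, size):  # pragma: no cover - exercised via Conv3d
    """out[n,o,·] = Σ_c Σ_q w[o,c,q] · xp[n,c,·+q] over a ``size``³ grid."""
    n_batch, n_in = xp.shape[0], xp.shape[1]
    n_out, k = w.shape[0], w.shape[2]
    out = np.zeros((n_batch, n_out, size, size, size))
    for n in range(n_batch):
        for o in range(n_out):
            for c in range(n_in):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            wv = w[o, c, i, j, l]
                            if wv == 0.0:
                                continue
                            for d in range(size):
                                for h in range(size):
                                    for v in range(size):
                                        out[n, o, d, h, v] += wv * xp[n, c, d + i, h + j, v + l]
    return out


@njit(cache=True, fastmath=True)
def _conv3d_grad_w(xp, grad):  # pragma: no cover - exercised via Conv3d
    """gw[o,c,q] = Σ_n Σ_p grad[n,o,p] · xp[n,c,p+q]."""
    n_batch, n_in = xp.shape[0], xp.shape[1]
    n_out, size = grad.shape[1], grad.shape[2]
    k = xp.shape[2] - size + 1
    gw = np.zeros((n_out, n_in, k, k, k))
    for n in range(n_batch):
        for o in range(n_out):
            for c in range(n_in):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            acc = 0.0
                            for d in range(size):
                                for h in range(size):
                                    for v in range(size):
                                        acc += grad[n, o, d, h, v] * xp[n, c, d + i, h + j, v + l]
                            gw[o, c, i, j, l] += acc
    return gw


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding.

    Weight shape is ``(out_channels, in_channels, k, k, k)``; initialization
    is He-normal scaled by fan-in, drawn from the supplied generator. The
    three inner loops (forward correlation, weight gradient, input
    gradient) are JIT-compiled.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.k = kernel
        fan_in = in_channels * kernel ** 3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kernel, kernel, kernel))
        self.b = np.zeros(out_channels)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: Optional[np.ndarray] = None

    def _pads(self) -> Tuple[int, int]:
        lo = (self.k - 1) // 2
        return lo, self.k - 1 - lo

    def forward(self, x, *, training=False):
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (N,{self.in_channels},D,H,W), got {x.shape}")
        if min(x.shape[2:]) < 1:
            raise ValueError("empty spatial extent")
        lo, hi = self._pads()
        pad = ((0, 0), (0, 0), (lo, hi), (lo, hi), (lo, hi))
        xp = np.ascontiguousarray(np.pad(x, pad).astype(float))
        self._xp = xp
        out = _conv3d_correlate(xp, self.w, x.shape[2])
        return out + self.b[None, :, None, None, None]

    def backward(self, grad, *, guided=False):
        if self._xp is None:
            raise RuntimeError("backward before forward")
        k = self.k
        grad = np.ascontiguousarray(grad.astype(float))
        self.gw = _conv3d_grad_w(self._xp, grad)
        self.gb = grad.sum(axis=(0, 2, 3, 4))
        # gradient w.r.t. the padded input is a full correlation of the
        # upstream gradient with the spatially flipped, transposed kernel
        gp = np.ascontiguousarray(
            np.pad(grad, ((0, 0), (0, 0)) + ((k - 1, k - 1),) * 3))
        wT = np.ascontiguousarray(
            self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        gxp = _conv3d_correlate(gp, wT, self._xp.shape[2])
        lo, hi = self._pads()
        d = self._xp.shape[2] - lo - hi
        return gxp[:, :, lo:lo + d, lo:lo + d, lo:lo + d]

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x, *, training=False):
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv[None, :, None, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]

    def backward(self, grad, *, guided=False):
        xhat, inv, training, shape = self._cache
        axes = (0, 2, 3, 4)
        self.ggamma = (grad * xhat).sum(axis=axes)
        self.gbeta = grad.sum(axis=axes)
        gsc = self.gamma[None, :, None, None, None] * inv[None, :, None, None, None]
        if not training:
            return grad * gsc
        gmean = grad.mean(axis=axes)[None, :, None, None, None]
        gdot = (grad * xhat).mean(axis=axes)[None, :, None, None, None]
        return gsc * (grad - gmean - xhat * gdot)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.ggamma, "beta": self.gbeta}


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, *, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad, *, guided=False):
        g = np.where(self._mask, grad, 0.0)
        if guided:
            g = np.where(g > 0, g, 0.0)
        return g


class MaxPool3d(Layer):
    """Non-overlapping max pooling; spatial dims must divide the kernel."""

    def __init__(self, kernel: int = 2):
        self.k = kernel
        self._cache = None

    def forward(self, x, *, training=False):
        p = self.k
        n, c, d, h, w = x.shape
        if d % p or h % p or w % p:
            raise ValueError(f"spatial dims {x.shape[2:]} not divisible by pool kernel {p}")
        blocks = (x.reshape(n, c, d // p, p, h // p, p, w // p, p)
                   .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                   .reshape(n, c, d // p, h // p, w // p, p ** 3))
        arg = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape)
        return out

    def backward(self, grad, *, guided=False):
        arg, shape = self._cache
        p = self.k
        n, c, d, h, w = shape
        gb = np.zeros((n, c, d // p, h // p, w // p, p ** 3))
        np.put_along_axis(gb, arg[..., None], grad[..., None], axis=-1)
        return (gb.reshape(n, c, d // p, h // p, w // p, p, p, p)
                  .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                  .reshape(n, c, d, h, w))


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, *, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad, *, guided=False):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, *, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad, *, guided=False):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def forward(self, x, *, training=False):
        if x.ndim != 2 or x.shape[1] != self.w.shape[0]:
            raise ValueError(f"expected (N,{self.w.shape[0]}), got {x.shape}")
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad, *, guided=False):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.gw, "b": self.gb}


class Sequential:
    """An ordered chain of layers with capture points for Grad-CAM.

    ``forward`` caches each layer's output in ``activations`` so that the
    feature map of any intermediate (e.g. the final convolutional) layer is
    retrievable; ``backward`` records the gradient flowing into each
    layer's output in ``output_grads`` for the same reason.
    """

    def __init__(self, layers: Sequence[Layer]):
        self.layers: List[Layer] = list(layers)
        self.activations: List[np.ndarray] = []
        self.output_grads: List[Optional[np.ndarray]] = []

    def forward(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        self.activations = []
        for layer in self.layers:
            x = layer.forward(x, training=training)
            self.activations.append(x)
        return x

    def __call__(self, x: np.ndarray, *, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    def backward(self, grad: np.ndarray, *, guided: bool = False) -> np.ndarray:
        self.output_grads = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, -1, -1):
            self.output_grads[i] = grad
            grad = self.layers[i].backward(grad, guided=guided)
        return grad

    # -- parameter bookkeeping -------------------------------------------
    def named_params(self) -> Dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def named_grads(self) -> Dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, g in layer.grads().items():
                out[f"{i}.{name}"] = g
        return out

    def num_params(self) -> int:
        n = sum(p.size for p in self.named_params().values())
        # running batch-norm statistics are state, not parameters
        return n

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.named_params().items()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm3d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = self.named_params()
        for key, value in state.items():
            if key in params:
                params[key][...] = value
            else:
                idx, name = key.split(".", 1)
                setattr(self.layers[int(idx)], name, value.copy())


class Adam:
    """Adam optimizer over a Sequential's named parameters."""

    def __init__(self, model: Sequential, lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.named_params().items()}
        self.v = {k: np.zeros_like(v) for k, v in model.named_params().items()}

    def step(self) -> None:
        self.t += 1
        params = self.model.named_params()
        grads = self.model.named_grads()
        for key, p in params.items():
            g = grads[key]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
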