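"""Seven attribution-based saliency methods for volumetric regressors.

All methods share one contract: a :class:`~neurosal.nn.Sequential`
regressor plus a 3D input volume in, a signed voxelwise attribution field
of the same shape out. Signs are preserved here; absolute value and
normalization to a probability density happen later (see
:mod:`neurosal.simmetrics`).

Methods
-------
G      plain gradient of the scalar output w.r.t. the input
IXG    input ⊙ gradient
MG     gradient zeroed outside a brain mask (default: nonzero support of
       the skull-stripped input)
GB     guided backpropagation — every ReLU backward pass additionally
       zeroes negative gradient entries (and entries whose forward
       activation was non-positive)
GGC    guided Grad-CAM — channel-weighted, ReLU-rectified activation of
       the final convolutional layer, trilinearly upsampled and
       multiplied voxelwise with GB
IG     integrated gradients along the straight path from a baseline,
       Gauss–Legendre quadrature (default 50 nodes)
GSHAP  gradient SHAP — expectation of (noisy input − baseline) ⊙ gradient
       at a uniformly random point on the baseline→noisy-input segment
       (default 5 noise draws)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .phantom import IntensityVolume

__all__ = [
    "METHODS",
    "RawAttribution",
    "AttributionOptions",
    "grad_saliency",
    "input_x_gradient",
    "masked_gradient",
    "guided_backprop",
    "guided_gradcam",
    "integrated_gradients",
    "gradient_shap",
    "compute_attribution",
]

METHODS = ("G", "IXG", "MG", "GB", "GGC", "IG", "GSHAP")


@dataclass
class RawAttribution:
    data: np.ndarray
    method: str
    options: Dict = field(default_factory=dict)

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError(f"{self.method}: attribution contains non-finite values")
        self.data = d


@dataclass(frozen=True)
class AttributionOptions:
    ig_points: int = 50
    gshap_samples: int = 5
    gshap_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.ig_points < 1:
            raise ValueError("ig_points must be >= 1")
        if self.gshap_samples < 1:
            raise ValueError("gshap_samples must be >= 1")
        if self.gshap_sigma < 0:
            raise ValueError("gshap_sigma must be >= 0")


def _vol(x) -> np.ndarray:
    data = x.data if isinstance(x, IntensityVolume) else np.asarray(x, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    return data


def _input_gradient(model: nn.Sequential, x: np.ndarray, *,
                    guided: bool = False) -> np.ndarray:
    """d(output)/d(input) for a single volume, evaluation mode."""
    out = model.forward(x[None, None], training=False)
    grad = model.backward(np.ones_like(out), guided=guided)
    return grad[0, 0]


def _batched_input_gradients(model: nn.Sequential, xs: np.ndarray) -> np.ndarray:
    """Per-sample input gradients for a batch (samples are independent,
    so one backward of the summed output gives every row's gradient)."""
    out = model.forward(xs[:, None], training=False)
    return model.backward(np.ones_like(out))[:, 0]


def grad_saliency(model: nn.Sequential, x) -> RawAttribution:
    """G — signed gradient of the estimated age w.r.t. each voxel."""
    return RawAttribution(_input_gradient(model, _vol(x)), "G")


def input_x_gradient(model: nn.Sequential, x) -> RawAttribution:
    """IXG — voxelwise product of the input with its gradient."""
    data = _vol(x)
    return RawAttribution(data * _input_gradient(model, data), "IXG")


def masked_gradient(model: nn.Sequential, x, mask: Optional[np.ndarray] = None
                    ) -> RawAttribution:
    """MG — gradient with voxels outside the brain mask zeroed.

    With no mask given, the nonzero-intensity support of the
    skull-stripped input is used.
    """
    data = _vol(x)
    if mask is None:
        mask = data != 0
    mask = np.asarray(mask)
    if mask.shape != data.shape:
        raise ValueError("mask shape must match the volume")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    return RawAttribution(_input_gradient(model, data) * (mask != 0), "MG")


def guided_backprop(model: nn.Sequential, x) -> RawAttribution:
    """GB — gradient with every ReLU passing only positive gradients at
    positive forward activations. Without any ReLU this degenerates to
    the plain gradient."""
    return RawAttribution(_input_gradient(model, _vol(x), guided=True), "GB")


def _find_last_conv(model: nn.Sequential) -> int:
    for i in range(len(model.layers) - 1, -1, -1):
        if isinstance(model.layers[i], nn.Conv3d):
            return i
    raise ValueError("model has no convolutional layer")


def guided_gradcam(model: nn.Sequential, x, target_layer: Optional[int] = None,
                   upsample: str = "trilinear") -> RawAttribution:
    """GGC — Grad-CAM at the final conv layer, refined by GB.

    The coarse map is ``ReLU(Σ_c α_c A_c)`` with ``α_c`` the spatial mean
    of the output's gradient at channel ``c`` of the target layer's
    feature map, upsampled to input shape and multiplied voxelwise with
    the guided-backpropagation field.
    """
    data = _vol(x)
    if target_layer is None:
        target_layer = _find_last_conv(model)
    if not 0 <= target_layer < len(model.layers) or \
            not isinstance(model.layers[target_layer], nn.Conv3d):
        raise ValueError(f"target_layer {target_layer} is not a convolutional layer")

    out = model.forward(data[None, None], training=False)
    acts = model.activations[target_layer]          # (1, C, d, h, w)
    model.backward(np.ones_like(out))
    grads = model.output_grads[target_layer]
    alpha = grads.mean(axis=(2, 3, 4))              # (1, C)
    cam = np.maximum((alpha[:, :, None, None, None] * acts).sum(axis=1), 0.0)[0]

    factors = np.array(data.shape) / np.array(cam.shape)
    order = 1 if upsample == "trilinear" else 0
    cam_up = ndimage.zoom(cam, factors, order=order, mode="nearest", grid_mode=True)
    if cam_up.shape != data.shape:  # guard against rounding in zoom
        raise RuntimeError(f"upsampled CAM shape {cam_up.shape} != {data.shape}")

    gb = _input_gradient(model, data, guided=True)
    return RawAttribution(cam_up * gb, "GGC", {"target_layer": target_layer})


def integrated_gradients(model: nn.Sequential, x, baseline=None,
                         n_points: int = 50) -> RawAttribution:
    """IG — path integral of the gradient from baseline to input,
    approximated by Gauss–Legendre quadrature on [0, 1]."""
    data = _vol(x)
    if baseline is None:
        base = np.zeros_like(data)
    else:
        base = _vol(baseline)
        if base.shape != data.shape:
            raise ValueError("baseline shape must match the input")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    nodes, weights = np.polynomial.legendre.leggauss(n_points)
    t = (nodes + 1.0) / 2.0          # map [-1, 1] -> [0, 1]
    w = weights / 2.0
    diff = data - base
    points = base[None] + t[:, None, None, None] * diff[None]
    grads = _batched_input_gradients(model, points)
    avg_grad = np.tensordot(w, grads, axes=1)
    return RawAttribution(diff * avg_grad, "IG",
                          {"n_points": n_points, "baseline": "zero" if baseline is None else "given"})


def gradient_shap(model: nn.Sequential, x, baselines: Sequence, n_samples: int = 5,
                  sigma: float = 0.05, rng: Optional[np.random.Generator] = None
                  ) -> RawAttribution:
    """GSHAP — Monte-Carlo expectation of (x̃ − b) ⊙ ∇f at a random point
    on the segment from a random baseline b to the noise-perturbed input
    x̃ = x + N(0, σ²)."""
    data = _vol(x)
    pool = [_vol(b) for b in baselines]
    if len(pool) == 0:
        raise ValueError("baseline pool must be nonempty")
    for b in pool:
        if b.shape != data.shape:
            raise ValueError("every baseline must match the input shape")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    acc = np.zeros_like(data)
    for _ in range(n_samples):
        noisy = data + (rng.normal(0.0, sigma, data.shape) if sigma > 0 else 0.0)
        b = pool[rng.integers(len(pool))]
        alpha = rng.random()
        point = b + alpha * (noisy - b)
        acc += (noisy - b) * _input_gradient(model, point)
    return RawAttribution(acc / n_samples, "GSHAP",
                          {"n_samples": n_samples, "sigma": sigma})


def compute_attribution(method: str, model: nn.Sequential, x,
                        options: Optional[AttributionOptions] = None,
                        baselines: Optional[Sequence] = None,
                        mask: Optional[np.ndarray] = None) -> RawAttribution:
    """Dispatch a method by name with shared options (used by the CLI)."""
    opts = options or AttributionOptions()
    if method == "G":
        return grad_saliency(model, x)
    if method == "IXG":
        return input_x_gradient(model, x)
    if method == "MG":
        return masked_gradient(model, x, mask)
    if method == "GB":
        return guided_backprop(model, x)
    if method == "GGC":
        return guided_gradcam(model, x)
    if method == "IG":
        return integrated_gradients(model, x, n_points=opts.ig_points)
    if method == "GSHAP":
        pool = baselines if baselines is not None else [np.zeros_like(_vol(x))]
        rng = np.random.default_rng(np.random.SeedSequence([opts.seed, 17]))
        return gradient_shap(model, x, pool, n_samples=opts.gshap_samples,
                             sigma=opts.gshap_sigma, rng=rng)
    raise ValueError(f"unknown attribution method {method!r}; choose from {METHODS}")
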