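"""3D-CNN brain-age regressor.

Architecture: a stack of convolutional blocks, each
``conv(k³) → batch-norm → ReLU → max-pool(2³)`` with optional dropout,
followed by flatten and two dense layers ending in one scalar (estimated
brain age, years). Trained with mean-absolute-error loss and Adam, with
patience-based early stopping that restores the best-validation weights.

The default :class:`CNNConfig` is the full-scale architecture (128³
input, four blocks of 16/32/64/128 filters of size 6³, dropout 0.2 on
blocks 2–4, learning rate 1e-4, patience 20);
:meth:`CNNConfig.reduced` is a desk-scale configuration of the same code
path for 32³ phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .phantom import IntensityVolume

__all__ = [
    "CNNConfig",
    "TrainingHistory",
    "EarlyStopper",
    "build_model",
    "train",
    "estimate_ba",
    "downsample",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class CNNConfig:
    input_size: int = 128
    n_blocks: int = 4
    filters: Tuple[int, ...] = (16, 32, 64, 128)
    conv_kernel: int = 6
    pool_kernel: int = 2
    dropout_rate: float = 0.2
    dropout_blocks: Tuple[int, ...] = (2, 3, 4)   # 1-based block indices
    dense_sizes: Tuple[int, ...] = (128,)         # hidden widths before the scalar head
    learning_rate: float = 1e-4
    patience: int = 20
    max_epochs: int = 200
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1:
            raise ValueError("need at least one convolutional block")
        if len(self.filters) != self.n_blocks:
            raise ValueError("len(filters) must equal n_blocks")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        size = self.input_size
        for _ in range(self.n_blocks):
            if size % self.pool_kernel:
                raise ValueError(
                    f"input_size {self.input_size} incompatible with "
                    f"{self.n_blocks} pooling stages of {self.pool_kernel}")
            size //= self.pool_kernel
        if size < 1:
            raise ValueError("pooling chain collapses below one voxel")

    @classmethod
    def reduced(cls, **overrides) -> "CNNConfig":
        """Desk-scale configuration for 32³ phantom cohorts."""
        base = dict(input_size=32, n_blocks=2, filters=(4, 8), conv_kernel=3,
                    dropout_blocks=(2,), dense_sizes=(32,),
                    learning_rate=1e-3, patience=5, max_epochs=40)
        base.update(overrides)
        return cls(**base)

    @property
    def feature_size(self) -> int:
        """Spatial extent after the pooling chain."""
        size = self.input_size
        for _ in range(self.n_blocks):
            size //= self.pool_kernel
        return size


@dataclass
class TrainingHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def to_csv(self, path: Path) -> None:
        import pandas as pd
        pd.DataFrame({"epoch": np.arange(1, len(self.train_loss) + 1),
                      "train_mae": self.train_loss,
                      "val_mae": self.val_loss}).to_csv(path, index=False)


class EarlyStopper:
    """Stop when the validation loss has not improved for ``patience``
    consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.bad_epochs = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def build_model(config: CNNConfig) -> nn.Sequential:
    """Assemble the configured block stack; weight init is seeded."""
    if config.conv_kernel > config.input_size:
        raise ValueError("conv kernel exceeds input size")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    layers: List[nn.Layer] = []
    in_ch = 1
    size = config.input_size
    for b in range(config.n_blocks):
        if config.conv_kernel > size:
            raise ValueError(
                f"block {b + 1}: kernel {config.conv_kernel} exceeds feature map {size}")
        layers.append(nn.Conv3d(in_ch, config.filters[b], config.conv_kernel, rng))
        layers.append(nn.BatchNorm3d(config.filters[b]))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool3d(config.pool_kernel))
        if (b + 1) in config.dropout_blocks and config.dropout_rate > 0:
            layers.append(nn.Dropout(
                config.dropout_rate,
                np.random.default_rng(np.random.SeedSequence([config.seed, 11, b]))))
        in_ch = config.filters[b]
        size //= config.pool_kernel
    layers.append(nn.Flatten())
    feat = in_ch * size ** 3
    for width in config.dense_sizes:
        layers.append(nn.Dense(feat, width, rng))
        layers.append(nn.ReLU())
        feat = width
    layers.append(nn.Dense(feat, 1, rng))  # linear regression head, no activation
    return nn.Sequential(layers)


def _as_arrays(dataset) -> Tuple[np.ndarray, np.ndarray]:
    """Accept (X, y) arrays or a sequence of (IntensityVolume, age) pairs."""
    if isinstance(dataset, tuple) and len(dataset) == 2 and \
            isinstance(dataset[0], np.ndarray):
        X, y = dataset
    else:
        vols, ages = zip(*dataset)
        X = np.stack([v.data if isinstance(v, IntensityVolume) else np.asarray(v)
                      for v in vols])
        y = np.asarray(ages, dtype=float)
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def train(model: nn.Sequential, train_set, val_set, config: CNNConfig
          ) -> Tuple[nn.Sequential, TrainingHistory]:
    """MAE/Adam training with early stopping and best-epoch restoration.

    ``train_set`` / ``val_set`` are either ``(X, y)`` arrays (X of shape
    ``(N, S, S, S)``) or sequences of ``(volume, age)`` pairs. The scalar
    head's bias is initialized to the mean training age, the standard
    head initialization for regression onto an uncentered target.
    """
    Xtr, ytr = _as_arrays(train_set)
    Xva, yva = _as_arrays(val_set)
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("train and validation sets must be nonempty")

    head = model.layers[-1]
    if isinstance(head, nn.Dense) and np.all(head.b == 0):
        head.b[:] = ytr.mean()

    opt = nn.Adam(model, lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    history = TrainingHistory()
    best_state = model.state_dict()

    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(Xtr))
        losses = []
        for start in range(0, len(Xtr), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Xtr[idx][:, None]            # (n, 1, S, S, S)
            yb = ytr[idx]
            pred = model.forward(xb, training=True)[:, 0]
            resid = pred - yb
            loss = np.abs(resid).mean()
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
            model.backward(np.sign(resid)[:, None] / len(idx))
            opt.step()
        val = evaluate_mae(model, Xva, yva, batch_size=config.batch_size)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(val))
        improved = val < stopper.best
        stop = stopper.update(epoch, val)
        if improved:
            best_state = model.state_dict()
        if stop:
            break
    history.stopped_epoch = len(history.val_loss)
    history.best_epoch = stopper.best_epoch
    model.load_state_dict(best_state)
    return model, history


def evaluate_mae(model: nn.Sequential, X: np.ndarray, y: np.ndarray,
                 batch_size: int = 8) -> float:
    preds = []
    for start in range(0, len(X), batch_size):
        xb = X[start:start + batch_size][:, None]
        preds.append(model.forward(xb, training=False)[:, 0])
    return float(np.abs(np.concatenate(preds) - y).mean())


def estimate_ba(model: nn.Sequential, volume) -> float:
    """Estimated brain age (years) for one volume, in evaluation mode."""
    data = volume.data if isinstance(volume, IntensityVolume) else np.asarray(volume)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    out = model.forward(data[None, None].astype(float), training=False)
    val = float(out[0, 0])
    if not np.isfinite(val):
        raise FloatingPointError("non-finite brain-age estimate")
    return val


def downsample(volume: IntensityVolume, factor: int) -> IntensityVolume:
    """Block-mean downsampling by an integer factor per axis; the voxel
    size scales by the same factor (e.g. 256³ @ 1 mm → 128³ @ 2 mm)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    d = volume.data
    s = d.shape[0]
    if s % factor:
        raise ValueError(f"grid size {s} not divisible by factor {factor}")
    m = s // factor
    pooled = d.reshape(m, factor, m, factor, m, factor).mean(axis=(1, 3, 5))
    return IntensityVolume(pooled, volume.voxel_mm * factor)


# ---------------------------------------------------------------------------
# checkpoints: weights as .npz plus a JSON sidecar with the configuration
# ---------------------------------------------------------------------------

def save_checkpoint(model: nn.Sequential, config: CNNConfig, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(config), indent=2))
    return path


def load_checkpoint(path: Path) -> Tuple[nn.Sequential, CNNConfig]:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    for key in ("filters", "dropout_blocks", "dense_sizes"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = CNNConfig(**cfg_raw)
    model = build_model(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, config
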