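"""Dose-prediction models and their training protocol.

Two variants are supported.  ``unet`` takes the anatomical-structure channel
(optionally also CT) through one encoder-decoder; ``attunet`` runs separate
structure and CT encoders and fuses them at the bottleneck with multi-head
attention (queries from structures, keys/values from CT).

Training follows the usual voxel-wise regression recipe: Kaiming
initialization, MSE between the predicted and the reference dose, Adam with
learning rate 1e-4 and batch size 2, up to 1000 epochs, learning rate
divided by 10 when the validation loss plateaus, early stopping after 100
epochs without improvement.  The full-scale preset (depth 4, base 32,
224 x 224 x 32 inputs) is GPU-scale; the desk preset (depth 3, base 16) and
the smoke preset (depth 2, base 8) run on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid
from .nn import Adam, AttUNet3D, MultiHeadAttention3d, UNet3D
from .preprocess import TensorCase, restore_dose

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "build_model",
    "attention_fuse",
    "train",
    "predict_dose",
]


@dataclass
class ModelConfig:
    """Architecture description.

    ``bottleneck_filters`` is fixed by the doubling schedule,
    ``base_filters * 2**depth`` (32 -> 64 -> 128 -> 256 -> 512 for the
    full-scale preset).  ``n_heads * head_dim`` sets the attention embedding
    width of the ``attunet`` variant.
    """

    variant: str = "unet"
    depth: int = 4
    base_filters: int = 32
    n_heads: int = 8
    head_dim: int = 64
    scale_attention: bool = True
    struct_channels: int = 1
    include_ct_in_unet: bool = False
    seed: int = 0

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2**self.depth

    @classmethod
    def paper_preset(cls, variant: str = "unet") -> "ModelConfig":
        """Full-scale preset: depth 4, base 32, 8 heads x 64 dims (GPU-scale)."""
        return cls(variant=variant)

    @classmethod
    def desk_preset(cls, variant: str = "unet") -> "ModelConfig":
        """CPU-tractable preset for 96 x 96 x 32 grids."""
        return cls(variant=variant, depth=3, base_filters=16, n_heads=4, head_dim=16)

    @classmethod
    def smoke_preset(cls, variant: str = "unet") -> "ModelConfig":
        """Minimal preset for convergence smoke tests on small crops."""
        return cls(variant=variant, depth=2, base_filters=8, n_heads=2, head_dim=8)


@dataclass
class TrainConfig:
    """Optimization protocol."""

    learning_rate: float = 1e-4
    batch_size: int = 2
    max_epochs: int = 1000
    plateau_factor: float = 10.0
    plateau_patience: int = 50
    early_stop_patience: int = 100
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("early_stop_patience must be below max_epochs")


def build_model(config: ModelConfig):
    """Instantiate the network described by ``config``.

    Input-shape divisibility by ``2**depth`` is validated at forward time
    with an explicit message, since the grid is not known at build time.
    """
    if config.variant == "unet":
        cin = config.struct_channels + (1 if config.include_ct_in_unet else 0)
        model = UNet3D(cin, config.depth, config.base_filters, seed=config.seed)
    elif config.variant == "attunet":
        model = AttUNet3D(
            config.struct_channels, 1, config.depth, config.base_filters,
            config.n_heads, config.head_dim, config.scale_attention, seed=config.seed,
        )
    else:
        raise ValueError(f"unknown variant {config.variant!r}")
    model.config = config
    return model


def _model_input(model, case: TensorCase) -> np.ndarray:
    cfg: ModelConfig = model.config
    if cfg.variant == "attunet" or cfg.include_ct_in_unet:
        return case.inputs
    return case.inputs[:-1]  # drop the CT channel: structures-only wiring


def attention_fuse(
    struct_feats: np.ndarray,
    ct_feats: np.ndarray,
    n_heads: int = 8,
    head_dim: int = 64,
    scale: bool = True,
    layer: MultiHeadAttention3d | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Fuse two volumetric feature blocks with multi-head attention.

    Convenience wrapper around :class:`MultiHeadAttention3d`; pass ``layer``
    to reuse (or hand-set) projection weights.
    """
    if layer is None:
        layer = MultiHeadAttention3d(
            struct_feats.shape[0], ct_feats.shape[0], n_heads, head_dim, scale,
            rng=np.random.default_rng(seed),
        )
    return layer.forward(struct_feats, ct_feats)


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(model, dataset: list[TensorCase], cfg: TrainConfig | None = None) -> dict:
    """Train a dose predictor; returns per-epoch loss history.

    Deterministic given the seeds in the configs.  The validation split is
    drawn once from ``dataset`` (80/20 by default); with a single case the
    training case doubles as validation, which is exactly the memorization
    regime used for convergence smoke tests.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    for case in dataset:
        if case.target is None:
            raise ValueError("every training case needs a target dose")

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.validation_fraction * len(dataset)))
    perm = rng.permutation(len(dataset))
    val_idx = set(perm[:n_val].tolist())
    train_set = [dataset[i] for i in range(len(dataset)) if i not in val_idx]
    val_set = [dataset[i] for i in sorted(val_idx)] or train_set

    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    since_best = 0
    since_plateau = 0

    for epoch in range(cfg.max_epochs):
        model.set_training(True)
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
            model.zero_grad()
            loss_sum = 0.0
            for case in batch:
                x = _model_input(model, case)
                pred = model.forward(x)
                loss_sum += _mse(pred, case.target)
                model.backward(2.0 * (pred - case.target) / (pred.size * len(batch)))
            optimizer.step()
            epoch_loss += loss_sum
        epoch_loss /= len(train_set)

        model.set_training(False)
        val_loss = float(
            np.mean([_mse(model.forward(_model_input(model, c)), c.target) for c in val_set])
        )
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(optimizer.lr)

        if val_loss < best_val * (1 - 1e-6):
            best_val = val_loss
            since_best = 0
            since_plateau = 0
        else:
            since_best += 1
            since_plateau += 1
        if since_plateau >= cfg.plateau_patience:
            optimizer.lr /= cfg.plateau_factor
            since_plateau = 0
            log.info("epoch %d: plateau, lr -> %.2e", epoch, optimizer.lr)
        if since_best >= cfg.early_stop_patience:
            log.info("early stop at epoch %d (best val %.3e)", epoch, best_val)
            break
    return history


def predict_dose(model, case: TensorCase) -> VoxelGrid:
    """Forward pass, dose denormalization and return to CT coordinates."""
    if not case.meta:
        raise ValueError("TensorCase meta is required to restore physical dose")
    model.set_training(False)
    pred = model.forward(_model_input(model, case))
    return restore_dose(pred, case.meta)
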