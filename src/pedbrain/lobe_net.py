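"""First cascade model: 3D lobe segmentation.

A 3D U-Net labels each brain voxel forebrain / brainstem / cerebellum
(three output channels).  Inputs are clipped to ``[0, 2030]`` and
standardized (mean 730, SD 361); the Dice loss and the prediction argmax
are restricted to brain voxels (brain = raw intensity above a fixed
threshold, which cleanly separates tissue from air on phantoms).  The lobe
prediction feeds the downstream tumor-location heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MRIStudy
from .nn import UNet, flip_scale_augment, softmax_dice, train_network
from .nn import dice_loss  # noqa: F401  (re-exported training loss)
from .preprocess import clip_and_standardize, resample_to_grid

#: raw intensity above which a voxel counts as brain tissue
BRAIN_THRESHOLD = 200.0

N_LOBE_CHANNELS = 3


class DataError(RuntimeError):
    pass


@dataclass
class LobeNetConfig:
    """Phantom preset; the full-scale cohort preset uses
    ``input_dims=(256, 256, 24)`` with more channels."""
    input_dims: tuple = (64, 64, 16)
    base_channels: int = 8
    depth: int = 2
    max_epochs: int = 50
    early_stop_patience: int = 5
    learning_rate: float = 1e-3
    dice_smooth: float = 1.0
    convs_per_block: int = 1
    sequence: str = "t1"
    augment: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if any(d % 2 ** self.depth for d in self.input_dims):
            raise ValueError(f"input_dims {self.input_dims} must be divisible "
                             f"by 2**depth={2 ** self.depth}")


def _prepare_case(case, cfg: LobeNetConfig):
    raw = resample_to_grid(case.study.get(cfg.sequence), cfg.input_dims, "linear")
    brain = (raw > BRAIN_THRESHOLD).astype(np.float32)
    if not brain.any():
        raise DataError(f"case {case.case_id!r} has no brain voxels")
    x = clip_and_standardize(raw).astype(np.float32)[None, None]
    lobes = resample_to_grid(case.lobes, cfg.input_dims, "nearest", is_label=True)
    onehot = np.stack([(lobes == lab).astype(np.float32)
                       for lab in (1, 2, 3)])[None]
    return x, onehot, brain[None, None]


def build_lobe_net(cfg: LobeNetConfig) -> UNet:
    return UNet(ndim=3, in_channels=1, out_channels=N_LOBE_CHANNELS,
                base_channels=cfg.base_channels, depth=cfg.depth,
                convs_per_block=cfg.convs_per_block, seed=cfg.seed)


def train_lobe_net(train_cases, val_cases, cfg: LobeNetConfig):
    """Train the lobe network on phantom cases; returns ``(net, curve)``."""
    net = build_lobe_net(cfg)
    train_items = [_prepare_case(c, cfg) for c in train_cases]
    val_items = [_prepare_case(c, cfg) for c in val_cases]

    def loss_fn(logits, target, mask):
        return softmax_dice(logits, target, smooth=cfg.dice_smooth, mask=mask)

    curve = train_network(net, loss_fn, train_items, val_items,
                          max_epochs=cfg.max_epochs,
                          patience=cfg.early_stop_patience,
                          lr=cfg.learning_rate, seed=cfg.seed,
                          augment_fn=flip_scale_augment if cfg.augment else None)
    return net, curve


def predict_lobes(study: MRIStudy, net: UNet, cfg: LobeNetConfig) -> np.ndarray:
    """Voxel-wise lobe labels on the study's native grid (0 outside brain)."""
    native_dims = study.shape
    raw = resample_to_grid(study.get(cfg.sequence), cfg.input_dims, "linear")
    brain = raw > BRAIN_THRESHOLD
    x = clip_and_standardize(raw).astype(np.float32)[None, None]
    logits = net.forward(x)[0]
    labels = (np.argmax(logits, axis=0) + 1).astype(np.int16)
    labels[~brain] = 0
    return resample_to_grid(labels, native_dims, "nearest", is_label=True)
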