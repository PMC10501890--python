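"""Second cascade model: two-step 2D tumor segmentation.

Stage 1 is a single-channel 2D U-Net that segments the whole tumor on
axial post-contrast T1 slices (sigmoid Dice head).  Stage 2 takes a
two-channel input -- the original slice stacked with a whole-tumor guide
mask (the ground-truth mask during teacher-forced training, the stage-1
probability map at inference) -- and predicts enhancing vs non-enhancing
within the whole-tumor region (softmax Dice masked to the tumor).  At
inference, stage-2 labels are kept only where stage 1 fires, so the final
map is always a subset of the stage-1 mask; connected components smaller
than ``min_component_vox`` are removed, which is also the abnormality
criterion ("is any sufficiently large tumor component present?").

Slices are clipped to ``[0, 2030]`` and min-max normalized (162-2030).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .core import (MRIStudy, TUMOR_ENHANCING, TUMOR_NONENHANCING)
from .nn import (UNet, sigmoid_dice, softmax_dice, train_network)
from .preprocess import clip_and_minmax, resample_to_grid

log = logging.getLogger(__name__)


@dataclass
class TumorNetConfig:
    """Phantom preset; the cohort preset uses 512x512 slices.

    ``slice_dims`` is the cascade's working resolution: native slices are
    resampled into it for training/inference and predictions are
    resampled back.  48x48 is the phantom preset -- at desk scale it
    trains collapse-free where larger working grids are bistable.
    """
    slice_dims: tuple = (48, 48)
    stage1_epochs: int = 35
    stage2_epochs: int = 40
    base_channels: int = 8
    depth: int = 2
    learning_rate: float = 1e-3
    dice_smooth: float = 1.0
    convs_per_block: int = 1
    early_stop_patience: int = None  # the two stages train for a fixed budget
    min_component_vox: int = 5
    sequence: str = "t1c"
    teacher_forcing: bool = True
    batch_slices: int = 16
    #: stage-1 restarts: if training ends in the empty-prediction collapse
    #: (train loss above ``collapse_loss``), retrain with a shifted
    #: initialisation seed, at most ``max_restarts`` times (deterministic)
    max_restarts: int = 2
    collapse_loss: float = 0.40
    seed: int = 0

    def __post_init__(self):
        if any(d % 2 ** self.depth for d in self.slice_dims):
            raise ValueError(f"slice_dims {self.slice_dims} must be divisible "
                             f"by 2**depth={2 ** self.depth}")


BRAIN_THRESHOLD = 200.0  # raw intensity separating head tissue from air


def _case_slices(case, cfg: TumorNetConfig):
    """Normalized axial slices, tumor-label slices and brain-mask slices."""
    nz = case.study.shape[2]
    vol = resample_to_grid(case.study.get(cfg.sequence),
                           cfg.slice_dims + (nz,), "linear")
    x = clip_and_minmax(vol).astype(np.float32)
    brain = (vol > BRAIN_THRESHOLD).astype(np.float32)
    labels = resample_to_grid(case.tumor, cfg.slice_dims + (nz,),
                              "nearest", is_label=True)
    # (nz, H, W) stacks
    return (np.moveaxis(x, 2, 0), np.moveaxis(labels, 2, 0),
            np.moveaxis(brain, 2, 0))


def _batched(arrays, batch: int):
    n = arrays[0].shape[0]
    return [tuple(a[i:i + batch] for a in arrays) for i in range(0, n, batch)]


def build_stage1_net(cfg: TumorNetConfig, seed_offset: int = 0) -> UNet:
    net = UNet(ndim=2, in_channels=1, out_channels=1,
               base_channels=cfg.base_channels, depth=cfg.depth,
               convs_per_block=cfg.convs_per_block,
               seed=cfg.seed + seed_offset)
    # start near the background prior (p ~ 0.12) rather than p = 0.5: the
    # initial "suppress everything" phase of the Dice loss is then mild
    # enough for foreground features to form before the head saturates
    net.out_conv.b[:] = -2.0
    return net


def build_stage2_net(cfg: TumorNetConfig) -> UNet:
    return UNet(ndim=2, in_channels=2, out_channels=2,
                base_channels=cfg.base_channels, depth=cfg.depth,
                convs_per_block=cfg.convs_per_block, seed=cfg.seed + 1)


def train_stage1(train_cases, val_cases, cfg: TumorNetConfig):
    """Whole-tumor slice segmentation; normals contribute empty targets.

    Three measures keep the Dice loss out of its empty-prediction
    attractor at desk scale (tumor pixels are ~1% of a slice): training
    slices are balanced (all tumor-bearing slices plus an equal draw of
    empty ones), the Dice term is per-slice rather than per-batch, and
    the head starts at a negative output bias.  The logit clamp in
    :func:`pedbrain.nn.sigmoid_dice` additionally guarantees the gradient
    never underflows to exactly zero, so a transiently suppressed head
    can still recover.
    """
    rng = np.random.default_rng(cfg.seed)

    def items(cases, balance):
        xs, ts, ms = [], [], []
        for c in cases:
            x, lab, brain = _case_slices(c, cfg)
            xs.append(x)
            ts.append((lab > 0).astype(np.float32))
            ms.append(brain)
        x = np.concatenate(xs)[:, None]
        t = np.concatenate(ts)[:, None]
        m = np.concatenate(ms)[:, None]
        if balance:
            has_tumor = t.any(axis=(1, 2, 3))
            pos = np.flatnonzero(has_tumor)
            neg = np.flatnonzero(~has_tumor)
            if len(pos) and len(neg):
                neg = rng.choice(neg, size=min(len(neg), max(len(pos), 8)),
                                 replace=False)
            keep = rng.permutation(np.concatenate([pos, neg]))
            x, t, m = x[keep], t[keep], m[keep]
        return [(xb, tb, mb)
                for xb, tb, mb in _batched((x, t, m), cfg.batch_slices)]

    def loss_fn(logits, target, _mask):
        return sigmoid_dice(logits, target, smooth=cfg.dice_smooth)

    train_items = items(train_cases, balance=True)
    val_items = items(val_cases, balance=False)
    for attempt in range(cfg.max_restarts + 1):
        net = build_stage1_net(cfg, seed_offset=1000 * attempt)
        curve = train_network(net, loss_fn, train_items, val_items,
                              max_epochs=cfg.stage1_epochs,
                              patience=cfg.early_stop_patience,
                              lr=cfg.learning_rate, seed=cfg.seed + attempt)
        if curve.records[-1]["train_loss"] < cfg.collapse_loss:
            break
        log.warning("stage-1 training collapsed (train loss %.3f); "
                    "restarting with a new initialisation",
                    curve.records[-1]["train_loss"])
    return net, curve


def _stage1_prob(net: UNet, x_slices: np.ndarray) -> np.ndarray:
    """Tumor-probability map (N, 1, H, W)."""
    return expit(net.forward(x_slices).astype(np.float64)).astype(np.float32)


def train_stage2(train_cases, val_cases, stage1_net, cfg: TumorNetConfig):
    """Enhancing/non-enhancing split within the whole tumor.

    With ``cfg.teacher_forcing`` (default) the guide channel is the
    ground-truth whole-tumor mask; otherwise ``stage1_net`` must be given
    and its probability map is used, as at inference.
    """
    if not cfg.teacher_forcing and stage1_net is None:
        raise ValueError("stage-1 model required when teacher_forcing=False")

    def items(cases):
        xs, gs, ts, ms = [], [], [], []
        for c in cases:
            x, lab, _brain = _case_slices(c, cfg)
            keep = (lab > 0).any(axis=(1, 2))  # tumor-bearing slices only
            if not keep.any():
                continue
            x, lab = x[keep], lab[keep]
            wt = (lab > 0).astype(np.float32)
            if cfg.teacher_forcing:
                guide = wt
            else:
                guide = _stage1_prob(stage1_net, x[:, None])[:, 0]
            xs.append(x); gs.append(guide); ms.append(wt)
            ts.append(np.stack([(lab == TUMOR_ENHANCING),
                                (lab == TUMOR_NONENHANCING)], axis=1).astype(np.float32))
        if not xs:
            raise ValueError("no tumor-bearing slices in the given cases")
        x = np.stack([np.concatenate(xs), np.concatenate(gs)], axis=1)
        t = np.concatenate(ts)
        m = np.concatenate(ms)[:, None]
        return [(xb, tb, mb) for xb, tb, mb in _batched((x, t, m), cfg.batch_slices)]

    net = build_stage2_net(cfg)

    def loss_fn(logits, target, mask):
        return softmax_dice(logits, target, smooth=cfg.dice_smooth, mask=mask)

    curve = train_network(net, loss_fn, items(train_cases), items(val_cases),
                          max_epochs=cfg.stage2_epochs,
                          patience=cfg.early_stop_patience,
                          lr=cfg.learning_rate, seed=cfg.seed + 1)
    return net, curve


def remove_small_components(mask: np.ndarray, min_vox: int) -> np.ndarray:
    """Drop connected components smaller than ``min_vox`` voxels."""
    labelled, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(labelled.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_vox
    return keep[labelled]


def predict_tumor(study: MRIStudy, stage1_net: UNet, stage2_net: UNet,
                  cfg: TumorNetConfig) -> np.ndarray:
    """Slice-wise cascade inference stacked to a 3D tumor label map."""
    native_dims = study.shape
    nz = native_dims[2]
    vol = resample_to_grid(study.get(cfg.sequence), cfg.slice_dims + (nz,), "linear")
    brain = np.moveaxis(vol > BRAIN_THRESHOLD, 2, 0)
    x = np.moveaxis(clip_and_minmax(vol).astype(np.float32), 2, 0)[:, None]
    prob_wt = _stage1_prob(stage1_net, x)
    wt = (prob_wt[:, 0] > 0.5) & brain
    x2 = np.concatenate([x, prob_wt], axis=1)
    logits2 = stage2_net.forward(x2)
    comp = np.argmax(logits2, axis=1)  # 0 -> enhancing, 1 -> non-enhancing
    labels = np.where(comp == 0, TUMOR_ENHANCING, TUMOR_NONENHANCING)
    labels = np.where(wt, labels, 0).astype(np.int16)
    labels = np.moveaxis(labels, 0, 2)  # back to (x, y, z)
    keep = remove_small_components(labels > 0, cfg.min_component_vox)
    labels[~keep] = 0
    return resample_to_grid(labels, native_dims, "nearest", is_label=True)


def detect_abnormality(tumor_map: np.ndarray, min_component_vox: int = 5) -> bool:
    """True iff any connected tumor component has >= ``min_component_vox`` voxels."""
    labelled, n = ndimage.label(np.asarray(tumor_map) > 0)
    if n == 0:
        return False
    sizes = np.bincount(labelled.ravel())[1:]
    return bool((sizes >= min_component_vox).any())
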