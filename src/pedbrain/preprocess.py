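"""Intensity preprocessing, grid resampling and the randomized cohort split.

Two normalizations feed the two networks:

* the 3D lobe network sees volumes clipped to ``[0, 2030]`` and standardized
  with the fixed constants mean 730 / SD 361;
* the 2D tumor networks see slices clipped to ``[0, 2030]`` and min-max
  normalized with minimum 162 and maximum 2030.

The min-max constants leave clipped values in ``[0, 162)`` slightly
negative; the output is therefore clamped to ``[0, 1]`` (logged when it
happens) so network inputs stay in a fixed range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    clip_lo: float = 0.0
    clip_hi: float = 2030.0
    standardize_mean: float = 730.0
    standardize_sd: float = 361.0
    minmax_lo: float = 162.0
    minmax_hi: float = 2030.0
    lobe_input_dims: tuple = (256, 256, 24)
    tumor_slice_dims: tuple = (512, 512)

    def __post_init__(self):
        if not self.clip_lo < self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if not self.minmax_lo < self.minmax_hi:
            raise ValueError("minmax_lo must be < minmax_hi")
        if self.standardize_sd <= 0:
            raise ValueError("standardize_sd must be positive")


DEFAULT_CONFIG = PreprocessConfig()


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{what} contains non-finite voxels")


def clip_and_standardize(volume: np.ndarray,
                         cfg: PreprocessConfig = DEFAULT_CONFIG) -> np.ndarray:
    """``(clip(v, 0, 2030) - 730) / 361`` elementwise."""
    volume = np.asarray(volume, dtype=float)
    _check_finite(volume, "volume")
    clipped = np.clip(volume, cfg.clip_lo, cfg.clip_hi)
    return (clipped - cfg.standardize_mean) / cfg.standardize_sd


def unstandardize(volume: np.ndarray,
                  cfg: PreprocessConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Inverse of :func:`clip_and_standardize` on the non-clipped range."""
    return np.asarray(volume, dtype=float) * cfg.standardize_sd + cfg.standardize_mean


def clip_and_minmax(image: np.ndarray,
                    cfg: PreprocessConfig = DEFAULT_CONFIG,
                    clamp: bool = True) -> np.ndarray:
    """``(clip(v, 0, 2030) - 162) / (2030 - 162)``, clamped to ``[0, 1]``."""
    image = np.asarray(image, dtype=float)
    _check_finite(image, "image")
    clipped = np.clip(image, cfg.clip_lo, cfg.clip_hi)
    out = (clipped - cfg.minmax_lo) / (cfg.minmax_hi - cfg.minmax_lo)
    if clamp:
        n_neg = int(np.count_nonzero(out < 0))
        if n_neg:
            log.debug("clip_and_minmax clamped %d sub-minimum values to 0", n_neg)
        out = np.clip(out, 0.0, 1.0)
    return out


def unminmax(image: np.ndarray,
             cfg: PreprocessConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Inverse of :func:`clip_and_minmax` on the non-clamped range."""
    return np.asarray(image, dtype=float) * (cfg.minmax_hi - cfg.minmax_lo) + cfg.minmax_lo


def resample_to_grid(volume: np.ndarray, target_dims, mode: str = "linear",
                     is_label: bool = False) -> np.ndarray:
    """Resample a scalar volume (linear) or label map (nearest) to new dims."""
    target_dims = tuple(int(d) for d in target_dims)
    if any(d <= 0 for d in target_dims):
        raise ValueError(f"target_dims must be positive, got {target_dims}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    if is_label and mode != "nearest":
        raise ValueError("label maps must be resampled with mode='nearest'")
    volume = np.asarray(volume)
    if volume.shape == target_dims:
        return volume.copy()
    order = 0 if mode == "nearest" else 1
    out = resize(volume.astype(float), target_dims, order=order,
                 mode="edge", anti_aliasing=False, preserve_range=True)
    if is_label or mode == "nearest":
        return np.rint(out).astype(volume.dtype)
    return out


def largest_remainder_counts(n: int, proportions) -> list:
    """Integer allocation of ``n`` items to proportions, summing exactly to n."""
    proportions = np.asarray(proportions, dtype=float)
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {proportions.sum()}")
    raw = n * proportions
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    # hand out the leftover items to the largest remainders (stable on ties)
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    return counts.tolist()


def split_cohort(case_ids, proportions, seed: int):
    """Randomized disjoint train/val/test split with largest-remainder sizes."""
    case_ids = list(case_ids)
    if not case_ids:
        raise ValueError("cannot split an empty cohort")
    if len(proportions) != 3:
        raise ValueError("proportions must be (train, val, test)")
    counts = largest_remainder_counts(len(case_ids), proportions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    shuffled = [case_ids[i] for i in order]
    train = shuffled[: counts[0]]
    val = shuffled[counts[0]: counts[0] + counts[1]]
    test = shuffled[counts[0] + counts[1]:]
    return train, val, test
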