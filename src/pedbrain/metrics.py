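"""Segmentation and diagnostic evaluation metrics.

Dice overlap and the robust 95th-percentile Hausdorff surface distance for
segmentation quality (per compartment: whole tumor, enhancing,
non-enhancing); sensitivity / specificity / PPV / NPV / accuracy from
confusion counts; Cohen's kappa for inter-rater agreement; and the
mean / SD / quartile aggregation used to report per-dataset tables.

Conventions for degenerate inputs follow common segmentation-challenge
practice: Dice of two empty masks is 1 (flagged in the log); HD95 is
undefined (``None``, with a reason code) when either mask is empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

COMPARTMENTS = ("WT", "ET", "NET")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn == 0:
            raise ValueError("confusion counts are all zero")


def dice_score(a: np.ndarray, b: np.ndarray) -> float:
    """``2|A∩B| / (|A|+|B|)``; 1.0 by convention when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        log.warning("dice_score of two empty masks: returning 1.0 by convention")
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / size


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def hausdorff95(a: np.ndarray, b: np.ndarray,
                spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> Optional[float]:
    """Max of the two directed 95th-percentile boundary distances, in mm.

    Distances are measured between boundary-voxel centres with anisotropic
    ``spacing``; pass unit spacing for voxel units.  Returns ``None`` when
    either mask is empty (undefined).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        log.info("hausdorff95 undefined: empty mask (reason=empty-mask)")
        return None
    ba, bb = _boundary(a), _boundary(b)

    def directed(src, dst):
        # exact Euclidean distance to the nearest dst boundary voxel
        dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
        return float(np.percentile(dt[src], 95))

    return max(directed(ba, bb), directed(bb, ba))


def segmentation_metrics(pred: np.ndarray, truth: np.ndarray,
                         spacing=(1.0, 1.0, 1.0)) -> Dict[str, dict]:
    """Dice and HD95 per compartment (WT / ET / NET label maps 1=ET, 2=NET)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    masks = {"WT": (pred > 0, truth > 0),
             "ET": (pred == 1, truth == 1),
             "NET": (pred == 2, truth == 2)}
    return {k: {"dice": dice_score(p, t), "hd95": hausdorff95(p, t, spacing)}
            for k, (p, t) in masks.items()}


def diagnostic_metrics(c: ConfusionCounts) -> Dict[str, Optional[float]]:
    """Sensitivity, specificity, PPV, NPV, accuracy; ``None`` when undefined."""
    def ratio(num, den):
        return num / den if den > 0 else None

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
        "accuracy": (c.tp + c.tn) / (c.tp + c.fp + c.fn + c.tn),
    }


def cohen_kappa(pairs: Sequence[Tuple]) -> Optional[float]:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)`` of two raters.

    ``p_e`` comes from the product of the raters' marginal label
    frequencies.  Returns ``None`` (flagged) for degenerate marginals with
    ``p_e = 1``.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 rating pairs")
    labels = sorted({x for p in pairs for x in p}, key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for a, b in pairs:
        table[index[a], index[b]] += 1
    table /= table.sum()
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if abs(1.0 - p_e) < 1e-12:
        log.warning("cohen_kappa undefined: degenerate marginals (p_e = 1)")
        return None
    return (p_o - p_e) / (1.0 - p_e)


def aggregate_metrics(values: Sequence[Optional[float]]) -> dict:
    """Mean, SD and 25th/75th quartiles over the defined values of a metric.

    ``None`` entries (e.g. undefined HD95) are excluded and counted.
    """
    values = list(values)
    if not values:
        raise ValueError("need at least one case")
    defined = np.array([v for v in values if v is not None], dtype=float)
    out = {"n": len(values), "n_undefined": len(values) - len(defined)}
    if len(defined) == 0:
        out.update({"mean": None, "sd": None, "q25": None, "q75": None})
        return out
    out.update({
        "mean": float(defined.mean()),
        "sd": float(defined.std(ddof=0)),
        "q25": float(np.percentile(defined, 25)),  # linear (type-7) interpolation
        "q75": float(np.percentile(defined, 75)),
    })
    return out


def aggregate_segmentation_table(per_case: List[Dict[str, dict]]) -> "object":
    """Dataset summary mirroring the usual Dice/HD95 x WT/ET/NET layout."""
    import pandas as pd
    rows = []
    for metric in ("dice", "hd95"):
        for comp in COMPARTMENTS:
            agg = aggregate_metrics([case[comp][metric] for case in per_case])
            rows.append({"metric": metric, "compartment": comp, **agg})
    return pd.DataFrame(rows)
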