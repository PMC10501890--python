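"""Shared containers and NIfTI I/O for the paediatric brain-tumor pipeline.

The pipeline operates on aligned multi-sequence 3D MRI studies.  Conventions
used throughout the package:

* volumes are numpy arrays indexed ``(x, y, z)`` with the third axis axial
  (inferior -> superior); slices for the 2D tumor networks are taken along
  that axis;
* intensities live on a fixed absolute scale in ``[0, 2030]`` so that the
  preprocessing constants (clip 0-2030, standardize 730/361, min-max
  162-2030) are meaningful;
* lobe label maps use ``0`` background, ``1`` forebrain, ``2`` brainstem,
  ``3`` cerebellum (the cerebellum label also covers the fourth ventricle);
* tumor label maps use ``0`` background, ``1`` enhancing, ``2`` non-enhancing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

# ----------------------------------------------------------------- labels

LOBE_BACKGROUND = 0
LOBE_FOREBRAIN = 1
LOBE_BRAINSTEM = 2
LOBE_CEREBELLUM = 3

LOBE_NAMES = {
    LOBE_FOREBRAIN: "forebrain",
    LOBE_BRAINSTEM: "brainstem",
    LOBE_CEREBELLUM: "cerebellum_fourth_ventricle",
}

TUMOR_BACKGROUND = 0
TUMOR_ENHANCING = 1
TUMOR_NONENHANCING = 2

#: canonical sequence keys, in manifest column order
SEQUENCES = ("t1", "t1c", "t2", "flair", "dwi", "adc")

TUMOR_CLASSES = (
    "ependymoma",
    "medulloblastoma",
    "pilocytic_astrocytoma",
    "brainstem_glioma",
)

INTENSITY_CLASSES = ("hyperintense", "isointense", "hypointense")
ENHANCEMENT_GRADES = ("mild", "moderate", "severe")
ENHANCEMENT_PATTERNS = ("homogeneous", "heterogeneous")
LOCATIONS = ("forebrain", "brainstem", "cerebellum_fourth_ventricle")


# ----------------------------------------------------------------- containers


@dataclass
class MRIStudy:
    """An aligned multi-sequence 3D study.

    ``sequences`` maps sequence names (subset of :data:`SEQUENCES`) to 3D
    float arrays on a common grid; ``spacing`` is the voxel size in mm.
    """

    sequences: dict
    spacing: tuple = (1.0, 1.0, 1.0)

    @property
    def shape(self):
        return next(iter(self.sequences.values())).shape

    def __post_init__(self):
        shapes = {v.shape for v in self.sequences.values()}
        if len(shapes) > 1:
            raise ValueError(f"sequences are not on a common grid: {shapes}")

    def get(self, name: str) -> np.ndarray:
        if name not in self.sequences:
            raise KeyError(f"sequence {name!r} missing from study "
                           f"(has {sorted(self.sequences)})")
        return self.sequences[name]


@dataclass
class SemanticFeatures:
    """Radiologist-style categorical description of a tumor.

    Intensity classes are judged against grey matter; ``enhancement_grade``
    bins the enhancing fraction of the whole tumor (mild < 25%, moderate
    25-75%, severe > 75%); ``location`` is the lobe with maximal overlap.
    Fields that could not be computed are ``None`` and a reason is recorded
    in ``flags``.
    """

    t1_intensity: Optional[str] = None
    t2_intensity: Optional[str] = None
    flair_intensity: Optional[str] = None
    haemorrhage: Optional[bool] = None
    diffusion_restriction: Optional[bool] = None
    cyst: Optional[bool] = None
    necrosis: Optional[bool] = None
    enhancement_pattern: Optional[str] = None
    enhancement_grade: Optional[str] = None
    location: Optional[str] = None
    flags: dict = field(default_factory=dict)

    FIELDS = (
        "t1_intensity", "t2_intensity", "flair_intensity", "haemorrhage",
        "diffusion_restriction", "cyst", "necrosis", "enhancement_pattern",
        "enhancement_grade", "location",
    )
    BOOLEAN_FIELDS = ("haemorrhage", "diffusion_restriction", "cyst", "necrosis")

    def __post_init__(self):
        for name in ("t1_intensity", "t2_intensity", "flair_intensity"):
            v = getattr(self, name)
            if v is not None and v not in INTENSITY_CLASSES:
                raise ValueError(f"{name}={v!r} not in {INTENSITY_CLASSES}")
        if self.enhancement_grade not in ENHANCEMENT_GRADES + (None,):
            raise ValueError(f"enhancement_grade={self.enhancement_grade!r}")
        if self.enhancement_pattern not in ENHANCEMENT_PATTERNS + (None,):
            raise ValueError(f"enhancement_pattern={self.enhancement_pattern!r}")
        if self.location not in LOCATIONS + (None,):
            raise ValueError(f"location={self.location!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SemanticFeatures":
        return cls(**{k: d.get(k) for k in cls.FIELDS})

    def agreement(self, other: "SemanticFeatures") -> float:
        """Fraction of the ten feature fields on which two records agree."""
        hits = sum(getattr(self, k) == getattr(other, k) for k in self.FIELDS)
        return hits / len(self.FIELDS)


@dataclass
class ReferenceStats:
    """Robust per-sequence reference statistics of normal tissue.

    Medians and MAD-derived SDs of the grey-matter reference region, the
    comparator for every intensity rule ("similar intensity to grey
    matter").  Sequences missing from the study are absent from the dicts
    and listed in ``missing``.
    """

    medians: dict
    sds: dict
    missing: tuple = ()

    def median(self, seq: str) -> float:
        if seq not in self.medians:
            raise KeyError(f"no reference statistics for sequence {seq!r}")
        return self.medians[seq]

    def sd(self, seq: str) -> float:
        return self.sds[seq]


# ----------------------------------------------------------------- NIfTI I/O


def save_nifti(volume: np.ndarray, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume), affine)
    nib.save(img, str(path))


def load_nifti(path):
    """Return ``(volume, spacing)`` from a NIfTI file."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return vol, spacing


def save_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_json(path):
    with open(path) as fh:
        return json.load(fh)


def asdict_shallow(dc) -> dict:
    return {f.name: getattr(dc, f.name) for f in dataclasses.fields(dc)}
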