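"""Synthetic multi-sequence brain MRI phantoms with known ground truth.

A phantom is a desk-scale stand-in for a paediatric brain study: three lobe
compartments built from simple solids (a large forebrain ellipsoid, an
inferior-posterior cerebellar ellipsoid, an inferior-central brainstem
cylinder), a 2-voxel grey-matter rim inside the forebrain surface as the
intensity reference, and an optional spherical tumor whose voxel data
*realizes* a requested semantic-feature profile:

* the enhancing / non-enhancing split is carved to an exact voxel fraction
  inside the requested enhancement-grade band (mild < 25%, moderate 25-75%,
  severe > 75%);
* cysts and necrosis are distinct non-enhancing components that are T2
  bright and T1 dark, with FLAIR suppression forced above 75% (cyst) or
  below 25% (necrosis) of their voxels;
* haemorrhage appears as 1-3 small foci of strong T1 hyperintensity;
* diffusion restriction raises DWI and lowers ADC across the tumor.

All noise-free intensities sit inside ``[0, 2030]`` so the fixed
preprocessing constants are meaningful; additive Gaussian noise is applied
per sequence afterwards.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (LOBE_BRAINSTEM, LOBE_CEREBELLUM, LOBE_FOREBRAIN,
                   SEQUENCES, TUMOR_CLASSES, TUMOR_ENHANCING,
                   TUMOR_NONENHANCING, MRIStudy, SemanticFeatures, save_json,
                   save_nifti)
from .preprocess import largest_remainder_counts
from .reference_cohort import TYPICAL_FEATURES, class_prevalences

#: grey-matter anchor intensity (the standardization mean of the pipeline)
GM_INTENSITY = 730.0
BACKGROUND_INTENSITY = 30.0

#: noise-free tissue intensities per sequence (absolute units in [0, 2030])
TISSUE_INTENSITIES = {
    #            t1     t1c    t2     flair  dwi    adc
    "forebrain": (950.0, 950.0, 560.0, 620.0, 640.0, 900.0),
    "gm":        (730.0, 730.0, 730.0, 730.0, 730.0, 730.0),
    "brainstem": (880.0, 880.0, 620.0, 660.0, 660.0, 880.0),
    "cerebellum": (820.0, 820.0, 680.0, 700.0, 700.0, 860.0),
}

#: tumor-intensity multipliers applied to the grey-matter anchor
INTENSITY_CLASS_FACTOR = {"hyperintense": 1.15, "isointense": 1.0,
                          "hypointense": 0.85}
#: representative enhancing fractions inside each grade band
GRADE_FRACTION = {"mild": 0.12, "moderate": 0.50, "severe": 0.80}

CYST_T1 = 365.0       # 0.5 x GM: clearly T1 dark
CYST_T2 = 1170.0      # 1.6 x GM: clearly T2 bright
CYST_FLAIR = 480.0    # far below GM -> suppressed
NECROSIS_FLAIR = 800.0  # above GM -> unsuppressed
HAEMORRHAGE_T1 = 980.0
ENHANCE_HOMOGENEOUS = 1500.0
ENHANCE_HET_LO, ENHANCE_HET_HI = 900.0, 1900.0
DWI_RESTRICTED, ADC_RESTRICTED = 1.40, 0.55  # multipliers of the anchor


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass
class PhantomSpec:
    grid_dims: tuple = (64, 64, 32)
    spacing_mm: tuple = (1.0, 1.0, 1.0)
    tumor_class: str = "none"
    target_features: Optional[SemanticFeatures] = None
    tumor_radius_vox: float = 7.0
    noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self):
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) != 3 or any(d < 16 for d in dims):
            raise PhantomError(f"grid_dims must be three values >= 16, got {self.grid_dims}")
        self.grid_dims = dims
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.tumor_class not in TUMOR_CLASSES + ("none",):
            raise PhantomError(f"tumor_class {self.tumor_class!r} unknown")
        if self.tumor_radius_vox <= 0:
            raise PhantomError(f"tumor_radius_vox must be positive, got {self.tumor_radius_vox}")
        if self.tumor_radius_vox >= min(dims) / 3:
            raise PhantomError("tumor_radius_vox must be < min(grid_dims)/3, "
                               f"got {self.tumor_radius_vox} on grid {dims}")
        if self.noise_sd < 0:
            raise PhantomError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.tumor_class == "none" and self.target_features is not None:
            raise PhantomError("target_features must be absent when tumor_class='none'")


@dataclass
class PhantomCase:
    case_id: str
    study: MRIStudy
    lobes: np.ndarray
    tumor: np.ndarray
    gm_mask: np.ndarray
    truth: Optional[SemanticFeatures]
    class_label: str
    spec: PhantomSpec = None

    @property
    def brain_mask(self) -> np.ndarray:
        return self.lobes > 0


# ------------------------------------------------------------- geometry


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return acc <= 1.0


def _sphere(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum((g - c) ** 2 for g, c in zip(grids, center))
    return acc <= radius ** 2


def brain_geometry(dims) -> np.ndarray:
    """Lobe label map: disjoint forebrain / brainstem / cerebellum masks."""
    nx, ny, nz = dims
    fb = _ellipsoid(dims, (nx / 2, ny * 0.46, nz * 0.60),
                    (nx * 0.42, ny * 0.42, nz * 0.36))
    cb = _ellipsoid(dims, (nx / 2, ny * 0.68, nz * 0.26),
                    (nx * 0.28, ny * 0.22, nz * 0.21))
    xs, ys, zs = np.ogrid[0:nx, 0:ny, 0:nz]
    r_stem = 0.13 * min(nx, ny)
    stem = (((xs - nx / 2) ** 2 + (ys - ny * 0.40) ** 2) <= r_stem ** 2) \
        & (zs >= nz * 0.04) & (zs <= nz * 0.40)
    lobes = np.zeros(dims, dtype=np.int16)
    lobes[fb] = LOBE_FOREBRAIN
    lobes[cb] = LOBE_CEREBELLUM
    lobes[stem] = LOBE_BRAINSTEM
    return lobes


def grey_matter_rim(lobes: np.ndarray) -> np.ndarray:
    fb = lobes == LOBE_FOREBRAIN
    interior = ndimage.binary_erosion(fb, iterations=2)
    return fb & ~interior


# ------------------------------------------------------------- tumor carving


def _place_tumor_center(lobes, gm_mask, location, radius, rng):
    """Deepest point of the target lobe (outside grey matter), jittered."""
    label = {"forebrain": LOBE_FOREBRAIN, "brainstem": LOBE_BRAINSTEM,
             "cerebellum_fourth_ventricle": LOBE_CEREBELLUM}[location]
    allowed = (lobes == label) & ~gm_mask
    dt = ndimage.distance_transform_edt(allowed)
    max_depth = float(dt.max())
    r_eff = min(radius, max_depth - 1.5)
    if r_eff < 2.5:
        raise PhantomError(f"lobe {location!r} cannot host a tumor on this grid")
    deep = np.argwhere(dt >= r_eff + 1.0)
    centroid = deep.mean(axis=0)
    # jitter among deep voxels: pick the deep voxel closest to a jittered centroid
    target = centroid + rng.normal(scale=1.5, size=3)
    center = deep[np.argmin(((deep - target) ** 2).sum(axis=1))]
    return tuple(int(c) for c in center), r_eff


def _nearest_k(coords: np.ndarray, center, k: int) -> np.ndarray:
    d2 = ((coords - np.asarray(center)) ** 2).sum(axis=1)
    return coords[np.argsort(d2, kind="stable")[:k]]


def _carve_tumor(dims, center, radius, truth, rng):
    """Return (tumor label map, per-voxel lesion masks, realized truth)."""
    truth = copy.deepcopy(truth)
    sphere = _sphere(dims, center, radius)
    coords = np.argwhere(sphere)
    n = len(coords)

    f = GRADE_FRACTION[truth.enhancement_grade or "moderate"]
    n_et = int(round(f * n))
    # planar split along x gives contiguous compartments
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    et_coords = coords[order[:n_et]]
    net_coords = coords[order[n_et:]]

    tumor = np.zeros(dims, dtype=np.int16)
    tumor[tuple(et_coords.T)] = TUMOR_ENHANCING
    if len(net_coords):
        tumor[tuple(net_coords.T)] = TUMOR_NONENHANCING

    cyst_mask = np.zeros(dims, dtype=bool)
    nec_mask = np.zeros(dims, dtype=bool)
    if len(net_coords):
        pool = net_coords
        centroid = pool.mean(axis=0)
        if truth.cyst:
            k = min(max(8, int(round(0.10 * n))), int(0.45 * len(pool)))
            if k >= 6:
                sel = _nearest_k(pool, centroid + (0, radius * 0.45, 0), k)
                cyst_mask[tuple(sel.T)] = True
            else:
                truth.cyst = False
                truth.flags["cyst"] = "not realizable at this tumor size"
        if truth.necrosis:
            # keep a one-voxel solid gap to the cyst so components stay separate
            blocked = ndimage.binary_dilation(cyst_mask, iterations=2)
            pool2 = pool[~blocked[tuple(pool.T)]]
            k = min(max(8, int(round(0.07 * n))), int(0.45 * len(pool2)))
            if k >= 6:
                sel = _nearest_k(pool2, centroid - (0, radius * 0.45, 0), k)
                nec_mask[tuple(sel.T)] = True
            else:
                truth.necrosis = False
                truth.flags["necrosis"] = "not realizable at this tumor size"

    haem_mask = np.zeros(dims, dtype=bool)
    if truth.haemorrhage:
        pool = coords[~(cyst_mask | nec_mask)[tuple(coords.T)]]
        if len(pool) >= 10:
            n_foci = int(rng.integers(1, 4))
            order2 = np.lexsort((pool[:, 0], pool[:, 1], pool[:, 2]))
            picks = [pool[order2[int(q * (len(pool) - 1))]]
                     for q in (0.30, 0.60, 0.85)[:n_foci]]
            for c in picks:
                focus = _nearest_k(pool, c, 12)
                haem_mask[tuple(focus.T)] = True
        else:
            truth.haemorrhage = False
            truth.flags["haemorrhage"] = "not realizable at this tumor size"

    lesions = {"cyst": cyst_mask, "necrosis": nec_mask, "haemorrhage": haem_mask}
    return tumor, lesions, truth


# ------------------------------------------------------------- intensities


def _paint_study(dims, lobes, gm_mask, tumor, lesions, truth, rng, noise_sd):
    seqs = {}
    tissue_masks = {
        "forebrain": (lobes == LOBE_FOREBRAIN) & ~gm_mask,
        "gm": gm_mask,
        "brainstem": lobes == LOBE_BRAINSTEM,
        "cerebellum": lobes == LOBE_CEREBELLUM,
    }
    et = tumor == TUMOR_ENHANCING
    net = tumor == TUMOR_NONENHANCING
    wt = et | net
    for si, seq in enumerate(SEQUENCES):
        vol = np.full(dims, BACKGROUND_INTENSITY)
        for tissue, values in TISSUE_INTENSITIES.items():
            vol[tissue_masks[tissue]] = values[si]
        if truth is not None and wt.any():
            base = GM_INTENSITY
            if seq in ("t1", "t1c"):
                solid = base * INTENSITY_CLASS_FACTOR[truth.t1_intensity]
            elif seq == "t2":
                solid = base * INTENSITY_CLASS_FACTOR[truth.t2_intensity]
            elif seq == "flair":
                solid = base * INTENSITY_CLASS_FACTOR[truth.flair_intensity]
            elif seq == "dwi":
                solid = base * (DWI_RESTRICTED if truth.diffusion_restriction else 1.0)
            else:  # adc
                solid = base * (ADC_RESTRICTED if truth.diffusion_restriction else 1.0)
            vol[wt] = solid
            if seq in ("t1", "t1c"):
                vol[lesions["cyst"] | lesions["necrosis"]] = CYST_T1
                vol[lesions["haemorrhage"]] = HAEMORRHAGE_T1
            elif seq == "t2":
                vol[lesions["cyst"] | lesions["necrosis"]] = CYST_T2
            elif seq == "flair":
                vol[lesions["cyst"]] = CYST_FLAIR
                vol[lesions["necrosis"]] = NECROSIS_FLAIR
            if seq == "t1c" and et.any():
                if truth.enhancement_pattern == "heterogeneous":
                    idx = np.argwhere(et)
                    half = rng.permutation(len(idx)) < len(idx) // 2
                    vol[tuple(idx[half].T)] = ENHANCE_HET_LO
                    vol[tuple(idx[~half].T)] = ENHANCE_HET_HI
                else:
                    vol[et] = ENHANCE_HOMOGENEOUS
                vol[lesions["haemorrhage"] & et] = HAEMORRHAGE_T1
        assert vol.min() >= 0 and vol.max() <= 2030
        if noise_sd > 0:
            vol = vol + rng.normal(scale=noise_sd, size=dims)
        seqs[seq] = np.clip(vol, 0.0, 2030.0)
    return seqs


# ------------------------------------------------------------- public API


def generate_phantom(spec: PhantomSpec, case_id: str = "case") -> PhantomCase:
    """Generate one phantom study realizing ``spec.target_features``."""
    rng = np.random.default_rng(spec.seed)
    dims = spec.grid_dims
    lobes = brain_geometry(dims)
    gm_mask = grey_matter_rim(lobes)

    tumor = np.zeros(dims, dtype=np.int16)
    lesions = {k: np.zeros(dims, dtype=bool) for k in ("cyst", "necrosis", "haemorrhage")}
    truth = None
    if spec.tumor_class != "none":
        truth = spec.target_features or SemanticFeatures.from_dict(
            TYPICAL_FEATURES[spec.tumor_class])
        truth = copy.deepcopy(truth)
        center, radius = _place_tumor_center(lobes, gm_mask, truth.location,
                                             spec.tumor_radius_vox, rng)
        tumor, lesions, truth = _carve_tumor(dims, center, radius, truth, rng)

    seqs = _paint_study(dims, lobes, gm_mask, tumor, lesions, truth, rng,
                        spec.noise_sd)
    study = MRIStudy(sequences=seqs, spacing=tuple(spec.spacing_mm))
    return PhantomCase(case_id=case_id, study=study, lobes=lobes, tumor=tumor,
                       gm_mask=gm_mask, truth=truth,
                       class_label=spec.tumor_class, spec=spec)


def sample_class_features(tumor_class: str, rng: np.random.Generator,
                          mode: str = "prevalence") -> SemanticFeatures:
    """Draw a semantic-feature profile for a tumor class.

    ``mode='typical'`` returns the class's modal profile; ``'prevalence'``
    samples each field independently from the reference-cohort prevalences.
    T1 hyperintensity never occurs in the cohort, which the phantom relies
    on (a globally T1-bright tumor would mimic haemorrhage).
    """
    if mode == "typical":
        return SemanticFeatures.from_dict(TYPICAL_FEATURES[tumor_class])
    if mode != "prevalence":
        raise ValueError(f"unknown feature sampling mode {mode!r}")
    prev = class_prevalences()[tumor_class]

    def draw(dist):
        levels = list(dist)
        return levels[rng.choice(len(levels), p=np.array([dist[k] for k in levels]))]

    return SemanticFeatures(
        t1_intensity=draw(prev["t1_intensity"]),
        t2_intensity=draw(prev["t2_intensity"]),
        flair_intensity=draw(prev["flair_intensity"]),
        enhancement_pattern=draw(prev["enhancement_pattern"]),
        enhancement_grade=draw(prev["enhancement_grade"]),
        location=draw(prev["location"]),
        haemorrhage=bool(rng.random() < prev["haemorrhage"]),
        diffusion_restriction=bool(rng.random() < prev["diffusion_restriction"]),
        cyst=bool(rng.random() < prev["cyst"]),
        necrosis=bool(rng.random() < prev["necrosis"]),
    )


MANIFEST_COLUMNS = ("case_id", "class", "path_t1", "path_t1c", "path_t2",
                    "path_flair", "path_dwi", "path_adc", "path_lobes",
                    "path_tumor", "path_gm", "path_truth")


def generate_cohort(n: int, class_mix: dict, base_spec: PhantomSpec,
                    seed: int, out_dir=None, feature_sampling: str = "prevalence"):
    """Generate ``n`` phantoms with class counts matching ``class_mix``.

    Returns ``(manifest, cases)``; when ``out_dir`` is given, each case's
    sequences and masks are written as ``.nii.gz`` plus a JSON truth record,
    and the manifest as CSV.  Deterministic (byte-identical outputs) for a
    fixed seed.
    """
    classes = list(class_mix)
    props = [class_mix[c] for c in classes]
    counts = largest_remainder_counts(n, props)
    rng = np.random.default_rng(seed)
    labels = [c for c, k in zip(classes, counts) for _ in range(k)]
    case_seeds = rng.integers(0, 2 ** 31, size=n)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows, cases = [], []
    for i, cls in enumerate(labels):
        case_id = f"phantom_{i:03d}"
        features = None
        radius = base_spec.tumor_radius_vox
        if cls != "none":
            features = sample_class_features(cls, rng, feature_sampling)
            radius = base_spec.tumor_radius_vox * float(rng.uniform(0.8, 1.2))
        spec = replace(base_spec, tumor_class=cls, target_features=features,
                       tumor_radius_vox=radius, seed=int(case_seeds[i]))
        case = generate_phantom(spec, case_id=case_id)
        cases.append(case)
        row = {"case_id": case_id, "class": cls}
        if out_dir is not None:
            cdir = out_dir / case_id
            cdir.mkdir(exist_ok=True)
            for seq, vol in case.study.sequences.items():
                p = cdir / f"{seq}.nii.gz"
                save_nifti(vol.astype(np.float32), spec.spacing_mm, p)
                row[f"path_{seq}"] = str(p)
            for name, vol in (("lobes", case.lobes), ("tumor", case.tumor),
                              ("gm", case.gm_mask.astype(np.int16))):
                p = cdir / f"{name}.nii.gz"
                save_nifti(vol, spec.spacing_mm, p)
                row[f"path_{name}"] = str(p)
            p = cdir / "truth.json"
            save_json({"class": cls, "seed": int(case_seeds[i]),
                       "features": None if case.truth is None else case.truth.to_dict()}, p)
            row["path_truth"] = str(p)
        rows.append(row)

    manifest = pd.DataFrame(rows, columns=[c for c in MANIFEST_COLUMNS
                                           if out_dir is not None or c in ("case_id", "class")])
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, cases
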