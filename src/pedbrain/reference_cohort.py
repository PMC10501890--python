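"""Reference-cohort tables: feature-by-subtype counts for 75 paediatric brain tumors.

These are the published univariate contingency tables of an institutional
cohort (14 ependymoma, 21 medulloblastoma, 19 pilocytic astrocytoma, 21
brainstem glioma), kept here as plain count data.  They serve two roles:

* inputs for the :mod:`pedbrain.stats` layer (chi-square tests, odds
  ratios) so the statistics can be exercised on real printed counts, and
* per-class feature prevalences that parameterize the phantom cohort
  generator (:mod:`pedbrain.phantom`).

Clinical-feature rows use per-feature denominators (11/18/19/18 for the
clinical assessments), which is why their column sums differ from the
imaging rows.  The cranial-nerve row is transcribed as printed although its
pilocytic-astrocytoma column is internally inconsistent.
"""

from __future__ import annotations

import numpy as np

#: column (group) order of every table below
GROUPS = (
    "ependymoma",
    "medulloblastoma",
    "pilocytic_astrocytoma",
    "brainstem_glioma",
)

#: cohort sizes per group (imaging features)
GROUP_N = {"ependymoma": 14, "medulloblastoma": 21,
           "pilocytic_astrocytoma": 19, "brainstem_glioma": 21}

# --------------------------------------------------------------- clinical

CLINICAL_TABLES = {
    "seizures": {"yes": (0, 1, 4, 2), "no": (11, 17, 15, 16)},
    "gait_ataxia": {"yes": (3, 10, 5, 17), "no": (8, 8, 14, 1)},
    "cranial_nerve_palsy": {"yes": (3, 6, 6, 15), "no": (8, 12, 10, 3)},
}

# --------------------------------------------------------------- imaging

IMAGING_TABLES = {
    "t1wi": {
        "hypointense": (12, 21, 17, 20),
        "isointense": (2, 0, 2, 1),
    },
    "t2wi": {
        "hyperintense": (2, 0, 6, 6),
        "hypointense": (1, 0, 0, 0),
        "isointense": (11, 21, 13, 15),
    },
    "flair": {
        "hyperintense": (11, 1, 12, 6),
        "isointense": (3, 20, 7, 15),
    },
    "enhancement_pattern": {
        "homogeneous": (1, 5, 5, 0),
        "heterogeneous": (13, 16, 14, 21),
    },
    "enhancement_grade": {
        "mild": (3, 6, 5, 17),
        "moderate": (5, 5, 6, 4),
        "severe": (6, 10, 8, 0),
    },
    "haemorrhage": {"no": (5, 13, 18, 16), "yes": (9, 8, 1, 5)},
    "calcification": {"no": (9, 20, 19, 21), "yes": (5, 1, 0, 0)},
    "diffusion_restriction": {
        "no": (10, 1, 13, 14),
        "yes": (3, 16, 4, 6),
    },
    "cyst": {"no": (4, 2, 5, 20), "yes": (10, 19, 14, 1)},
    "necrosis": {"no": (4, 20, 19, 13), "yes": (10, 1, 0, 8)},
    "tumor_margins": {
        "well_defined": (6, 19, 15, 3),
        "ill_defined": (8, 2, 4, 18),
    },
    "tumor_location": {
        "forebrain": (6, 0, 13, 0),
        "brainstem": (0, 0, 0, 21),
        "cerebellum_fourth_ventricle": (8, 21, 6, 0),
    },
    "laterality": {
        "right": (2, 1, 4, 3),
        "left": (4, 1, 4, 2),
        "midline": (8, 19, 11, 16),
    },
    "oedema": {
        "no": (4, 15, 7, 5),
        "less_than_tumor": (9, 6, 10, 16),
        "equal_to_tumor": (0, 0, 1, 0),
        "more_than_tumor": (1, 0, 1, 0),
    },
    "midline_shift": {"no": (12, 21, 17, 21), "yes": (2, 0, 2, 0)},
    "hydrocephalus": {"absent": (5, 0, 8, 12), "present": (9, 21, 11, 9)},
}


def table_array(name: str):
    """Return ``(levels, counts)`` for a named cohort table as a 2D array."""
    src = CLINICAL_TABLES.get(name) or IMAGING_TABLES.get(name)
    if src is None:
        raise KeyError(f"unknown cohort table {name!r}")
    levels = tuple(src)
    return levels, np.array([src[k] for k in levels], dtype=int)


# ------------------------------------------------- detection confusion counts
# Held-out test set of the reference study: 21 scans (18 tumors, 3 normal);
# 16 tumors found, 2 missed, no false positives.
DETECTION_COUNTS = {"tp": 16, "fn": 2, "fp": 0, "tn": 3}


# ------------------------------------------------- generator parameterization


def _p(table: str, level: str) -> dict:
    levels, counts = table_array(table)
    col = counts[levels.index(level)] / counts.sum(axis=0)
    return dict(zip(GROUPS, col))


def class_prevalences() -> dict:
    """Per-class probabilities of the generator-relevant features.

    Derived from the cohort tables above; intensity classes collapse to a
    categorical distribution, lesion features to Bernoulli probabilities.
    """
    out = {}
    for gi, g in enumerate(GROUPS):
        def dist(table):
            levels, counts = table_array(table)
            col = counts[:, gi].astype(float)
            return dict(zip(levels, col / col.sum()))

        out[g] = {
            "t1_intensity": dist("t1wi"),
            "t2_intensity": dist("t2wi"),
            "flair_intensity": dist("flair"),
            "enhancement_pattern": dist("enhancement_pattern"),
            "enhancement_grade": dist("enhancement_grade"),
            "location": dist("tumor_location"),
            "haemorrhage": _p("haemorrhage", "yes")[g],
            "diffusion_restriction": _p("diffusion_restriction", "yes")[g],
            "cyst": _p("cyst", "yes")[g],
            "necrosis": _p("necrosis", "yes")[g],
        }
    return out


#: modal ("typical") feature profile per class, used when a cohort should
#: carry each class's characteristic presentation rather than sampled ones
TYPICAL_FEATURES = {
    "ependymoma": dict(
        t1_intensity="hypointense", t2_intensity="isointense",
        flair_intensity="hyperintense", enhancement_pattern="heterogeneous",
        enhancement_grade="severe", location="cerebellum_fourth_ventricle",
        haemorrhage=True, diffusion_restriction=False, cyst=True,
        necrosis=True,
    ),
    "medulloblastoma": dict(
        t1_intensity="hypointense", t2_intensity="isointense",
        flair_intensity="isointense", enhancement_pattern="heterogeneous",
        enhancement_grade="severe", location="cerebellum_fourth_ventricle",
        haemorrhage=False, diffusion_restriction=True, cyst=True,
        necrosis=False,
    ),
    "pilocytic_astrocytoma": dict(
        t1_intensity="hypointense", t2_intensity="isointense",
        flair_intensity="hyperintense", enhancement_pattern="heterogeneous",
        enhancement_grade="severe", location="forebrain",
        haemorrhage=False, diffusion_restriction=False, cyst=True,
        necrosis=False,
    ),
    "brainstem_glioma": dict(
        t1_intensity="hypointense", t2_intensity="isointense",
        flair_intensity="isointense", enhancement_pattern="heterogeneous",
        enhancement_grade="mild", location="brainstem",
        haemorrhage=False, diffusion_restriction=False, cyst=False,
        necrosis=False,
    ),
}
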