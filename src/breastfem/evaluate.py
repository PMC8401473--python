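"""Quantitative evaluation: target registration error and cohort statistics.

TRE is the 3D Euclidean distance between the lesion centroid in the fixed
(MR-like) image and in the registered moving (PET-like) image.  Cohort
summaries mirror the study's analyses: low/high-density and small/large-
volume group comparisons by Welch's unpaired t-test, and Pearson
correlation of image features against TRE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .volume import LabelMap, Label

__all__ = ["lesion_centroid", "tre", "lesion_location_ratio",
           "group_compare", "feature_correlation", "TREReport"]


@dataclass
class TREReport:
    """Per-case registration outcome and the features used in the cohort
    analysis (lesion size mm, nipple displacement mm, lesion location
    ratio, volumetric density, breast volume mL, optionally weight)."""

    case_id: str
    C_MR: np.ndarray
    C_PET: np.ndarray
    tre: float
    features: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"case_id": self.case_id, "C_MR": np.asarray(self.C_MR).tolist(),
                "C_PET": np.asarray(self.C_PET).tolist(), "tre_mm": self.tre,
                "features": {k: float(v) for k, v in self.features.items()}}


def lesion_centroid(source, threshold_frac: float = 0.5) -> np.ndarray:
    """Lesion centroid in world mm.

    For a :class:`LabelMap`, the unweighted centroid of the lesion voxels.
    For a scalar :class:`Volume` (a warped PET hot spot), the
    intensity-weighted centroid of the voxels above ``threshold_frac`` of
    the maximum — PET lesions have no crisp boundary, so a half-maximum
    delineation stands in for one.
    """
    if isinstance(source, LabelMap):
        mask = source.mask(Label.LESION)
        if not mask.any():
            raise ValueError("label map contains no lesion voxels")
        idx = np.argwhere(mask)
        return source.origin + idx.mean(axis=0) * source.spacing
    v = np.asarray(source.data, float)
    peak = v.max()
    mask = v >= threshold_frac * peak
    if not mask.any() or peak <= 0:
        raise ValueError("no hot spot above threshold")
    idx = np.argwhere(mask)
    w = v[mask]
    com = (idx * w[:, None]).sum(axis=0) / w.sum()
    return source.origin + com * source.spacing


def tre(C_MR, C_PET) -> float:
    """3D target registration error ``||C_MR - C_PET||`` in mm."""
    a = np.asarray(C_MR, float)
    b = np.asarray(C_PET, float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("centroids must be 3-vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite centroid coordinates")
    return float(np.linalg.norm(a - b))


def lesion_location_ratio(lesion_centroid_mm, chest_wall_point,
                          chest_wall_normal, surface_vertices) -> float:
    """Lesion depth ratio: distance to the chest wall over the farthest
    surface vertex's distance — 0 at the wall, 1 at the breast surface
    apex."""
    verts = np.asarray(surface_vertices, float)
    if verts.ndim != 2 or len(verts) == 0:
        raise ValueError("empty breast surface")
    n = np.asarray(chest_wall_normal, float)
    n = n / np.linalg.norm(n)
    p0 = np.asarray(chest_wall_point, float)
    d_far = np.abs((verts - p0) @ n).max()
    if d_far <= 0:
        raise ValueError("degenerate breast surface (no extent off the wall)")
    d = abs(float((np.asarray(lesion_centroid_mm, float) - p0) @ n))
    return min(d / d_far, 1.0)


def group_compare(tre_values, groups, labels=("low", "high")) -> dict:
    """Welch two-sample t-test between two groups of TRE values.

    ``groups`` is a boolean array (True -> second group).  Reports per-group
    n, mean, SD, the t statistic, two-sided p, and the significance flag at
    0.05.  Welch's unequal-variance form is used for the unpaired test.
    """
    x = np.asarray(tre_values, float)
    g = np.asarray(groups, bool)
    a, b = x[~g], x[g]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two cases")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        labels[0]: {"n": len(a), "mean": float(a.mean()), "sd": float(a.std(ddof=1))},
        labels[1]: {"n": len(b), "mean": float(b.mean()), "sd": float(b.std(ddof=1))},
        "t": float(t), "p": float(p), "significant_at_0.05": bool(p < 0.05),
        "test": "Welch unpaired t-test",
    }


def feature_correlation(features: dict, tre_values) -> dict:
    """Pearson R and p of each feature against TRE.

    Zero-variance features are reported with ``R = None`` rather than a
    spurious value.
    """
    y = np.asarray(tre_values, float)
    if len(y) < 3:
        raise ValueError("need at least 3 cases")
    out = {}
    for name, vals in features.items():
        x = np.asarray(vals, float)
        if len(x) != len(y):
            raise ValueError(f"feature {name!r} length mismatch")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[name] = {"R": None, "p": None, "note": "zero variance"}
            continue
        r, p = stats.pearsonr(x, y)
        out[name] = {"R": float(r), "p": float(p)}
    return out
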