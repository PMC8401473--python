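"""Preprocessing of the supine/prone image pair.

Covers the steps applied to the clinical volumes before model building:
linear resampling of all modalities onto a common isotropic grid, cropping
to the ipsilateral breast, intensity-based fuzzy c-means segmentation of
the breast interior into adipose and fibro-glandular tissue, and the
volumetric density / breast volume features used in the cohort analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .volume import Volume, LabelMap, Label

__all__ = ["resample_isotropic", "crop_breast", "fcm_segment", "FcmResult",
           "breast_volume_and_density"]


def resample_isotropic(v: Volume, target_spacing: float = 1.0,
                       order: int = 1) -> Volume:
    """Trilinear resampling onto an isotropic grid.

    The physical extent spanned by the voxel centres is preserved (within
    one voxel); origin and orientation are unchanged.  Label maps should be
    resampled with ``order=0``.
    """
    if not target_spacing > 0:
        raise ValueError("target_spacing must be positive")
    if not np.all(np.isfinite(v.data)):
        raise ValueError("volume contains non-finite voxels")
    old_n = np.array(v.shape)
    extent = (old_n - 1) * v.spacing
    new_n = np.floor(extent / target_spacing + 1e-9).astype(int) + 1
    if np.allclose(v.spacing, target_spacing) and np.all(new_n == old_n):
        return replace(v, data=v.data.copy())
    grids = np.meshgrid(*(np.arange(n) * target_spacing / s
                          for n, s in zip(new_n, v.spacing)), indexing="ij")
    data = map_coordinates(np.asarray(v.data, float), np.stack(grids),
                           order=order, mode="nearest")
    out = replace(v, data=data, spacing=np.full(3, float(target_spacing)))
    if isinstance(v, LabelMap):
        out.data = np.rint(data).astype(np.int64)
    return out


def crop_breast(v: Volume, labels: LabelMap, margin: float = 0.0
                ) -> tuple[Volume, LabelMap]:
    """Crop both volumes to the breast bounding box plus a margin (mm).

    The box is the minimal axis-aligned bounding box of the non-background
    breast labels, grown by ``margin`` and clamped to the image bounds — no
    padding is invented.
    """
    if v.shape != labels.shape:
        raise ValueError("volume and label map shapes differ")
    mask = labels.breast_mask()
    if not mask.any():
        raise ValueError("label map contains no breast voxels")
    idx = np.argwhere(mask)
    mvox = np.ceil(margin / labels.spacing - 1e-9).astype(int)
    lo = np.maximum(idx.min(axis=0) - mvox, 0)
    hi = np.minimum(idx.max(axis=0) + mvox, np.array(v.shape) - 1)
    sl = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
    new_origin = v.index_to_world(lo)
    vc = replace(v, data=v.data[sl].copy(), origin=new_origin)
    lc = replace(labels, data=labels.data[sl].copy(), origin=new_origin)
    return vc, lc


@dataclass
class FcmResult:
    """Outcome of a fuzzy c-means run on the masked voxels.

    ``memberships`` has one row per masked voxel and one column per cluster
    (rows sum to 1); ``centroids`` are sorted ascending; ``objective`` is
    the trace of the within-cluster fuzzy objective across iterations.
    """

    memberships: np.ndarray
    centroids: np.ndarray
    iterations: int
    final_shift: float
    converged: bool
    objective: list


def fcm_segment(v: Volume, mask: np.ndarray, c: int = 2, m: float = 2.0,
                tol: float = 1e-5, max_iter: int = 300
                ) -> tuple[FcmResult, LabelMap]:
    """Fuzzy c-means segmentation of the breast interior.

    Standard intensity FCM with fuzzifier ``m``: memberships
    ``u_ik = (1/d_ik^2)^(1/(m-1))`` normalised over clusters, centroids the
    ``u^m``-weighted intensity means; iterated until the largest centroid
    shift falls below ``tol`` (relative to the intensity range).  A voxel
    coinciding exactly with a centroid receives membership one for it.
    Centroids start at evenly spaced intensity percentiles (25/75 for
    ``c=2``), which keeps the stage deterministic.

    Hard labels are assigned by maximum membership; the lowest-centroid
    cluster becomes adipose and the highest fibro-glandular (fat is the
    darker tissue on CT).  With ``c > 2`` the intermediate clusters are
    assigned to the nearer of the two extremes by centroid distance.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != v.shape:
        raise ValueError("mask shape differs from the volume")
    if not mask.any():
        raise ValueError("empty mask")
    if c < 2:
        raise ValueError("need at least two clusters")
    x = np.asarray(v.data, float)[mask]
    qs = np.linspace(0, 100, 2 * c + 1)[1::2]        # 25/75 for c=2
    centroids = np.percentile(x, qs)
    scale = max(np.ptp(x), 1e-12)

    expo = 1.0 / (m - 1.0)
    u = np.empty((x.size, c))
    objective: list[float] = []
    converged = False
    shift = np.inf
    for it in range(1, max_iter + 1):
        d2 = (x[:, None] - centroids[None, :]) ** 2
        exact = d2 < 1e-30
        with np.errstate(divide="ignore"):
            w = d2 ** (-expo)
        u = w / w.sum(axis=1, keepdims=True)
        hit = exact.any(axis=1)
        if hit.any():
            u[hit] = exact[hit] / exact[hit].sum(axis=1, keepdims=True)
        um = u ** m
        objective.append(float((um * d2).sum()))
        new_c = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = float(np.abs(new_c - centroids).max())
        centroids = new_c
        if shift / scale < tol:
            converged = True
            break
    if not converged:
        import warnings
        warnings.warn(f"fuzzy c-means did not converge in {max_iter} "
                      f"iterations (last shift {shift:.3g})")

    order = np.argsort(centroids)
    centroids = centroids[order]
    u = u[:, order]
    result = FcmResult(memberships=u, centroids=centroids, iterations=it,
                       final_shift=shift, converged=converged,
                       objective=objective)

    hard = np.argmax(u, axis=1)
    # map clusters to the two tissues: nearest extreme centroid
    tissue_of = np.where(
        np.abs(centroids - centroids[0]) <= np.abs(centroids - centroids[-1]),
        Label.ADIPOSE, Label.FIBROGLANDULAR)
    lab = np.zeros(v.shape, dtype=np.int64)
    lab[mask] = tissue_of[hard]
    labels = LabelMap(data=lab, spacing=v.spacing.copy(),
                      origin=v.origin.copy(), orientation=v.orientation)
    return result, labels


def breast_volume_and_density(labels: LabelMap) -> tuple[float, float]:
    """Breast volume (mL) and volumetric density.

    Volume counts adipose, fibro-glandular and lesion voxels; density is
    the fibro-glandular fraction of the breast region (fibro-glandular
    volume over breast volume).
    """
    n_breast = int(labels.breast_mask().sum())
    if n_breast == 0:
        raise ValueError("label map contains no breast voxels")
    n_gland = int(labels.mask(Label.FIBROGLANDULAR).sum())
    voxel_mm3 = float(np.prod(labels.spacing))
    volume_ml = n_breast * voxel_mm3 / 1000.0
    return volume_ml, n_gland / n_breast
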