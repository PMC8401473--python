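"""Image-space warping of the FE solution and landmark-based refinement.

The converged node displacements are interpolated to a dense voxel field,
the functional (PET-like) volume is warped through it by backward mapping,
and a closed-form landmark transform estimated from chest-wall points
refines the result.  With exactly three landmark pairs a 12-dof affine is
under-determined, so the refinement is the least-squares similarity
transform (rotation, uniform scale, translation); four or more non-coplanar
pairs unlock the full affine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .volume import Volume

__all__ = ["AffineTransform", "field_to_grid", "warp_volume",
           "affine_from_landmarks", "fuse_overlay"]


@dataclass(frozen=True)
class AffineTransform:
    """World-mm affine map ``x -> A x + t``."""

    A: np.ndarray
    t: np.ndarray
    kind: str = "affine"           # rigid | similarity | affine

    def __post_init__(self):
        A = np.asarray(self.A, float)
        if A.shape != (3, 3) or abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("linear part must be a non-singular 3x3 matrix")
        if self.kind == "rigid":
            if not (np.allclose(A @ A.T, np.eye(3), atol=1e-8)
                    and np.linalg.det(A) > 0):
                raise ValueError("rigid transform must be a proper rotation")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self.A.T + self.t

    def inverse(self) -> "AffineTransform":
        Ai = np.linalg.inv(self.A)
        return AffineTransform(A=Ai, t=-Ai @ self.t, kind=self.kind)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.A
        M[:3, 3] = self.t
        return M

    def save(self, path) -> None:
        np.savetxt(path, self.matrix(), header=f"kind: {self.kind}")

    @classmethod
    def identity(cls, kind="rigid") -> "AffineTransform":
        return cls(A=np.eye(3), t=np.zeros(3), kind=kind)


def field_to_grid(nodes: np.ndarray, displacements: np.ndarray,
                  target: Volume, extrapolate_mm: float = 2.0) -> Volume:
    """Interpolate scattered node displacements onto a voxel grid.

    Linear (barycentric) interpolation inside the convex support of the
    nodes; voxels within ``extrapolate_mm`` outside the support take the
    displacement of the nearest node; everything farther away is zero.
    Returns a 3-channel Volume on the target grid.
    """
    nodes = np.asarray(nodes, float)
    displacements = np.asarray(displacements, float)
    if len(nodes) == 0:
        raise ValueError("empty displacement field")
    grids = np.meshgrid(*(np.arange(n) * s + o for n, s, o in
                          zip(target.shape, target.spacing, target.origin)),
                        indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    interp = LinearNDInterpolator(nodes, displacements, fill_value=np.nan)
    vals = interp(pts)
    out = np.nan_to_num(vals, nan=0.0)
    missing = np.isnan(vals[:, 0])
    if missing.any():
        tree = cKDTree(nodes)
        d, j = tree.query(pts[missing], k=1)
        near = d <= extrapolate_mm
        rows = np.flatnonzero(missing)[near]
        out[rows] = displacements[j[near]]
    return replace(target, data=out.reshape(*target.shape, 3),
                   spacing=target.spacing.copy())


def _sample_field(field: Volume, pts_mm: np.ndarray,
                  mode: str = "constant") -> np.ndarray:
    idx = field.world_to_index(pts_mm).T
    return np.stack([map_coordinates(field.data[..., k], idx, order=1,
                                     mode=mode, cval=0.0)
                     for k in range(3)], axis=1)


def invert_field(field: Volume, pts_mm: np.ndarray, tol: float = 0.1,
                 max_iter: int = 20) -> tuple[np.ndarray, int]:
    """Invert the forward map ``phi(x) = x + u(x)`` at target points.

    Fixed-point iteration ``x <- y - u(x)`` per point; returns the source
    points and the number of points that failed to reach ``tol`` mm (those
    keep their last iterate).
    """
    y = np.asarray(pts_mm, float)
    x = y.copy()
    active = np.ones(len(y), bool)
    for _ in range(max_iter):
        # extend the field by its edge values so boundary voxels converge
        u = _sample_field(field, x[active], mode="nearest")
        x_new = y[active] - u
        moved = np.linalg.norm(x_new - x[active], axis=1)
        x[active] = x_new
        still = moved > tol
        idx = np.flatnonzero(active)
        active[:] = False
        active[idx[still]] = True
        if not active.any():
            break
    return x, int(active.sum())


def warp_volume(moving: Volume, field: Volume, direction: str = "forward",
                ) -> Volume:
    """Warp a volume through a dense displacement field.

    ``direction="forward"`` treats the field as the forward map of material
    points (``x -> x + u(x)``, e.g. supine to prone) and resamples by
    backward mapping: each output voxel pulls its value from the
    fixed-point-inverted source location (tolerance 0.1 mm, 20 iterations).
    ``direction="backward"`` treats the field as already pointing from the
    output grid into the moving image.  Out-of-support voxels are
    zero-filled.
    """
    import warnings

    grids = np.meshgrid(*(np.arange(n) * s + o for n, s, o in
                          zip(field.shape, field.spacing, field.origin)),
                        indexing="ij")
    y = np.stack([g.ravel() for g in grids], axis=1)
    if direction == "forward":
        src, n_fail = invert_field(field, y)
        if n_fail:
            warnings.warn(f"displacement-field inversion not converged at "
                          f"{n_fail} voxel(s); nearest iterate used")
    elif direction == "backward":
        src = y + _sample_field(field, y)
    else:
        raise ValueError("direction must be 'forward' or 'backward'")
    idx = moving.world_to_index(src).T
    data = map_coordinates(np.asarray(moving.data, float), idx, order=1,
                           mode="constant", cval=0.0)
    return replace(moving, data=data.reshape(field.shape),
                   spacing=field.spacing.copy(), origin=field.origin.copy())


def affine_from_landmarks(src: np.ndarray, dst: np.ndarray,
                          kind: str | None = None) -> AffineTransform:
    """Least-squares landmark transform.

    With three pairs (or ``kind`` in {"rigid", "similarity"}) the
    closed-form orthogonal-Procrustes solution is used — rotation, optional
    uniform scale, translation; reflections are rejected.  With at least
    four non-coplanar pairs and ``kind="affine"`` a full 12-dof affine is
    fitted.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("landmark arrays must both be (n, 3)")
    n = len(src)
    if n < 3:
        raise ValueError("need at least 3 landmark pairs")
    if _collinear(src) or _collinear(dst):
        raise ValueError("landmarks are collinear")
    if kind is None:
        kind = "similarity" if n == 3 else "affine"
    if kind == "affine" and (n < 4 or _coplanar(src)):
        kind = "similarity"

    if kind == "affine":
        X = np.hstack([src, np.ones((n, 1))])
        sol, *_ = np.linalg.lstsq(X, dst, rcond=None)
        A, t = sol[:3].T, sol[3]
    else:
        cs, cd = src.mean(axis=0), dst.mean(axis=0)
        P, Q = src - cs, dst - cd
        H = P.T @ Q
        U, S, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        if d < 0 and S[-1] > 1e-9 * max(S[0], 1.0):
            # a full-rank correspondence that truly needs a reflection; for
            # coplanar (rank-2) sets the sign flip below is the standard
            # Kabsch correction, not a reflection
            raise ValueError("landmark correspondence requires a reflection")
        D = np.array([1.0, 1.0, d if d != 0 else 1.0])
        R = Vt.T @ np.diag(D) @ U.T
        if kind == "similarity":
            scale = (S * D).sum() / (P ** 2).sum()
        else:
            scale = 1.0
        A = scale * R
        t = cd - A @ cs
    return AffineTransform(A=A, t=t, kind=kind)


def _collinear(pts: np.ndarray, tol: float = 1e-8) -> bool:
    p = pts - pts.mean(axis=0)
    s = np.linalg.svd(p, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def _coplanar(pts: np.ndarray, tol: float = 1e-8) -> bool:
    p = pts - pts.mean(axis=0)
    s = np.linalg.svd(p, compute_uv=False)
    return s[2] <= tol * max(s[0], 1.0)


def fuse_overlay(fixed: Volume, warped_moving: Volume) -> Volume:
    """Two-colour fusion: moving in green, fixed in purple (red + blue).

    Each volume is robustly rescaled to [0, 1] between its 2nd and 98th
    intensity percentiles; the output is an RGB volume (last axis 3).
    """
    if not fixed.same_grid(warped_moving):
        raise ValueError("volumes are not on the same grid")

    def rescale(d):
        lo, hi = np.percentile(d, [2, 98])
        if hi <= lo:
            return np.zeros_like(np.asarray(d, float))
        return np.clip((d - lo) / (hi - lo), 0.0, 1.0)

    purple = rescale(fixed.data)
    green = rescale(warped_moving.data)
    rgb = np.stack([purple, green, purple], axis=-1)
    return replace(fixed, data=rgb, spacing=fixed.spacing.copy())
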