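"""Seeded synthetic supine/prone breast phantoms with known ground truth.

No clinical accession accompanies the method, so validation runs on
software phantoms that emulate the statistical structure of the study
cohorts: a hemispherical breast of adipose tissue on a flat chest wall,
fibro-glandular tissue at a configurable volumetric density (cohort
medians 0.15 and 0.27), a spherical lesion at a configurable depth ratio,
a nipple landmark at the apex, and three chest-wall landmarks.  The prone
appearance is produced by forward finite-element simulation with known
ground-truth moduli, which gives every downstream stage (segmentation,
inverse stiffness search, registration, TRE) an exact oracle.

The CT-like channel has distinct tissue means plus Gaussian noise; the
PET-like channel is near-uniform soft tissue with a hot lesion and a
4 mm-FWHM blur emulating low PET resolution; the MR-like prone volume is
the warped CT-like volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .volume import Volume, LabelMap, Label
from .materials import MaterialParams, default_materials

__all__ = ["PhantomSpec", "PhantomCase", "make_supine_phantom",
           "make_prone_ground_truth"]

# CT-like mean intensities (Hounsfield-flavoured) per tissue
_CT_MEANS = {Label.BACKGROUND: -1000.0, Label.ADIPOSE: -100.0,
             Label.FIBROGLANDULAR: 40.0, Label.LESION: 55.0,
             Label.CHEST_WALL: 120.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters; identical (spec, seed) pairs give bit-identical
    phantoms.

    breast_radius : hemisphere radius, mm
    chest_wall_extent : lateral margin of the chest-wall slab beyond the
        breast, mm
    volumetric_density_target : fibro-glandular volume fraction of the
        breast region, in (0, 1); the generator hits it to voxel precision
    lesion_location_ratio_target : lesion depth as distance-to-chest-wall
        over the farthest-vertex distance (0 at the wall, 1 at the nipple)
    true_E_adipose : ground-truth adipose Young's modulus, kPa
    stiffness_ratio : fibro-glandular over adipose modulus
    """

    breast_radius: float = 50.0
    chest_wall_extent: float = 8.0
    volumetric_density_target: float = 0.15
    lesion_radius: float = 5.0
    lesion_location_ratio_target: float = 0.5
    true_E_adipose: float = 2.0
    stiffness_ratio: float = 7.5
    voxel_spacing: float = 2.0
    seed: int = 0
    ct_noise_sigma: float = 12.0
    pet_fwhm: float = 4.0
    gland_texture_scale: float = 7.0   # mm, blob size of the gland pattern

    def __post_init__(self):
        if not 0.0 < self.volumetric_density_target < 1.0:
            raise ValueError("volumetric_density_target must lie in (0, 1)")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be positive")
        if self.breast_radius <= 0 or self.lesion_radius <= 0:
            raise ValueError("radii must be positive")
        r = self.lesion_location_ratio_target
        if not 0.0 <= r <= 1.0:
            raise ValueError("lesion_location_ratio_target must lie in [0, 1]")
        c = r * self.breast_radius
        if (c - self.lesion_radius < self.voxel_spacing
                or c + self.lesion_radius > self.breast_radius - self.voxel_spacing):
            raise ValueError(
                f"lesion of radius {self.lesion_radius} mm does not fit inside "
                f"the breast at location ratio {r}")

    def true_materials(self, base: MaterialParams | None = None) -> MaterialParams:
        """Ground-truth tissue parameters implied by these settings."""
        return (base or default_materials()).with_adipose_E(
            self.true_E_adipose, self.stiffness_ratio)


@dataclass
class PhantomCase:
    """One synthetic supine/prone pair with landmarks and ground truth."""

    ct_supine: Volume
    pet_supine: Volume
    labels_supine: LabelMap
    nipple_supine: np.ndarray
    lesion_centroid_supine: np.ndarray
    chest_wall_landmarks: np.ndarray          # (3, 3) mm, on the wall plane
    truth: PhantomSpec
    achieved_density: float
    mr_prone: Volume | None = None
    labels_prone: LabelMap | None = None
    nipple_prone: np.ndarray | None = None
    lesion_centroid_prone: np.ndarray | None = None
    chest_wall_landmarks_prone: np.ndarray | None = None
    forward_field: "Volume | None" = None      # dense supine->prone field
    forward_nipple_displacement: float | None = None

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ct_supine.save(out / "ct_supine.nii.gz")
        self.pet_supine.save(out / "pet_supine.nii.gz")
        self.labels_supine.save(out / "labels.nii.gz")
        if self.mr_prone is not None:
            self.mr_prone.save(out / "mr_prone.nii.gz")
        meta = {
            "truth": asdict(self.truth),
            "achieved_density": self.achieved_density,
            "nipple_supine": self.nipple_supine.tolist(),
            "lesion_centroid_supine": self.lesion_centroid_supine.tolist(),
            "chest_wall_landmarks": self.chest_wall_landmarks.tolist(),
        }
        for k in ("nipple_prone", "lesion_centroid_prone",
                  "chest_wall_landmarks_prone"):
            v = getattr(self, k)
            if v is not None:
                meta[k] = np.asarray(v).tolist()
        if self.forward_nipple_displacement is not None:
            meta["forward_nipple_displacement"] = self.forward_nipple_displacement
        (out / "landmarks.json").write_text(json.dumps(meta, indent=2))


def make_supine_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build the supine phantom (prone fields unset).

    The fibro-glandular pattern is the superlevel set of a sum of smoothed
    random anisotropic Gaussian blobs, thresholded at the quantile that
    makes the fibro-glandular voxel count match the density target exactly
    (so the achieved density deviates from the target only through the
    lesion carve-out, well within +-0.02).
    """
    rng = np.random.default_rng(spec.seed)
    R, sp = spec.breast_radius, spec.voxel_spacing
    pad = 2 * sp
    wall = spec.chest_wall_extent
    xs = np.arange(-R - pad, R + pad + sp / 2, sp)
    ys = np.arange(-wall, R + pad + sp / 2, sp)
    zs = xs.copy()
    origin = np.array([xs[0], ys[0], zs[0]])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    lab = np.zeros(X.shape, dtype=np.int64)
    lab[Y < 0] = Label.CHEST_WALL
    breast = (X ** 2 + Y ** 2 + Z ** 2 <= R ** 2) & (Y >= 0)
    lab[breast] = Label.ADIPOSE

    # lesion on the nipple axis at the target depth ratio, with a small
    # seeded lateral offset when it still fits
    cy = spec.lesion_location_ratio_target * R
    for _ in range(20):
        off = rng.normal(scale=0.08 * R, size=2)
        center = np.array([off[0], cy, off[1]])
        if np.linalg.norm(center) + spec.lesion_radius < R - sp:
            break
    else:
        center = np.array([0.0, cy, 0.0])
    lesion = ((X - center[0]) ** 2 + (Y - center[1]) ** 2
              + (Z - center[2]) ** 2) <= spec.lesion_radius ** 2
    lesion &= breast
    lab[lesion] = Label.LESION

    # fibro-glandular pattern: smoothed random blob field thresholded to the
    # exact target count among non-lesion breast voxels
    n_breast = int(breast.sum())
    n_gland = int(round(spec.volumetric_density_target * n_breast))
    candidates = breast & ~lesion
    blobfield = _blob_field(X, Y, Z, R, rng, spec.gland_texture_scale, sp)
    vals = blobfield[candidates]
    n_gland = min(n_gland, vals.size)
    if n_gland > 0:
        thr = np.partition(vals, vals.size - n_gland)[vals.size - n_gland]
        gland = candidates & (blobfield >= thr)
        lab[gland] = Label.FIBROGLANDULAR

    labels = LabelMap(data=lab, spacing=np.full(3, sp), origin=origin)
    n_g = int((lab == Label.FIBROGLANDULAR).sum())
    achieved = n_g / n_breast

    ct = _intensity_from_labels(lab)
    ct = ct + rng.normal(scale=spec.ct_noise_sigma, size=ct.shape)
    ct_vol = Volume(data=ct, spacing=np.full(3, sp), origin=origin)

    pet = np.zeros(lab.shape)
    pet[lab != Label.BACKGROUND] = 1.0
    pet[lab == Label.LESION] = 8.0
    sigma_vox = spec.pet_fwhm / 2.3548 / sp
    pet = gaussian_filter(pet, sigma_vox)
    pet += rng.normal(scale=0.02, size=pet.shape)
    pet_vol = Volume(data=pet, spacing=np.full(3, sp), origin=origin)

    nipple = np.array([0.0, R, 0.0])
    e = min(R * 0.8, R + wall - sp)
    landmarks = np.array([[-0.6 * e, 0.0, -0.5 * e],
                          [0.7 * e, 0.0, -0.4 * e],
                          [0.05 * e, 0.0, 0.8 * e]])
    lesion_centroid = _mask_centroid(lesion, origin, sp)
    return PhantomCase(ct_supine=ct_vol, pet_supine=pet_vol,
                       labels_supine=labels, nipple_supine=nipple,
                       lesion_centroid_supine=lesion_centroid,
                       chest_wall_landmarks=landmarks, truth=spec,
                       achieved_density=achieved)


def _intensity_from_labels(lab: np.ndarray) -> np.ndarray:
    lut = np.zeros(max(_CT_MEANS) + 1)
    for k, v in _CT_MEANS.items():
        lut[k] = v
    return lut[lab]


def _blob_field(X, Y, Z, R, rng, scale, sp) -> np.ndarray:
    """Sum of anisotropic Gaussian bumps at random centres in the breast."""
    vol = X.size * sp ** 3
    n_blobs = max(12, int(vol / (4 * scale) ** 3))
    f = np.zeros(X.shape)
    for _ in range(n_blobs):
        # bias toward the retroareolar core where glandular tissue sits
        c = rng.normal(scale=0.45 * R, size=3) * np.array([1.0, 0.8, 1.0])
        c[1] = abs(c[1])
        axes = rng.uniform(0.6, 1.8, size=3) * scale
        amp = rng.uniform(0.5, 1.5)
        f += amp * np.exp(-(((X - c[0]) / axes[0]) ** 2
                            + ((Y - c[1]) / axes[1]) ** 2
                            + ((Z - c[2]) / axes[2]) ** 2))
    return f


def _mask_centroid(mask: np.ndarray, origin, sp) -> np.ndarray:
    idx = np.argwhere(mask)
    return origin + idx.mean(axis=0) * sp


def make_prone_ground_truth(case: PhantomCase,
                            materials: MaterialParams | None = None,
                            fem_config=None, element_size: float = 4.0
                            ) -> PhantomCase:
    """Forward-simulate the prone appearance with the true moduli.

    Runs reference-state estimation and the prone-gravity solve on a mesh
    of the supine labels, interpolates the node displacements to a dense
    field, warps the CT-like volume into the MR-like prone volume and the
    labels into the prone label map, and records the ground-truth prone
    nipple and lesion centroid from the displacement field.
    """
    from . import fem as _fem
    from . import meshing as _meshing
    from . import register as _register

    if materials is None:
        materials = case.truth.true_materials()
    config = fem_config or _fem.FemConfig()

    mesh = _meshing.voxel_to_hex_mesh(case.labels_supine, element_size,
                                      nipple_mm=case.nipple_supine)
    disp = _fem.simulate_supine_to_prone(mesh, materials, config)

    dense = _register.field_to_grid(mesh.nodes, disp.u, case.ct_supine)
    mr = _register.warp_volume(case.ct_supine, dense, direction="forward")
    lab_float = Volume(data=np.asarray(case.labels_supine.data, float),
                       spacing=case.labels_supine.spacing.copy(),
                       origin=case.labels_supine.origin.copy(),
                       orientation=case.labels_supine.orientation)
    lab_w = _register.warp_volume(lab_float, dense, direction="forward")
    labels_prone = LabelMap(data=np.rint(lab_w.data).astype(np.int64),
                            spacing=lab_w.spacing, origin=lab_w.origin,
                            orientation=lab_w.orientation)

    nip_u = disp.u[mesh.nipple_node]
    lesion_u = _register._sample_field(dense, case.lesion_centroid_supine[None])[0]
    out = replace(case)
    out.mr_prone = mr
    out.labels_prone = labels_prone
    out.nipple_prone = case.nipple_supine + nip_u
    out.lesion_centroid_prone = case.lesion_centroid_supine + lesion_u
    out.chest_wall_landmarks_prone = case.chest_wall_landmarks.copy()
    out.forward_field = dense
    out.forward_nipple_displacement = float(np.linalg.norm(nip_u))
    return out
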