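"""End-to-end orchestration: phantom -> segment -> mesh -> solve ->
optimize -> register -> evaluate, as one reproducible run.

A :class:`RunConfig` round-trips losslessly through YAML; a run writes a
JSON manifest with per-stage outputs, parameters and checksums sufficient
to re-run bit-identically.  One global seed fans out to per-module seeds
by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import fem as _fem
from . import imageproc as _imageproc
from . import meshing as _meshing
from . import register as _register
from . import evaluate as _evaluate
from .inverse import E_LOWER_KPA, E_UPPER_KPA
from .materials import DEFAULT_STIFFNESS_RATIO
from .model import BreastRegistrationModel
from .phantom import PhantomSpec, make_supine_phantom, make_prone_ground_truth

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger(__name__)

ALL_STAGES = ("phantom", "segment", "mesh", "solve", "optimize", "register",
              "evaluate")

#: fixed per-module seed offsets fanned out from the global seed
_SEED_OFFSETS = {"phantom": 101}


@dataclass
class RunConfig:
    """Every knob of a pipeline run; defaults are the package defaults."""

    out_dir: str = "breastfem_run"
    stages: tuple = ALL_STAGES
    seed: int = 0
    # phantom
    breast_radius: float = 50.0
    volumetric_density_target: float = 0.15
    lesion_radius: float = 5.0
    lesion_location_ratio_target: float = 0.5
    true_E_adipose: float = 2.0
    voxel_spacing: float = 2.0
    # preprocessing
    resample_spacing: float = 0.0     # 0 keeps the native spacing
    crop_margin: float = 4.0
    fcm_clusters: int = 2
    fcm_fuzzifier: float = 2.0
    # mesh / fem
    element_size: float = 4.0
    skin_thickness: float = 1.0
    chest_wall_fixation: str = "ap"
    # optimization
    E_lower: float = E_LOWER_KPA
    E_upper: float = E_UPPER_KPA
    stiffness_ratio: float = DEFAULT_STIFFNESS_RATIO
    nipple_tol_mm: float = 1.0
    n_coarse: int = 12
    n_refine: int = 5
    refine_rounds: int = 2

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(**raw)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(breast_radius=self.breast_radius,
                           volumetric_density_target=self.volumetric_density_target,
                           lesion_radius=self.lesion_radius,
                           lesion_location_ratio_target=self.lesion_location_ratio_target,
                           true_E_adipose=self.true_E_adipose,
                           stiffness_ratio=self.stiffness_ratio,
                           voxel_spacing=self.voxel_spacing,
                           seed=self.seed + _SEED_OFFSETS["phantom"])

    def fem_config(self) -> "_fem.FemConfig":
        return _fem.FemConfig(chest_wall_fixation=self.chest_wall_fixation,
                              skin_thickness=self.skin_thickness)


def _checksum(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write the run manifest.

    Returns the manifest dict; on stage failure the manifest records the
    partial state and the exception is re-raised after writing it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "seed": config.seed}
    state: dict = {}

    def record(stage, **info):
        manifest["stages"][stage] = {"completed": True, **info}

    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            log.info("stage %s", stage)
            if stage == "phantom":
                case = make_supine_phantom(config.phantom_spec())
                case = make_prone_ground_truth(
                    case, fem_config=config.fem_config(),
                    element_size=config.element_size)
                case.save(out / "phantom")
                state["case"] = case
                record(stage, achieved_density=case.achieved_density,
                       forward_nipple_displacement=case.forward_nipple_displacement,
                       ct_checksum=_checksum(case.ct_supine.data))
            elif stage == "segment":
                case = state["case"]
                ct = case.ct_supine
                if config.resample_spacing > 0:
                    ct = _imageproc.resample_isotropic(ct, config.resample_spacing)
                mask = case.labels_supine.breast_mask()
                fcm, labels = _imageproc.fcm_segment(
                    case.ct_supine, mask, c=config.fcm_clusters,
                    m=config.fcm_fuzzifier)
                # carry lesion and chest wall through from the phantom truth
                keep = np.isin(case.labels_supine.data, (3, 4))
                labels.data[keep] = case.labels_supine.data[keep]
                labels.save(out / "labels_fcm.nii.gz")
                vol, dens = _imageproc.breast_volume_and_density(labels)
                state["labels"] = labels
                record(stage, centroids=fcm.centroids.tolist(),
                       iterations=fcm.iterations, breast_volume_ml=vol,
                       density=dens, labels_checksum=_checksum(labels.data))
            elif stage == "mesh":
                case = state["case"]
                labels = state.get("labels", case.labels_supine)
                mesh = _meshing.voxel_to_hex_mesh(labels, config.element_size,
                                                  nipple_mm=case.nipple_supine)
                _meshing.write_vtk(mesh, out / "mesh.vtk")
                state["mesh"] = mesh
                record(stage, n_elements=mesh.n_elements, n_nodes=mesh.n_nodes,
                       nodes_checksum=_checksum(mesh.nodes))
            elif stage == "solve":
                case = state["case"]
                mesh = state["mesh"]
                disp = _fem.simulate_supine_to_prone(
                    mesh, case.truth.true_materials(), config.fem_config())
                _meshing.write_vtk(mesh, out / "displacement.vtk",
                                   point_data={"u": disp.u})
                state["forward"] = disp
                record(stage, nipple_displacement=disp.nipple_displacement(),
                       newton_iterations=disp.newton_iterations,
                       u_checksum=_checksum(disp.u))
            elif stage == "optimize":
                case = state["case"]
                model = BreastRegistrationModel.from_case(
                    case, element_size=config.element_size,
                    skin_thickness=config.skin_thickness,
                    fem_config=config.fem_config())
                model._mesh = state.get("mesh")
                res = model.fit(lb=config.E_lower, ub=config.E_upper,
                                stiffness_ratio=config.stiffness_ratio,
                                tol=config.nipple_tol_mm,
                                n_coarse=config.n_coarse,
                                n_refine=config.n_refine,
                                refine_rounds=config.refine_rounds)
                (out / "optimization.json").write_text(
                    json.dumps(res.optimization.to_dict(), indent=2))
                state["results"] = res
                record(stage, **res.params,
                       objective_mm=res.optimization.objective,
                       converged=res.converged,
                       n_trials=len(res.optimization.history))
            elif stage == "register":
                res = state["results"]
                warped = res.warp(res.model.pet_supine)
                warped.save(out / "pet_registered.nii.gz")
                res.refine_transform.save(out / "refine_affine.txt")
                if res.model.mr_prone is not None:
                    fused = _register.fuse_overlay(res.model.mr_prone, warped)
                    np.save(out / "fusion_rgb.npy", fused.data)
                state["warped_pet"] = warped
                record(stage, warped_checksum=_checksum(warped.data),
                       refine_kind=res.refine_transform.kind)
            elif stage == "evaluate":
                case = state["case"]
                res = state["results"]
                c_pet = res.registered_lesion_centroid()
                c_mr = case.lesion_centroid_prone
                t = _evaluate.tre(c_mr, c_pet)
                vol, dens = _imageproc.breast_volume_and_density(case.labels_supine)
                ratio = _evaluate.lesion_location_ratio(
                    case.lesion_centroid_supine,
                    case.chest_wall_landmarks[0], [0, 1, 0],
                    case.labels_supine.origin
                    + np.argwhere(case.labels_supine.breast_mask())
                    * case.labels_supine.spacing)
                report = _evaluate.TREReport(
                    case_id=f"phantom-seed{config.seed}", C_MR=c_mr,
                    C_PET=c_pet, tre=t,
                    features={"lesion_size_mm": 2 * config.lesion_radius,
                              "nipple_displacement_mm": res.Vmax,
                              "lesion_location_ratio": ratio,
                              "density": dens, "volume_ml": vol})
                (out / "tre_report.json").write_text(
                    json.dumps(report.to_dict(), indent=2))
                record(stage, tre_mm=t)
            else:
                raise ValueError(f"unknown stage {stage!r}")
            manifest["stages"][stage]["wall_time_s"] = time.perf_counter() - t0
    except Exception as exc:
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
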