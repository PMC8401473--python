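"""Model/Results interface to the full registration method.

:class:`BreastRegistrationModel` bundles the inputs of one case (supine
label map and landmarks, prone landmarks, optionally the PET-like and
MR-like volumes); :meth:`~BreastRegistrationModel.fit` runs the method —
rigid chest-wall pre-registration, the patient-specific stiffness grid
search driven by the nipple displacement, the finite-element warp and the
landmark refinement — and returns a :class:`RegistrationResults` carrying
the estimated moduli, the optimization trace, diagnostics and a
``summary()`` table, with helpers to warp volumes and score the target
registration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import fem as _fem
from . import inverse as _inverse
from . import meshing as _meshing
from . import register as _register
from . import evaluate as _evaluate
from .materials import MaterialParams, default_materials, DEFAULT_STIFFNESS_RATIO
from .volume import Volume, LabelMap

__all__ = ["BreastRegistrationModel", "RegistrationResults"]


class BreastRegistrationModel:
    """Patient-specific biomechanical supine-to-prone registration model.

    Parameters
    ----------
    labels_supine : LabelMap
        Tissue labels of the (cropped) supine anatomy.
    nipple_supine, nipple_prone : (3,) mm
    chest_landmarks_supine, chest_landmarks_prone : (3+, 3) mm
        Manually picked chest-wall contour points in both postures.
    pet_supine, mr_prone : Volume, optional
        Needed only for image warping / image-based TRE.
    materials : MaterialParams, optional
        Initial (pre-optimization) tissue table.
    element_size : float, mm — FE mesh resolution.
    skin_thickness : float, mm — membrane skin thickness (0 disables).
    fem_config : FemConfig, optional
    """

    def __init__(self, labels_supine: LabelMap, nipple_supine, nipple_prone,
                 chest_landmarks_supine, chest_landmarks_prone,
                 pet_supine: Volume | None = None, mr_prone: Volume | None = None,
                 materials: MaterialParams | None = None,
                 element_size: float = 4.0, skin_thickness: float = 1.0,
                 fem_config: "_fem.FemConfig | None" = None):
        self.labels_supine = labels_supine
        self.nipple_supine = np.asarray(nipple_supine, float)
        self.nipple_prone = np.asarray(nipple_prone, float)
        self.chest_landmarks_supine = np.asarray(chest_landmarks_supine, float)
        self.chest_landmarks_prone = np.asarray(chest_landmarks_prone, float)
        self.pet_supine = pet_supine
        self.mr_prone = mr_prone
        self.materials = materials or default_materials()
        self.element_size = float(element_size)
        self.skin_thickness = float(skin_thickness)
        cfg = fem_config or _fem.FemConfig()
        if cfg.skin_thickness != skin_thickness:
            cfg = cfg.replace(skin_thickness=float(skin_thickness))
        self.fem_config = cfg
        self._mesh: "_meshing.HexMesh | None" = None

    @classmethod
    def from_case(cls, case, **kwargs) -> "BreastRegistrationModel":
        """Build from a :class:`~breastfem.phantom.PhantomCase` (with prone
        ground truth set)."""
        if case.nipple_prone is None:
            raise ValueError("case has no prone ground truth; run "
                             "make_prone_ground_truth first")
        return cls(labels_supine=case.labels_supine,
                   nipple_supine=case.nipple_supine,
                   nipple_prone=case.nipple_prone,
                   chest_landmarks_supine=case.chest_wall_landmarks,
                   chest_landmarks_prone=case.chest_wall_landmarks_prone,
                   pet_supine=case.pet_supine, mr_prone=case.mr_prone,
                   **kwargs)

    @property
    def mesh(self) -> "_meshing.HexMesh":
        if self._mesh is None:
            self._mesh = _meshing.voxel_to_hex_mesh(
                self.labels_supine, self.element_size,
                nipple_mm=self.nipple_supine)
        return self._mesh

    def simulate(self, materials: MaterialParams | None = None
                 ) -> "_fem.DisplacementField":
        """One forward supine-to-prone simulation at the given materials."""
        return _fem.simulate_supine_to_prone(self.mesh,
                                             materials or self.materials,
                                             self.fem_config)

    def fit(self, lb: float = _inverse.E_LOWER_KPA,
            ub: float = _inverse.E_UPPER_KPA,
            stiffness_ratio: float = DEFAULT_STIFFNESS_RATIO,
            tol: float = 1.0, n_coarse: int = 12, n_refine: int = 5,
            refine_rounds: int = 2) -> "RegistrationResults":
        """Estimate patient-specific moduli and the resulting registration.

        Runs the rigid pre-registration to measure the target nipple
        displacement, the multi-resolution grid search over the adipose
        modulus (fibro-glandular slaved at ``stiffness_ratio``) with the
        ``tol`` = 1 mm stopping rule, one forward simulation at the winning
        moduli, and the similarity refinement from the chest-wall
        landmarks.
        """
        rigid, vmax = _inverse.rigid_preregister(
            self.nipple_supine, self.nipple_prone,
            self.chest_landmarks_supine, self.chest_landmarks_prone)

        disp_cache: dict[float, _fem.DisplacementField] = {}
        last: dict = {"disp": None}

        def simulate(mats: MaterialParams) -> float:
            d = _fem.simulate_supine_to_prone(self.mesh, mats, self.fem_config,
                                              warm=last["disp"])
            disp_cache[mats.adipose.E] = d
            last["disp"] = d
            return d.nipple_displacement()

        mats, state = _inverse.grid_search_optimize(
            self.mesh, vmax, base_materials=self.materials, lb=lb, ub=ub,
            stiffness_ratio=stiffness_ratio, tol=tol, n_coarse=n_coarse,
            n_refine=n_refine, refine_rounds=refine_rounds,
            fem_config=self.fem_config, simulate=simulate)
        disp = disp_cache[mats.adipose.E]

        # landmark refinement: predicted prone chest points -> observed ones
        pred_landmarks = self.chest_landmarks_supine + _interp_at(
            self.mesh, disp.u, self.chest_landmarks_supine)
        refine = _register.affine_from_landmarks(
            pred_landmarks, self.chest_landmarks_prone, kind="similarity")

        return RegistrationResults(model=self, materials=mats,
                                   optimization=state, displacement=disp,
                                   rigid_transform=rigid,
                                   refine_transform=refine)


def _interp_at(mesh, u, pts):
    """Displacement at arbitrary points, inverse-distance over nearest nodes."""
    from scipy.spatial import cKDTree
    d, j = cKDTree(mesh.nodes).query(np.asarray(pts, float), k=4)
    w = 1.0 / np.maximum(d, 1e-6)
    w /= w.sum(axis=1, keepdims=True)
    return np.einsum("pk,pki->pi", w, u[j])


@dataclass
class RegistrationResults:
    """Fitted moduli, optimization trace and registration operators."""

    model: BreastRegistrationModel
    materials: MaterialParams
    optimization: "_inverse.OptimizationState"
    displacement: "_fem.DisplacementField"
    rigid_transform: "_register.AffineTransform"
    refine_transform: "_register.AffineTransform"
    _dense_field: Volume | None = field(default=None, repr=False)

    # -- parameter access --------------------------------------------------
    @property
    def params(self) -> dict:
        return {"E_adipose_kPa": self.materials.adipose.E,
                "E_fibroglandular_kPa": self.materials.fibroglandular.E}

    @property
    def Vmax(self) -> float:
        return self.optimization.Vmax

    @property
    def Vn(self) -> float:
        return self.optimization.Vn

    @property
    def converged(self) -> bool:
        return self.optimization.converged

    # -- registration operators -------------------------------------------
    def dense_field(self, target: Volume | None = None) -> Volume:
        """Dense supine-to-prone displacement field on the target grid."""
        if self._dense_field is None or target is not None:
            tgt = target or self.model.pet_supine or _grid_like(self.model)
            f = _register.field_to_grid(self.model.mesh.nodes,
                                        self.displacement.u, tgt)
            if target is not None:
                return f
            self._dense_field = f
        return self._dense_field

    def warp(self, moving: Volume) -> Volume:
        """FE-warp a supine volume into the predicted prone posture."""
        return _register.warp_volume(moving, self.dense_field(),
                                     direction="forward")

    def predict_point(self, pts_mm) -> np.ndarray:
        """Map supine world points to refined prone positions."""
        pts = np.atleast_2d(np.asarray(pts_mm, float))
        moved = pts + _interp_at(self.model.mesh, self.displacement.u, pts)
        return self.refine_transform.apply(moved)

    def registered_lesion_centroid(self) -> np.ndarray:
        """Lesion centroid of the warped PET hot spot, after refinement."""
        if self.model.pet_supine is None:
            raise ValueError("model built without a PET volume")
        warped = self.warp(self.model.pet_supine)
        c = _evaluate.lesion_centroid(warped)
        return self.refine_transform.apply(c)

    def tre(self, lesion_centroid_mr) -> float:
        """3D TRE of the registered PET lesion against the MR centroid."""
        return _evaluate.tre(lesion_centroid_mr,
                             self.registered_lesion_centroid())

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        o = self.optimization
        lines = [
            "Patient-specific biomechanical registration",
            "=" * 59,
            f"{'mesh elements':<34}{self.model.mesh.n_elements:>25}",
            f"{'element size (mm)':<34}{self.model.element_size:>25.2f}",
            f"{'target nipple displacement Vmax':<34}{o.Vmax:>22.3f} mm",
            f"{'simulated nipple displacement Vn':<34}{o.Vn:>22.3f} mm",
            f"{'|Vmax - Vn| at termination':<34}{o.objective:>22.3f} mm",
            f"{'stopping tolerance':<34}{1.0:>22.3f} mm",
            f"{'grid trials':<34}{len(o.history):>25}",
            f"{'converged':<34}{str(o.converged):>25}",
            "-" * 59,
            "estimated moduli (kPa)          E        nu      rho(kg/m3)",
        ]
        for name in ("adipose", "fibroglandular", "skin"):
            t = self.materials.for_tissue(name)
            lines.append(f"  {name:<22}{t.E:>9.3f}{t.nu:>10.2f}{t.rho:>12.0f}")
        lines.append("-" * 59)
        lines.append(f"{'admissible E range (kPa)':<34}"
                     f"{f'({o.lb}, {o.ub})':>25}")
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """Objective |Vmax - Vn| against the trial adipose modulus."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        h = sorted(self.optimization.history)
        ax.loglog([e for e, _ in h], [o for _, o in h], "o-")
        ax.axhline(1.0, ls="--", color="grey", label="1 mm stop")
        ax.axvline(self.materials.adipose.E, color="C3", ls=":",
                   label="estimate")
        ax.set_xlabel("adipose Young's modulus E (kPa)")
        ax.set_ylabel("|Vmax $-$ Vn| (mm)")
        ax.legend()
        return ax


def _grid_like(model: BreastRegistrationModel) -> Volume:
    lab = model.labels_supine
    return Volume(data=np.zeros(lab.shape), spacing=lab.spacing.copy(),
                  origin=lab.origin.copy(), orientation=lab.orientation)
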