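"""Patient-specific material estimation.

The only observable the optimization consumes is the nipple displacement
between postures: a rigid pre-registration of the chest-wall landmarks
measures the target displacement magnitude Vmax, and a multi-resolution
grid search over the adipose Young's modulus E in [0.5, 500] kPa matches
the simulated nipple displacement Vn to it, stopping when
|Vmax - Vn| <= 1 mm.  The fibro-glandular modulus is slaved to the adipose
one at the fixed composition ratio (default 7.5) — the reported per-cohort
moduli keep an essentially constant ratio, so a single degree of freedom
is searched; searching both independently is available but off by default.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .materials import MaterialParams, default_materials, DEFAULT_STIFFNESS_RATIO
from .meshing import HexMesh
from .register import affine_from_landmarks, AffineTransform
from . import fem as _fem

__all__ = ["rigid_preregister", "grid_search_optimize", "OptimizationState",
           "E_LOWER_KPA", "E_UPPER_KPA"]

log = logging.getLogger(__name__)

#: admissible adipose Young's modulus bounds, kPa
E_LOWER_KPA = 0.5
E_UPPER_KPA = 500.0


def rigid_preregister(nipple_supine, nipple_prone,
                      chest_landmarks_supine, chest_landmarks_prone
                      ) -> tuple[AffineTransform, float]:
    """Rigid chest-wall alignment and the target nipple displacement Vmax.

    Least-squares rigid fit (rotation + translation, no scaling) of the
    supine chest-wall landmarks onto the prone ones; Vmax is the distance
    between the prone nipple and the rigidly mapped supine nipple, i.e. the
    nipple motion that gravity alone must explain.
    """
    T = affine_from_landmarks(np.asarray(chest_landmarks_supine, float),
                              np.asarray(chest_landmarks_prone, float),
                              kind="rigid")
    vmax = float(np.linalg.norm(np.asarray(nipple_prone, float)
                                - T.apply(np.asarray(nipple_supine, float))))
    return T, vmax


@dataclass
class OptimizationState:
    """Grid-search trace.

    ``history`` holds (E_adipose kPa, |Vmax - Vn| mm) per trial in
    evaluation order; ``best_objective_trace`` is the best-so-far objective,
    monotone non-increasing by construction.
    """

    Vmax: float
    Vn: float = np.nan
    E_adipose: float = np.nan
    lb: float = E_LOWER_KPA
    ub: float = E_UPPER_KPA
    history: list = field(default_factory=list)
    failed_trials: list = field(default_factory=list)
    converged: bool = False
    wall_time_s: float = 0.0

    @property
    def objective(self) -> float:
        return abs(self.Vmax - self.Vn)

    @property
    def best_objective_trace(self) -> np.ndarray:
        return np.minimum.accumulate([obj for _, obj in self.history])

    def to_dict(self) -> dict:
        return {"Vmax": self.Vmax, "Vn": self.Vn, "E_adipose": self.E_adipose,
                "bounds_kPa": [self.lb, self.ub], "converged": self.converged,
                "objective_mm": self.objective, "n_trials": len(self.history),
                "history": [[float(E), float(o)] for E, o in self.history],
                "failed_trials": self.failed_trials,
                "wall_time_s": self.wall_time_s}


def grid_search_optimize(mesh_supine: HexMesh, Vmax: float,
                         base_materials: MaterialParams | None = None,
                         lb: float = E_LOWER_KPA, ub: float = E_UPPER_KPA,
                         stiffness_ratio: float = DEFAULT_STIFFNESS_RATIO,
                         tol: float = 1.0,
                         n_coarse: int = 12, n_refine: int = 5,
                         refine_rounds: int = 2,
                         fem_config: "_fem.FemConfig | None" = None,
                         simulate=None,
                         ) -> tuple[MaterialParams, OptimizationState]:
    """Multi-resolution grid search for the adipose Young's modulus.

    A log-spaced coarse pass over [lb, ub] (stiff end first, so each trial
    warm-starts cheaply and the expensive very-soft trials are only reached
    when needed) is followed by ``refine_rounds`` rounds of ``n_refine``
    log-spaced points bracketing the incumbent.  Every trial sets the
    fibro-glandular modulus to ``stiffness_ratio`` times the trial adipose
    modulus, runs the full supine-to-prone simulation and scores
    |Vmax - Vn| from the nipple-node displacement.  The search stops as
    soon as a trial is within ``tol`` (default 1 mm) or when the grid is
    exhausted; trials tying within 0.01 mm resolve to the smaller modulus.

    ``simulate(materials) -> Vn`` may be injected (used by tests); by
    default it wraps :func:`breastfem.fem.simulate_supine_to_prone`.

    Returns the best material set and the search trace.  Raises when no
    trial converges in the FE solver; warns when the sampled objective is
    not quasi-convex in E (non-physical for a gravity-loaded breast).
    """
    if not np.isfinite(Vmax) or Vmax < 0:
        raise ValueError(f"invalid target displacement Vmax={Vmax}")
    base = base_materials or default_materials()
    config = fem_config or _fem.FemConfig()

    if simulate is None:
        last: dict = {"disp": None}

        def simulate(mats: MaterialParams) -> float:
            # continuation: warm-start each trial from the previous one
            disp = _fem.simulate_supine_to_prone(mesh_supine, mats, config,
                                                 warm=last["disp"])
            last["disp"] = disp
            return disp.nipple_displacement()

    state = OptimizationState(Vmax=float(Vmax), lb=lb, ub=ub)
    vn_of: dict[float, float] = {}
    t0 = time.perf_counter()

    def run_trial(E: float) -> float | None:
        mats = base.with_adipose_E(E, stiffness_ratio)
        try:
            vn = simulate(mats)
        except _fem.FemError as exc:
            state.failed_trials.append([float(E), str(exc)])
            log.warning("trial E=%.3g kPa failed: %s", E, exc)
            return None
        obj = abs(state.Vmax - vn)
        state.history.append((float(E), float(obj)))
        vn_of[float(E)] = float(vn)
        log.info("trial E=%.4g kPa: Vn=%.3f mm, |Vmax-Vn|=%.3f mm", E, vn, obj)
        return obj

    def best_so_far() -> tuple[float, float]:
        # deterministic tie-break toward the smallest E within solver noise
        obj = min(o for _, o in state.history)
        E = min(E for E, o in state.history if o <= obj + 0.01)
        return E, dict(state.history)[E]

    # coarse pass over the open interval (the bounds are strict), stiff
    # end first; the simulated displacement grows monotonically as E
    # drops, so once a trial overshoots Vmax the minimum is bracketed and
    # softer (ever more expensive) trials cannot improve
    coarse = np.geomspace(lb, ub, n_coarse + 2)[-2:0:-1]
    done = False
    for E in coarse:
        obj = run_trial(float(E))
        if obj is not None and obj <= tol:
            done = True
            break
        if obj is not None and vn_of[float(E)] > state.Vmax:
            log.info("bracketed: Vn=%.3f exceeds Vmax=%.3f at E=%.3g kPa",
                     vn_of[float(E)], state.Vmax, E)
            break

    # refinement around the incumbent
    grid = coarse
    for _ in range(refine_rounds):
        if done or not state.history:
            break
        E_best, _ = best_so_far()
        sorted_grid = np.sort(grid)
        i = int(np.searchsorted(sorted_grid, E_best))
        lo = sorted_grid[max(i - 1, 0)]
        hi = sorted_grid[min(i + 1, len(sorted_grid) - 1)]
        lo, hi = max(lo, lb), min(hi, ub)
        grid = np.geomspace(lo, hi, n_refine + 2)[1:-1]
        for E in np.sort(grid)[::-1]:
            if any(abs(np.log(E / Eh)) < 1e-12 for Eh, _ in state.history):
                continue
            obj = run_trial(float(E))
            if obj is not None and obj <= tol:
                done = True
                break

    state.wall_time_s = time.perf_counter() - t0
    if not state.history:
        raise _fem.NonConvergenceError(
            "no grid trial converged in the FE solver; failures: "
            f"{state.failed_trials}")
    E_best, obj_best = best_so_far()
    state.E_adipose = E_best
    state.Vn = vn_of[E_best]
    state.converged = obj_best <= tol
    _check_quasiconvex(state)
    mats = base.with_adipose_E(E_best, stiffness_ratio)
    return mats, state


def _check_quasiconvex(state: OptimizationState, slack: float = 0.05) -> None:
    hist = sorted(state.history)
    objs = np.array([o for _, o in hist])
    if len(objs) < 3:
        return
    i_min = int(np.argmin(objs))
    left_ok = np.all(np.diff(objs[:i_min + 1]) <= slack)
    right_ok = np.all(np.diff(objs[i_min:]) >= -slack)
    if not (left_ok and right_ok):
        warnings.warn("objective |Vmax - Vn| is not quasi-convex in E over "
                      "the sampled grid; the displacement-modulus relation "
                      "is expected to be monotone")
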