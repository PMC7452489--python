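"""Surface-mapping registration: objective, optimizer, end-to-end pipeline.

The estimator places the bone's local coordinate system by a 6-DOF pose
``Q = (px, py, pz, thx, thy, thz)`` and scores it with the surface-mapping
error

    S(Q, M, E) = sum_i |d_i - eps_i|,    i over the analysis faces,

where d_i is the signed vertical distance from the posed face to its
nearest-line marker and eps_i the CT-measured soft-tissue thickness.  S is
minimized by a modified steepest-descent scheme with a fixed step h
(0.5 mm or degree by default): each coordinate is tried at q_i, q_i + h and
q_i - h and moved to whichever of the three gives the strictly smallest S;
ties keep the coordinate in place.  In the default *sequential* mode each
accepted move updates Q before the next coordinate is tested, which makes
the per-sweep S trace provably non-increasing; a *simultaneous* mode (all
six coordinates tested against the same Q, moves applied together) is
available for comparison.  Convergence = one full sweep with no move; the
fixed step makes h the accuracy floor of the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import trimesh

from .geometry import (
    Pose6,
    RigidTransform,
    pose_error,
    pose_to_transform,
    rigid_fit,
    transform_to_pose,
)
from .surface_model import (
    MarkerSet,
    SurfaceModel,
    correspond_and_distance,
    prepare_surface_model,
)

__all__ = [
    "OptimizerSettings",
    "RegistrationResult",
    "surface_mapping_error",
    "descent_sweep",
    "optimize_pose",
    "perturb_pose",
    "mocap_to_ct",
    "register",
]


class RegistrationStageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in ``stage``."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class OptimizerSettings:
    """Fixed-step descent settings.

    h: trial step, in mm for positions and degrees for angles (one shared
    value, matching the diagonal step matrix of the method).
    """

    h: float = 0.5
    max_sweeps: int = 10_000
    mode: str = "sequential"

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError("step size h must be positive")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.mode not in ("sequential", "simultaneous"):
            raise ValueError("mode must be 'sequential' or 'simultaneous'")


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a pose optimization / full registration run."""

    pose: Pose6
    final_s: float
    s_trace: tuple[float, ...]
    sweeps: int
    converged: bool
    dof_errors: Pose6 | None = None
    transfer_rms: float | None = None
    n_analysis: int | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "pose": self.pose.as_array().tolist(),
            "final_s": self.final_s,
            "s_trace": list(self.s_trace),
            "sweeps": self.sweeps,
            "converged": self.converged,
            "n_analysis": self.n_analysis,
            "config": self.config,
        }
        if self.dof_errors is not None:
            d["dof_errors"] = self.dof_errors.as_array().tolist()
        if self.transfer_rms is not None:
            d["transfer_rms"] = self.transfer_rms
        return d


def surface_mapping_error(pose: Pose6, model: SurfaceModel,
                          markers: MarkerSet) -> float:
    """S(Q, M, E) = sum over analysis faces of |d_i - eps_i|, in mm."""
    corr = correspond_and_distance(model, pose, markers)
    return float(np.abs(corr.distances - model.analysis_epsilon).sum())


def _try_coordinate(q: np.ndarray, i: int, h: float, s1: float,
                    model: SurfaceModel, markers: MarkerSet) -> tuple[float, float]:
    """Return (step in {-h, 0, +h}, resulting S) for coordinate i.

    Implements the three-way trial rule with strict inequalities: the
    coordinate moves only when one trial value is strictly smaller than both
    alternatives; any tie keeps the coordinate in place.
    """
    qp = q.copy()
    qp[i] += h
    s2 = surface_mapping_error(Pose6.from_array(qp), model, markers)
    qm = q.copy()
    qm[i] -= h
    s3 = surface_mapping_error(Pose6.from_array(qm), model, markers)
    if s2 < s1 and s2 < s3:
        return h, s2
    if s3 < s1 and s3 < s2:
        return -h, s3
    return 0.0, s1


def descent_sweep(pose: Pose6, model: SurfaceModel, markers: MarkerSet,
                  settings: OptimizerSettings = OptimizerSettings(),
                  s_current: float | None = None,
                  ) -> tuple[Pose6, float, np.ndarray]:
    """One full pass over the six coordinates.

    Returns ``(new_pose, new_S, moves)`` with ``moves`` the per-coordinate
    displacement, each exactly 0, +h or -h.  Sequential mode applies each
    accepted move before testing the next coordinate (S can only decrease);
    simultaneous mode evaluates all six trials at the incoming pose and
    applies the accepted moves together.
    """
    q = pose.as_array()
    if s_current is None:
        s_current = surface_mapping_error(pose, model, markers)
    moves = np.zeros(6)
    if settings.mode == "sequential":
        for i in range(6):
            step, s_new = _try_coordinate(q, i, settings.h, s_current, model, markers)
            if step != 0.0:
                q[i] += step
                s_current = s_new
                moves[i] = step
        return Pose6.from_array(q), s_current, moves
    # simultaneous: all trials against the incoming pose
    for i in range(6):
        step, _ = _try_coordinate(q, i, settings.h, s_current, model, markers)
        moves[i] = step
    q = q + moves
    new_pose = Pose6.from_array(q)
    return new_pose, surface_mapping_error(new_pose, model, markers), moves


def optimize_pose(initial: Pose6, model: SurfaceModel, markers: MarkerSet,
                  settings: OptimizerSettings = OptimizerSettings(),
                  ) -> RegistrationResult:
    """Sweep until a full sweep makes no move (converged) or max_sweeps.

    The S trace records the value after each sweep (index 0 = initial S);
    in sequential mode it is monotone non-increasing by construction.
    """
    pose = initial
    s = surface_mapping_error(pose, model, markers)
    trace = [s]
    converged = False
    sweeps = 0
    for sweeps in range(1, settings.max_sweeps + 1):
        pose, s, moves = descent_sweep(pose, model, markers, settings, s_current=s)
        trace.append(s)
        if not np.any(moves):
            converged = True
            break
    return RegistrationResult(
        pose=pose,
        final_s=s,
        s_trace=tuple(trace),
        sweeps=sweeps,
        converged=converged,
        n_analysis=model.n_analysis,
    )


def perturb_pose(true_pose: Pose6, magnitude: float = 10.0,
                 seed: int | np.random.Generator = 0) -> Pose6:
    """Offset every DOF by a uniform draw from [-magnitude, +magnitude].

    Emulates an initial guess with bounded error relative to the true local
    coordinate system (±10 mm or degrees by default).
    """
    if magnitude < 0:
        raise ValueError("perturbation magnitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = rng.uniform(-magnitude, magnitude, size=6)
    return true_pose.perturbed(offsets)


def mocap_to_ct(leg_markers_mocap, leg_markers_ct) -> tuple[RigidTransform, float]:
    """Rigid transfer from the motion-capture frame to the CT frame.

    Fitted by least squares on paired lower-leg landmark markers (medial
    tibial condyle, fibular head, medial/lateral malleoli in the reference
    protocol).  Returns the transform and the residual RMS (mm) as a
    transfer-quality metric.
    """
    return rigid_fit(leg_markers_mocap, leg_markers_ct)


def register(bone_ct: trimesh.Trimesh, skin_ct: trimesh.Trimesh,
             markers: MarkerSet, lcs_ct: RigidTransform,
             config: "RunConfig | None" = None,
             truth: RigidTransform | None = None,
             leg_markers_mocap=None, leg_markers_ct=None,
             seed: int | np.random.Generator = 0,
             model: SurfaceModel | None = None) -> RegistrationResult:
    """End-to-end registration on a bone + skin + marker scene.

    Pipeline: remesh the bone to the target edge length -> per-face
    soft-tissue thickness against the skin -> analysis-area selection ->
    optional mocap->CT marker transfer -> initial pose (the CT-derived LCS,
    perturbed ±magnitude when a ground truth is supplied, simulation style)
    -> fixed-step descent.  When ``truth`` is given the six signed DOF
    errors of the estimate are reported.

    ``model`` short-circuits the preparation stages with an already prepared
    surface model (used when many registrations share one prepared bone).
    """
    from .io import RunConfig  # deferred: io imports surface_model

    cfg = config or RunConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if model is None:
        try:
            model = prepare_surface_model(
                bone_ct, skin_ct, lcs_ct,
                target_edge=cfg.target_edge_mm,
                thickness_range=cfg.thickness_range_mm,
            )
        except Exception as e:  # noqa: BLE001 - stage naming
            raise RegistrationStageError("surface-model preparation", e) from e

    transfer_rms = None
    if markers.frame == "mocap":
        if leg_markers_mocap is None or leg_markers_ct is None:
            raise RegistrationStageError(
                "frame transfer",
                ValueError("mocap markers require leg markers in both frames"),
            )
        try:
            transfer, transfer_rms = mocap_to_ct(leg_markers_mocap, leg_markers_ct)
        except Exception as e:  # noqa: BLE001
            raise RegistrationStageError("frame transfer", e) from e
        markers = markers.transformed(transfer, "ct")

    initial = transform_to_pose(lcs_ct)
    if truth is not None and cfg.perturbation_mm_deg > 0:
        initial = perturb_pose(
            transform_to_pose(truth), cfg.perturbation_mm_deg, rng
        )

    settings = OptimizerSettings(h=cfg.h, max_sweeps=cfg.max_sweeps,
                                 mode=cfg.update_mode)
    try:
        result = optimize_pose(initial, model, markers, settings)
    except Exception as e:  # noqa: BLE001
        raise RegistrationStageError("pose optimization", e) from e

    errors = None
    if truth is not None:
        errors = pose_error(truth, pose_to_transform(result.pose))
    return RegistrationResult(
        pose=result.pose,
        final_s=result.final_s,
        s_trace=result.s_trace,
        sweeps=result.sweeps,
        converged=result.converged,
        dof_errors=errors,
        transfer_rms=transfer_rms,
        n_analysis=model.n_analysis,
        config=cfg.to_dict(),
    )
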