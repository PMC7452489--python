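"""Synthetic bone + skin + marker scenes with known ground-truth pose.

The phantom stands in for a CT scan of the knee: a patella-like bone, the
skin surface in front of it, and reflective markers stuck on the skin.
Because every scene is generated with a known true pose, estimator accuracy
can be measured exactly — something a real CT/mocap session cannot provide
at the desk.

Geometry
--------
* Bone: a superellipsoid with semi-axes 22.5 x 20 x 10 mm (mediolateral x
  proximodistal x anteroposterior, i.e. ~45 x 40 x 20 mm overall), rounded
  latitudinally (exponent 0.8) and boxier azimuthally (0.65) for the
  cornered patellar outline.  Its local coordinate system is the
  principal-axes frame: x mediolateral (largest extent), y proximodistal,
  z anteroposterior, origin at the centroid — so the bone mesh is
  generated directly in its LCS.
* Skin: the bone surface offset outward along its analytic normals by a
  soft-tissue :class:`ThicknessProfile` — thinnest (3 mm) over the
  anterior prominence, 20 mm where the surface turns sideways, capped
  posteriorly: the knee is thin-skinned over the kneecap and fleshy
  around it.  The bone is strictly inside the skin by construction
  (positive offset of a convex surface).
* Markers: ``grid`` lays rings on the skin at ~10-mm arc spacing over the
  anterior patch (emulating a hand-attached 79-marker layout);
  ``virtual`` throws Poisson-disk markers; :func:`exact_markers` builds
  the *noiseless* set — one marker per analysis face exactly at the
  soft-tissue thickness along its normal.
* Lower-leg landmarks: four labelled points rigidly attached to the scene,
  reported both in the CT frame and in a synthetic motion-capture frame, so
  the mocap->CT transfer step can be exercised.

The knee-angle pose model (glide + tilt coefficients in
:func:`pose_scenarios`) is a documented fixture providing distinct,
smoothly varying truths per flexion angle; it is not a claim about real
patellar kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .geometry import Pose6, RigidTransform, pose_to_transform
from .surface_model import (
    MarkerSet,
    generate_virtual_markers,
    points_inside_mesh,
)

__all__ = [
    "PhantomScene",
    "ThicknessProfile",
    "make_phantom",
    "make_scenarios",
    "pose_scenarios",
    "add_noise",
    "exact_markers",
    "anterior_patch",
]

# default shape (mm): semi-axes and superellipsoid exponents.  The
# latitudinal exponent rounds the anterior prominence; the boxier
# azimuthal exponent gives the bone the cornered outline of a patella,
# which is what makes rotation about the anterior axis observable.
BONE_SEMI_AXES = (22.5, 20.0, 10.0)
BONE_EXPONENT = 0.8          # latitudinal
BONE_EXPONENT_AZ = 0.65      # azimuthal
# soft-tissue profile defaults (mm / deg): thinnest over the anterior pole,
# 20 mm where the surface direction has swung theta_ref away from anterior,
# capped beyond.  The profile follows the *position* polar angle with a
# smoothstep so the gradient is spread over the whole anterior area instead
# of concentrating at the rim.
TAU_MIN = 3.0
TAU_MAX = 20.0
THETA_REF_DEG = 90.0
TAU_CAP = 32.0
GRID_SPACING = 10.0
# anterior marker patch extent (polar angle from the anterior axis).
# Markers must extend a little past the analysis-area rim (at theta_ref) so
# rim faces see candidates on both sides of their normal lines; sized so a
# 10-mm grid yields on the order of 79 markers.
PATCH_MAX_ANGLE_DEG = 95.0

# synthetic motion-capture frame: fixed rigid offset from the CT frame
_MOCAP_FROM_CT = RigidTransform(
    np.array(
        [
            [0.93629336, -0.27509585, 0.21835066],
            [0.28962948, 0.95642509, -0.03695701],
            [-0.19866933, 0.09784340, 0.97517033],
        ]
    ),
    np.array([480.0, 210.0, -95.0]),
)

_LEG_LANDMARKS_CT = {
    "med_tibial_condyle": np.array([-35.0, -60.0, -12.0]),
    "fibular_head": np.array([42.0, -65.0, -18.0]),
    "med_malleolus": np.array([-28.0, -390.0, -6.0]),
    "lat_malleolus": np.array([34.0, -395.0, -16.0]),
}


@dataclass(frozen=True)
class PhantomScene:
    """A generated scene: everything a registration run consumes, plus truth."""

    bone: trimesh.Trimesh          # CT frame, posed at the true pose
    skin: trimesh.Trimesh          # CT frame
    markers: MarkerSet             # CT frame
    true_pose: Pose6               # bone LCS -> CT frame
    leg_markers_ct: np.ndarray     # (4, 3)
    leg_markers_mocap: np.ndarray  # (4, 3)
    leg_labels: tuple[str, ...]
    knee_angle_deg: float = 0.0

    @property
    def true_lcs(self) -> RigidTransform:
        return pose_to_transform(self.true_pose)

    @property
    def markers_mocap(self) -> MarkerSet:
        """The skin markers as a motion-capture system would report them."""
        return self.markers.transformed(_MOCAP_FROM_CT, "mocap")


def _superellipsoid_point(direction, semi_axes, exponent, exponent_az=None):
    """Map unit direction vectors onto the superellipsoid surface + normals."""
    d = np.atleast_2d(direction)
    ax, ay, az = semi_axes
    e1 = exponent
    e2 = exponent if exponent_az is None else exponent_az
    v = np.arcsin(np.clip(d[:, 2], -1, 1))          # latitude
    u = np.arctan2(d[:, 1], d[:, 0])                # longitude

    def spow(x, p):
        return np.sign(x) * np.abs(x) ** p

    cv, sv = np.cos(v), np.sin(v)
    cu, su = np.cos(u), np.sin(u)
    pts = np.column_stack(
        [ax * spow(cv, e1) * spow(cu, e2),
         ay * spow(cv, e1) * spow(su, e2),
         az * spow(sv, e1)]
    )
    # analytic outward normal of the implicit superellipsoid
    nrm = np.column_stack(
        [spow(cv, 2 - e1) * spow(cu, 2 - e2) / ax,
         spow(cv, 2 - e1) * spow(su, 2 - e2) / ay,
         spow(sv, 2 - e1) / az]
    )
    nn = np.linalg.norm(nrm, axis=1, keepdims=True)
    nn[nn == 0] = 1.0
    return pts, nrm / nn


@dataclass(frozen=True)
class ThicknessProfile:
    """Soft-tissue thickness tau as a function of surface direction.

    tau rises from ``tau_min`` over the patellar prominence to ``tau_max``
    at angular distance ``theta_ref_deg`` from it through a smoothstep
    (zero gradient at both ends, spread evenly in between) and keeps
    growing at the terminal rate behind that rim until the ``tau_cap``
    clamp — the posterior of the knee is simply fleshy.

    Two anatomical asymmetries break rotational symmetry about the
    anterior axis (without them the rotation DOF would be nearly
    unobservable, which a real patella's surface is not):

    * ``asymmetry``: exponent modulation of the ramp with azimuth
      (ramp^(1 + a*cos az)) — the medial side is fleshier than the
      lateral side at the same angular distance;
    * ``tilt_deg``/``tilt_az_deg``: optionally move the prominence
      (profile center) off the anterior axis, e.g. supero-laterally.
      Off by default: a tilted thickness pattern couples axial rotation
      to in-plane translation, which degrades per-coordinate descent.

    The [tau_min, tau_max] range in front of the rim is preserved.
    """

    tau_min: float = TAU_MIN
    tau_max: float = TAU_MAX
    theta_ref_deg: float = THETA_REF_DEG
    tau_cap: float = TAU_CAP
    asymmetry: float = 0.25
    tilt_deg: float = 0.0
    tilt_az_deg: float = 135.0

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError("soft-tissue thickness must be strictly positive")
        if not (self.tau_min <= self.tau_max <= self.tau_cap):
            raise ValueError(
                "thickness profile must satisfy tau_min <= tau_max <= tau_cap"
            )

    @property
    def center(self) -> np.ndarray:
        """Unit direction of the prominence (thinnest tissue)."""
        t, a = np.deg2rad(self.tilt_deg), np.deg2rad(self.tilt_az_deg)
        return np.array([np.sin(t) * np.cos(a), np.sin(t) * np.sin(a), np.cos(t)])

    def __call__(self, directions) -> np.ndarray:
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        theta = np.degrees(np.arccos(np.clip(d @ self.center, -1.0, 1.0)))
        x = theta / self.theta_ref_deg
        ramp = np.where(x < 1.0, x * x * (3.0 - 2.0 * x), 1.0 + 3.0 * (x - 1.0))
        if self.asymmetry:
            az = np.arctan2(d[:, 1], d[:, 0])
            expo = 1.0 + self.asymmetry * np.cos(az)
            ramp = np.where(ramp < 1.0, np.clip(ramp, 0.0, 1.0) ** expo, ramp)
        return np.minimum(
            self.tau_min + (self.tau_max - self.tau_min) * ramp, self.tau_cap
        )


def _skin_point(direction, semi_axes, exponent, exponent_az,
                profile: ThicknessProfile):
    """Exact skin-surface point for unit direction(s): bone + tau * normal."""
    pts, nrm = _superellipsoid_point(direction, semi_axes, exponent, exponent_az)
    return pts + profile(direction)[:, None] * nrm


def _surface_grid_markers(spacing, max_theta_deg, semi_axes, exponent,
                          exponent_az, profile: ThicknessProfile,
                          transform: RigidTransform) -> MarkerSet:
    """Markers in a grid laid out *on* the skin at ~even arc spacing.

    Emulates markers stuck to the knee at fixed intervals measured along the
    skin: rings separated by ~``spacing`` mm of meridian arc, each filled at
    ~``spacing`` mm of circumferential arc (staggered on alternating rings).
    The grid is centered on the patellar prominence (where an experimenter
    would center it) and arc lengths are measured on the exact analytic skin
    surface.
    """
    # rotate ring directions so the grid is centered on the prominence
    c = profile.center
    axis = np.cross([0.0, 0.0, 1.0], c)
    na = np.linalg.norm(axis)
    if na < 1e-12:
        R_c = np.eye(3)
    else:
        axis = axis / na
        ang = np.arccos(np.clip(c[2], -1.0, 1.0))
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R_c = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)

    def skin(dirs):
        return _skin_point(dirs @ R_c.T, semi_axes, exponent, exponent_az,
                           profile)

    # meridian arc length s(theta), averaged over two azimuths
    theta = np.deg2rad(np.arange(0.0, max_theta_deg + 0.25, 0.25))
    arcs = []
    for az in (0.0, np.pi / 2):
        d = np.column_stack(
            [np.sin(theta) * np.cos(az), np.sin(theta) * np.sin(az), np.cos(theta)]
        )
        p = skin(d)
        arcs.append(np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(p, axis=0), axis=1))]))
    s = np.mean(arcs, axis=0)
    ring_thetas = np.interp(
        np.arange(0.0, s[-1] + 1e-9, spacing), s, theta
    )
    coords = []
    for k, th in enumerate(ring_thetas):
        if th < 1e-6:
            coords.append(skin(np.array([[0.0, 0.0, 1.0]]))[0])
            continue
        az_fine = np.linspace(0.0, 2 * np.pi, 721)
        d = np.column_stack(
            [np.sin(th) * np.cos(az_fine), np.sin(th) * np.sin(az_fine),
             np.full_like(az_fine, np.cos(th))]
        )
        p = skin(d)
        ring_s = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(p, axis=0), axis=1))])
        circumference = ring_s[-1]
        n_k = max(1, int(round(circumference / spacing)))
        offset = (circumference / n_k) * (0.5 if k % 2 else 0.0)
        targets = offset + np.arange(n_k) * circumference / n_k
        az_k = np.interp(targets, ring_s, az_fine)
        dk = np.column_stack(
            [np.sin(th) * np.cos(az_k), np.sin(th) * np.sin(az_k),
             np.full_like(az_k, np.cos(th))]
        )
        coords.extend(skin(dk))
    coords = transform.apply(np.array(coords))
    labels = tuple(f"G{i:03d}" for i in range(len(coords)))
    return MarkerSet(coords, labels, frame="ct")


def _shape_mesh(subdivisions, semi_axes, exponent, exponent_az):
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(base.vertices, dtype=float)
    pts, nrm = _superellipsoid_point(dirs, semi_axes, exponent, exponent_az)
    return pts, nrm, np.asarray(base.faces, dtype=int), dirs


def make_phantom(true_pose: Pose6 | None = None, *,
                 semi_axes=BONE_SEMI_AXES, exponent: float = BONE_EXPONENT,
                 exponent_az: float = BONE_EXPONENT_AZ,
                 profile: ThicknessProfile | None = None,
                 tau_min: float | None = None, tau_max: float | None = None,
                 marker_style: str = "grid", marker_spacing: float = GRID_SPACING,
                 marker_min_distance: float = 10.0,
                 seed: int | np.random.Generator = 0,
                 bone_subdivisions: int = 3, skin_subdivisions: int = 4,
                 knee_angle_deg: float = 0.0) -> PhantomScene:
    """Generate a bone + skin + marker scene with a known true pose.

    ``profile`` is the soft-tissue thickness model (default
    :class:`ThicknessProfile`); ``tau_min``/``tau_max`` are shortcuts that
    override just the thickness range.  ``marker_style``: ``grid`` lays
    markers at ``marker_spacing`` on the anterior patch; ``virtual`` throws
    Poisson-disk markers on the patch at ``marker_min_distance``; ``none``
    leaves marker placement to the caller.  Reproducible for a fixed seed.
    Raises if the thickness profile would let the bone pierce the skin.
    """
    if profile is None:
        profile = ThicknessProfile()
    overrides = {}
    if tau_min is not None:
        overrides["tau_min"] = float(tau_min)
    if tau_max is not None:
        overrides["tau_max"] = float(tau_max)
        overrides["tau_cap"] = max(profile.tau_cap, float(tau_max))
    if overrides:
        profile = replace(profile, **overrides)
    if true_pose is None:
        true_pose = Pose6(0, 0, 0, 0, 0, 0)
    t = pose_to_transform(true_pose)

    bone_pts, _, bone_faces, _ = _shape_mesh(
        bone_subdivisions, semi_axes, exponent, exponent_az
    )
    bone = trimesh.Trimesh(t.apply(bone_pts), bone_faces, process=False)

    skin_pts, skin_nrm, skin_faces, skin_dirs = _shape_mesh(
        skin_subdivisions, semi_axes, exponent, exponent_az
    )
    skin_lcs = skin_pts + profile(skin_dirs)[:, None] * skin_nrm
    skin = trimesh.Trimesh(t.apply(skin_lcs), skin_faces, process=False)

    anterior_axis = t.rotation @ np.array([0.0, 0.0, 1.0])
    patch = anterior_patch(skin, anterior_axis)
    if marker_style == "grid":
        markers = _surface_grid_markers(
            marker_spacing, PATCH_MAX_ANGLE_DEG, semi_axes, exponent,
            exponent_az, profile, t,
        )
    elif marker_style == "virtual":
        markers = generate_virtual_markers(patch, marker_min_distance, seed)
    elif marker_style == "none":
        markers = _fallback_marker(patch)  # caller supplies real markers
    else:
        raise ValueError(f"unknown marker_style {marker_style!r}")

    labels = tuple(_LEG_LANDMARKS_CT)
    leg_ct = np.array([_LEG_LANDMARKS_CT[k] for k in labels])
    leg_mocap = _MOCAP_FROM_CT.invert().apply(leg_ct)
    scene = PhantomScene(
        bone=bone,
        skin=skin,
        markers=markers,
        true_pose=true_pose,
        leg_markers_ct=leg_ct,
        leg_markers_mocap=leg_mocap,
        leg_labels=labels,
        knee_angle_deg=knee_angle_deg,
    )
    _check_bone_inside_skin(scene)
    return scene


def _fallback_marker(patch: trimesh.Trimesh) -> MarkerSet:
    return MarkerSet(patch.vertices[:1], ("P000",), "ct")


def exact_markers(model, true_pose: Pose6, min_distance: float = 10.0,
                  seed: int | np.random.Generator = 0,
                  label_prefix: str = "E") -> MarkerSet:
    """Markers lying exactly at the soft-tissue thickness along face normals.

    A random subset of the prepared model's analysis faces is chosen (greedy
    dart-throwing so markers stay >= ``min_distance`` apart) and each marker
    is placed at centroid + eps * outward normal of its face, posed by the
    true pose.  This is the *noiseless* marker construction: at the true
    pose every chosen face measures d_i = eps_i exactly, so marker error is
    zero by construction and estimator accuracy can be studied in
    isolation.  Skin-sampled markers (grid/virtual styles) additionally
    carry skin-sampling mismatch, as real markers do.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centroids, normals = model.posed_analysis_geometry(true_pose)
    pts = centroids + model.analysis_epsilon[:, None] * normals
    if min_distance <= 0:
        chosen = list(range(len(pts)))  # one marker per analysis face
    else:
        order = rng.permutation(len(pts))
        chosen = []
        d2 = min_distance * min_distance
        for i in order:
            if all(np.sum((pts[i] - pts[j]) ** 2) >= d2 for j in chosen):
                chosen.append(i)
    coords = pts[chosen]
    labels = tuple(f"{label_prefix}{i:03d}" for i in range(len(chosen)))
    return MarkerSet(coords, labels, frame="ct")


def anterior_patch(skin: trimesh.Trimesh, anterior_axis,
                   max_angle_deg: float = PATCH_MAX_ANGLE_DEG) -> trimesh.Trimesh:
    """Submesh of skin faces whose outward normal is near the anterior axis.

    This is the region of the knee a camera system can see markers on (and
    an experimenter can reach); marker generation is restricted to it.
    """
    from .geometry import face_geometry

    w = np.asarray(anterior_axis, float)
    w = w / np.linalg.norm(w)
    normals, _ = face_geometry(skin.vertices, skin.faces)
    keep = normals @ w >= np.cos(np.deg2rad(max_angle_deg))
    if not keep.any():
        raise ValueError("no skin face oriented toward the anterior axis")
    faces = np.asarray(skin.faces)[keep]
    used = np.unique(faces)
    remap = np.full(len(skin.vertices), -1, dtype=int)
    remap[used] = np.arange(used.size)
    return trimesh.Trimesh(np.asarray(skin.vertices)[used], remap[faces],
                           process=False)


def _check_bone_inside_skin(scene: PhantomScene, n_samples: int = 200) -> None:
    """Signed-distance spot check: sampled bone vertices must lie inside skin."""
    v = np.asarray(scene.bone.vertices)
    idx = np.linspace(0, len(v) - 1, min(n_samples, len(v))).astype(int)
    inside = points_inside_mesh(v[idx], scene.skin)
    if not inside.all():
        raise ValueError("thickness profile lets the bone pierce the skin")


# knee-angle pose model: per degree of knee flexion the patella glides
# distally/posteriorly and flexes/tilts.  Fixture constants, mm or deg per
# degree of knee flexion.
_POSE_RATES = np.array([0.03, -0.25, -0.10, 0.60, 0.05, 0.04])


def pose_scenarios(knee_angles_deg=(0.0, 30.0, 60.0, 90.0)
                   ) -> list[tuple[float, Pose6]]:
    """True patella pose per knee-flexion angle.

    A linear glide + tilt model: pose(beta) = rates * beta with the rates
    above (distal/posterior glide dominating, flexion at 0.6 deg per degree
    of knee flexion).  Each angle gets a distinct, known truth.
    """
    out = []
    for beta in knee_angles_deg:
        if not np.isfinite(beta):
            raise ValueError("knee angle must be finite")
        out.append((float(beta), Pose6.from_array(_POSE_RATES * float(beta))))
    return out


def make_scenarios(knee_angles_deg=(0.0, 30.0, 60.0, 90.0), *,
                   marker_style: str = "none",
                   seed: int | np.random.Generator = 0,
                   **phantom_kwargs) -> dict[float, PhantomScene]:
    """One phantom scene per knee angle, each at its scenario true pose."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scenes = {}
    for beta, pose in pose_scenarios(knee_angles_deg):
        scenes[beta] = make_phantom(
            pose, marker_style=marker_style, seed=rng,
            knee_angle_deg=beta, **phantom_kwargs,
        )
    return scenes


def add_noise(scene: PhantomScene, marker_jitter_sd: float = 0.0,
              thickness_bias: float = 0.0,
              seed: int | np.random.Generator = 0) -> PhantomScene:
    """Corrupt a scene: Gaussian marker jitter and/or a skin-offset bias.

    ``marker_jitter_sd`` displaces each marker by an isotropic Gaussian
    (mm), emulating skin movement and digitization error.
    ``thickness_bias`` shifts the whole skin surface outward along its
    vertex normals (mm), biasing every measured soft-tissue thickness
    additively while the markers stay put.  Seed-reproducible; zero noise
    returns an identical scene.
    """
    if marker_jitter_sd < 0 or thickness_bias < 0:
        raise ValueError("noise magnitudes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    markers = scene.markers
    if marker_jitter_sd > 0:
        jitter = rng.normal(0.0, marker_jitter_sd, size=markers.coords.shape)
        markers = MarkerSet(markers.coords + jitter, markers.labels, markers.frame)
    skin = scene.skin
    if thickness_bias > 0:
        vn = np.asarray(skin.vertex_normals)
        skin = trimesh.Trimesh(np.asarray(skin.vertices) + thickness_bias * vn,
                               np.asarray(skin.faces), process=False)
    return replace(scene, markers=markers, skin=skin)
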