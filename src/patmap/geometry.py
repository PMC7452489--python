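"""Rigid-body math for surface-mapping registration.

Conventions used throughout the package:

* millimetres and degrees everywhere;
* right-handed coordinate frames;
* Cardan (Tait-Bryan) x-y-z sequence: ``R = Rx(thx) @ Ry(thy) @ Rz(thz)``,
  i.e. rotations about the moving frame's x, then y, then z axis, matching
  the symbol order (theta_x, theta_y, theta_z) of the pose vector;
* 0-based vertex/face indexing.

A pose ``Q = (px, py, pz, thx, thy, thz)`` places a bone's local coordinate
system (LCS) in a world frame; :class:`RigidTransform` is the equivalent
matrix form used for frame plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pose6",
    "RigidTransform",
    "pose_to_transform",
    "transform_to_pose",
    "pose_error",
    "rigid_fit",
    "face_geometry",
]

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised for degenerate inputs (collinear point sets, zero-area faces)."""


@dataclass(frozen=True)
class Pose6:
    """Six degrees of freedom of a bone LCS: translation (mm) + Cardan angles (deg).

    Angles are stored wrapped into (-180, 180].
    """

    px: float
    py: float
    pz: float
    thx: float
    thy: float
    thz: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"pose components must be finite, got {vals}")
        for name in ("thx", "thy", "thz"):
            object.__setattr__(self, name, _wrap_angle(getattr(self, name)))

    @classmethod
    def from_array(cls, q) -> "Pose6":
        q = np.asarray(q, dtype=float)
        if q.shape != (6,):
            raise ValueError(f"pose array must have shape (6,), got {q.shape}")
        return cls(*q)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.px, self.py, self.pz, self.thx, self.thy, self.thz], dtype=float
        )

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.px, self.py, self.pz], dtype=float)

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.thx, self.thy, self.thz], dtype=float)

    def perturbed(self, offsets) -> "Pose6":
        return Pose6.from_array(self.as_array() + np.asarray(offsets, dtype=float))


def _wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = float(a) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``x -> R @ x + t`` with R orthonormal, det +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("transform components must be finite")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        """Transform one point (3,) or a stack of points (n, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``x -> self(other(x))``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


# ---------------------------------------------------------------------------
# Cardan x-y-z pose <-> matrix
# ---------------------------------------------------------------------------

def _elemental(axis: int, deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    if axis == 0:
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == 1:
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def pose_to_transform(pose: Pose6) -> RigidTransform:
    """Matrix form of a pose: ``R = Rx(thx) @ Ry(thy) @ Rz(thz)``, t = (px,py,pz)."""
    R = _elemental(0, pose.thx) @ _elemental(1, pose.thy) @ _elemental(2, pose.thz)
    return RigidTransform(R, pose.translation)


def transform_to_pose(t: RigidTransform) -> Pose6:
    """Cardan x-y-z decomposition of a rigid transform.

    For ``R = Rx(a) Ry(b) Rz(c)``::

        R = [[ cb*cc,            -cb*sc,            sb    ],
             [ ca*sc + sa*sb*cc,  ca*cc - sa*sb*sc, -sa*cb],
             [ sa*sc - ca*sb*cc,  sa*cc + ca*sb*sc,  ca*cb]]

    so b = asin(R02), a = atan2(-R12, R22), c = atan2(-R01, R00).  At gimbal
    lock (|b| = 90 deg) only a±c is defined; the convention here fixes c = 0
    and folds the remaining rotation into a (= atan2(R10, R11)).
    """
    R = t.rotation
    sb = np.clip(R[0, 2], -1.0, 1.0)
    b = np.arcsin(sb)
    if abs(sb) < 1.0 - 1e-12:
        a = np.arctan2(-R[1, 2], R[2, 2])
        c = np.arctan2(-R[0, 1], R[0, 0])
    else:  # gimbal lock
        a = np.arctan2(R[1, 0], R[1, 1])
        c = 0.0
    return Pose6(
        t.translation[0],
        t.translation[1],
        t.translation[2],
        np.rad2deg(a),
        np.rad2deg(b),
        np.rad2deg(c),
    )


def pose_error(true_lcs: RigidTransform, est_lcs: RigidTransform) -> Pose6:
    """Signed 6-DOF discrepancy between two frames.

    Translation error is the offset of the estimated origin from the true
    origin, expressed in the *true* frame's axes; angular error is the Cardan
    x-y-z decomposition of the relative rotation ``R_true^T @ R_est``.
    """
    dR = true_lcs.rotation.T @ est_lcs.rotation
    dt = true_lcs.rotation.T @ (est_lcs.translation - true_lcs.translation)
    return transform_to_pose(RigidTransform(dR, dt))


# ---------------------------------------------------------------------------
# Least-squares frame fitting (Kabsch)
# ---------------------------------------------------------------------------

def rigid_fit(source, target) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid transform taking ``source`` onto ``target``.

    Minimizes sum ||T(s_i) - t_i||^2 over rotations+translations (no scaling)
    via SVD of the cross-covariance (Kabsch).  Returns ``(transform, rms)``
    where rms is the root-mean-square residual in mm.

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or a
    collinear source configuration.
    """
    S = np.atleast_2d(np.asarray(source, dtype=float))
    T = np.atleast_2d(np.asarray(target, dtype=float))
    if S.shape != T.shape or S.ndim != 2 or S.shape[1] != 3:
        raise ValueError(f"paired (n, 3) point sets required, got {S.shape}/{T.shape}")
    n = S.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 paired points, got {n}")
    sc, tc = S.mean(axis=0), T.mean(axis=0)
    S0, T0 = S - sc, T - tc
    # collinearity check: second singular value of the centered source
    sv = np.linalg.svd(S0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("source points are (near-)collinear")
    H = S0.T @ T0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = tc - R @ sc
    fit = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((fit.apply(S) - T) ** 2, axis=1))))
    return fit, rms


# ---------------------------------------------------------------------------
# Per-face geometry
# ---------------------------------------------------------------------------

def face_geometry(vertices, faces, *, orient_outward: bool = True):
    """Unit normals and centroids of triangular faces.

    Normals follow the winding order (right-hand rule).  With
    ``orient_outward`` (default) each normal is flipped, if needed, to point
    away from the mesh centroid — adequate for the star-shaped bone surfaces
    this package registers, and checkable on the phantom meshes which are
    generated with consistent winding.

    Raises :class:`DegenerateGeometryError` naming the first zero-area face.
    """
    V = np.asarray(vertices, dtype=float)
    F = np.asarray(faces, dtype=int)
    tri = V[F]  # (n, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    bad = np.flatnonzero(norm < 1e-12)
    if bad.size:
        raise DegenerateGeometryError(f"zero-area face at index {bad[0]}")
    normals = cross / norm[:, None]
    centroids = tri.mean(axis=1)
    if orient_outward:
        center = V.mean(axis=0)
        flip = np.einsum("ij,ij->i", normals, centroids - center) < 0.0
        normals[flip] *= -1.0
    return normals, centroids
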