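"""Bone surface-model preparation and marker geometry.

The registration objective compares, per bone-surface triangle, the signed
"vertical" distance d_i from the triangle to its nearest skin marker against
the soft-tissue thickness eps_i measured once from CT-frame geometry.  This
module prepares everything that objective needs:

* isotropic remeshing of the bone surface to a target edge length;
* per-face soft-tissue thickness (centroid -> skin along the outward normal);
* the analysis-area mask (faces whose thickness falls inside a range);
* virtual (Poisson-disk / dart-throwing) and grid marker generation on skin;
* marker <-> face correspondence and signed vertical distances at a pose.

All distances in mm.  Meshes are :class:`trimesh.Trimesh` objects; the
low-level ray/point queries are implemented here with plain numpy so that
no spatial-index extension is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .geometry import Pose6, RigidTransform, face_geometry, pose_to_transform

__all__ = [
    "MarkerSet",
    "SurfaceModel",
    "Correspondence",
    "remesh_uniform",
    "compute_soft_tissue_thickness",
    "select_analysis_area",
    "generate_virtual_markers",
    "generate_grid_markers",
    "correspond_and_distance",
    "prepare_surface_model",
]

MARKER_FRAMES = ("mocap", "ct", "patella")


class EmptyAnalysisAreaError(ValueError):
    """No bone face has a soft-tissue thickness inside the configured range."""


class NoCoverageError(ValueError):
    """No bone face's outward normal reaches the skin surface."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerSet:
    """Labelled skin-marker coordinates (mm) tagged with their frame.

    ``frame`` is one of ``mocap`` (motion-capture global frame), ``ct``
    (CT global frame) or ``patella`` (bone LCS); the tag travels with the
    coordinates so a motion-capture set is never mistaken for a CT one.
    """

    coords: np.ndarray
    labels: tuple[str, ...]
    frame: str = "ct"

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 1:
            raise ValueError(f"marker coords must be (m, 3) with m >= 1, got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("marker coordinates must be finite")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != c.shape[0]:
            raise ValueError("one label per marker required")
        if self.frame not in MARKER_FRAMES:
            raise ValueError(f"frame must be one of {MARKER_FRAMES}, got {self.frame!r}")
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "labels", labels)

    @property
    def m(self) -> int:
        return self.coords.shape[0]

    def transformed(self, t: RigidTransform, frame: str) -> "MarkerSet":
        return MarkerSet(t.apply(self.coords), self.labels, frame)

    def min_pairwise_distance(self) -> float:
        if self.m < 2:
            return np.inf
        d = np.linalg.norm(self.coords[:, None] - self.coords[None, :], axis=2)
        return float(d[np.triu_indices(self.m, 1)].min())


@dataclass(frozen=True)
class SurfaceModel:
    """Prepared bone model: mesh in the patella LCS + thickness + analysis mask.

    ``epsilon`` holds the per-face soft-tissue thickness in mm with NaN for
    faces whose outward normal never reaches the skin; ``analysis_mask``
    marks the faces (thickness inside the configured range) that enter the
    surface-mapping error.  Face normals/centroids are cached in the LCS.
    """

    bone: trimesh.Trimesh
    epsilon: np.ndarray
    analysis_mask: np.ndarray
    thickness_range: tuple[float, float] | None = None
    _normals: np.ndarray = field(default=None, repr=False)
    _centroids: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        nf = len(self.bone.faces)
        eps = np.asarray(self.epsilon, dtype=float).reshape(nf)
        mask = np.asarray(self.analysis_mask, dtype=bool).reshape(nf)
        if np.any(mask & ~np.isfinite(eps)):
            raise ValueError("analysis mask selects a face with undefined thickness")
        normals, centroids = face_geometry(self.bone.vertices, self.bone.faces)
        object.__setattr__(self, "epsilon", eps)
        object.__setattr__(self, "analysis_mask", mask)
        object.__setattr__(self, "_normals", normals)
        object.__setattr__(self, "_centroids", centroids)

    @property
    def n_analysis(self) -> int:
        return int(self.analysis_mask.sum())

    @property
    def analysis_faces(self) -> np.ndarray:
        return np.flatnonzero(self.analysis_mask)

    @property
    def analysis_epsilon(self) -> np.ndarray:
        return self.epsilon[self.analysis_mask]

    def posed_analysis_geometry(self, pose: Pose6) -> tuple[np.ndarray, np.ndarray]:
        """Centroids and outward normals of the analysis faces placed by ``pose``."""
        t = pose_to_transform(pose)
        c = t.apply(self._centroids[self.analysis_mask])
        n = self._normals[self.analysis_mask] @ t.rotation.T
        return c, n


@dataclass(frozen=True)
class Correspondence:
    """Per analysis-face nearest marker and signed vertical distance (mm)."""

    face_indices: np.ndarray   # indices into the bone face array
    marker_indices: np.ndarray  # per analysis face, index into the marker set
    distances: np.ndarray       # signed d_i, positive outside the bone

    @property
    def n(self) -> int:
        return self.face_indices.size


# ---------------------------------------------------------------------------
# Low-level mesh queries (plain numpy, chunked)
# ---------------------------------------------------------------------------

_CHUNK = 4_000_000  # max ray x triangle pairs per chunk


def ray_mesh_first_hit(origins, directions, mesh: trimesh.Trimesh,
                       min_t: float = 1e-6) -> np.ndarray:
    """Distance along each ray to its first triangle intersection (inf = none).

    Vectorized Möller–Trumbore over all ray x triangle pairs, chunked to
    bound memory.  Only hits with parameter t > ``min_t`` count, so rays
    starting on the mesh skip their own face.
    """
    O = np.atleast_2d(np.asarray(origins, dtype=float))
    D = np.atleast_2d(np.asarray(directions, dtype=float))
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=int)
    if F.size == 0:
        raise ValueError("cannot intersect rays with an empty mesh")
    v0 = V[F[:, 0]]
    e1 = V[F[:, 1]] - v0
    e2 = V[F[:, 2]] - v0
    n_rays, n_tri = O.shape[0], F.shape[0]
    out = np.full(n_rays, np.inf)
    rows = max(1, _CHUNK // max(n_tri, 1))
    for lo in range(0, n_rays, rows):
        hi = min(lo + rows, n_rays)
        o, d = O[lo:hi, None, :], D[lo:hi, None, :]
        h = np.cross(d, e2[None, :, :])
        a = np.einsum("rtk,tk->rt", h, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = 1.0 / a
            s = o - v0[None, :, :]
            u = f * np.einsum("rtk,rtk->rt", s, h)
            q = np.cross(s, e1[None, :, :])
            v = f * np.einsum("rtk,rtk->rt", q, np.broadcast_to(d, q.shape))
            t = f * np.einsum("rtk,tk->rt", q, e2)
            ok = (
                (np.abs(a) > 1e-12)
                & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9)
                & (t > min_t)
            )
        t = np.where(ok, t, np.inf)
        out[lo:hi] = t.min(axis=1)
    return out


def _closest_point_triangles(P, a, b, c):
    """Closest point on each triangle (a,b,c) to each query point, all pairs.

    Standard region-based projection (Ericson).  P: (n,3); a,b,c: (f,3).
    Returns (n, f, 3) closest points.
    """
    ab = b - a
    ac = c - a
    ap = P[:, None, :] - a[None, :, :]
    d1 = np.einsum("fk,nfk->nf", ab, ap)
    d2 = np.einsum("fk,nfk->nf", ac, ap)
    bp = P[:, None, :] - b[None, :, :]
    d3 = np.einsum("fk,nfk->nf", ab, bp)
    d4 = np.einsum("fk,nfk->nf", ac, bp)
    cp = P[:, None, :] - c[None, :, :]
    d5 = np.einsum("fk,nfk->nf", ab, cp)
    d6 = np.einsum("fk,nfk->nf", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    denom_ab = d1 - d3
    denom_ac = d2 - d6

    with np.errstate(divide="ignore", invalid="ignore"):
        v_edge_ab = np.where(denom_ab != 0, d1 / denom_ab, 0.0)
        w_edge_ac = np.where(denom_ac != 0, d2 / denom_ac, 0.0)
        e_bc = d4 - d3
        denom_bc = e_bc + (d5 - d6)
        w_edge_bc = np.where(denom_bc != 0, e_bc / denom_bc, 0.0)
        denom_in = va + vb + vc
        v_in = np.where(denom_in != 0, vb / denom_in, 0.0)
        w_in = np.where(denom_in != 0, vc / denom_in, 0.0)

    # interior by default
    res = a[None] + v_in[..., None] * ab[None] + w_in[..., None] * ac[None]
    # edge BC region
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    res = np.where(m[..., None], b[None] + w_edge_bc[..., None] * (c - b)[None], res)
    # edge AC region
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    res = np.where(m[..., None], a[None] + w_edge_ac[..., None] * ac[None], res)
    # edge AB region
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    res = np.where(m[..., None], a[None] + v_edge_ab[..., None] * ab[None], res)
    # vertex regions
    m = (d6 >= 0) & (d5 <= d6)
    res = np.where(m[..., None], np.broadcast_to(c[None], res.shape), res)
    m = (d3 >= 0) & (d4 <= d3)
    res = np.where(m[..., None], np.broadcast_to(b[None], res.shape), res)
    m = (d1 <= 0) & (d2 <= 0)
    res = np.where(m[..., None], np.broadcast_to(a[None], res.shape), res)
    return res


def closest_point_on_mesh(points, mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """Closest surface point (and distance) on ``mesh`` for each query point.

    Brute force over all triangles, chunked over query points.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=int)
    a, b, c = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    n_pts, n_tri = P.shape[0], F.shape[0]
    best_pt = np.empty_like(P)
    best_d = np.empty(n_pts)
    rows = max(1, _CHUNK // (max(n_tri, 1) * 4))
    for lo in range(0, n_pts, rows):
        hi = min(lo + rows, n_pts)
        cand = _closest_point_triangles(P[lo:hi], a, b, c)
        d2 = np.sum((cand - P[lo:hi, None, :]) ** 2, axis=2)
        idx = np.argmin(d2, axis=1)
        r = np.arange(hi - lo)
        best_pt[lo:hi] = cand[r, idx]
        best_d[lo:hi] = np.sqrt(d2[r, idx])
    return best_pt, best_d


def points_inside_mesh(points, mesh: trimesh.Trimesh) -> np.ndarray:
    """Ray-parity containment test for a watertight mesh."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    direction = np.array([0.2357, 0.5868, 0.7746])  # arbitrary irrational-ish
    direction = direction / np.linalg.norm(direction)
    V = np.asarray(mesh.vertices, dtype=float)
    F = np.asarray(mesh.faces, dtype=int)
    v0 = V[F[:, 0]]
    e1 = V[F[:, 1]] - v0
    e2 = V[F[:, 2]] - v0
    counts = np.zeros(P.shape[0], dtype=int)
    n_tri = F.shape[0]
    rows = max(1, _CHUNK // max(n_tri, 1))
    d = direction[None, None, :]
    for lo in range(0, P.shape[0], rows):
        hi = min(lo + rows, P.shape[0])
        o = P[lo:hi, None, :]
        h = np.cross(d, e2[None])
        a = np.einsum("rtk,tk->rt", h, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = 1.0 / a
            s = o - v0[None]
            u = f * np.einsum("rtk,rtk->rt", s, h)
            q = np.cross(s, e1[None])
            v = f * np.einsum("rtk,rtk->rt", q, np.broadcast_to(d, q.shape))
            t = f * np.einsum("rtk,tk->rt", q, e2)
        ok = (np.abs(a) > 1e-12) & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
        counts[lo:hi] = ok.sum(axis=1)
    return counts % 2 == 1


# ---------------------------------------------------------------------------
# Isotropic remeshing
# ---------------------------------------------------------------------------

def remesh_uniform(mesh: trimesh.Trimesh, target_edge: float,
                   iterations: int = 5) -> trimesh.Trimesh:
    """Remesh toward a uniform target edge length (mm).

    Classic incremental isotropic remeshing: split edges longer than 4/3 of
    the target, collapse edges shorter than 4/5, flip edges toward regular
    vertex valence, then relax vertices tangentially and project them back
    onto the input surface.  Edge lengths can only be met approximately
    (roughly within 50% of the target); the output carries no degenerate
    faces and stays on the input surface.

    The practical target range for patella models is 2-4 mm (finer is
    needlessly expensive, coarser distorts the bone shape); values outside
    it are accepted with a warning.
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot remesh an empty mesh")
    if not (target_edge > 0):
        raise ValueError(f"target edge must be positive, got {target_edge}")
    if not 2.0 <= target_edge <= 4.0:
        warnings.warn(
            f"target edge {target_edge} mm outside the recommended 2-4 mm range",
            stacklevel=2,
        )
    ref = trimesh.Trimesh(
        np.asarray(mesh.vertices, float).copy(),
        np.asarray(mesh.faces, int).copy(),
        process=False,
    )
    V = np.asarray(mesh.vertices, dtype=float).copy()
    F = np.asarray(mesh.faces, dtype=int).copy()
    hi, lo = 4.0 / 3.0 * target_edge, 4.0 / 5.0 * target_edge
    for _ in range(iterations):
        V, F = trimesh.remesh.subdivide_to_size(V, F, max_edge=hi)
        V, F = _collapse_short_edges(V, F, lo, hi)
        F = _flip_edges_for_valence(V, F)
        V = _tangential_relax(V, F, ref)
        V, F = _drop_degenerate(V, F)
    out = trimesh.Trimesh(V, F, process=False)
    if len(out.faces) == 0:
        raise ValueError("remeshing removed all faces; target edge too large")
    return out


def _edge_arrays(F):
    E = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    E = np.sort(E, axis=1)
    Eu, counts = np.unique(E, axis=0, return_counts=True)
    return Eu, counts


def _collapse_short_edges(V, F, lo, hi):
    Eu, counts = _edge_arrays(F)
    boundary = set(Eu[counts != 2].ravel().tolist())
    lengths = np.linalg.norm(V[Eu[:, 0]] - V[Eu[:, 1]], axis=1)
    order = np.argsort(lengths)
    nbr: list[set] = [set() for _ in range(len(V))]
    for a, b in Eu:
        nbr[a].add(int(b))
        nbr[b].add(int(a))
    parent = np.arange(len(V))
    Vn = V.copy()
    touched = np.zeros(len(V), dtype=bool)
    for k in order:
        if lengths[k] >= lo:
            break
        a, b = int(Eu[k, 0]), int(Eu[k, 1])
        if touched[a] or touched[b] or a in boundary or b in boundary:
            continue
        if len(nbr[a] & nbr[b]) != 2:  # link condition: keep manifold
            continue
        mid = 0.5 * (V[a] + V[b])
        ring = (nbr[a] | nbr[b]) - {a, b}
        ring_idx = np.fromiter(ring, dtype=int)
        if np.any(np.linalg.norm(V[ring_idx] - mid, axis=1) > hi):
            continue  # collapse would create an over-long edge
        Vn[a] = mid
        parent[b] = a
        touched[a] = touched[b] = True
    F2 = parent[F]
    keep = (
        (F2[:, 0] != F2[:, 1]) & (F2[:, 1] != F2[:, 2]) & (F2[:, 0] != F2[:, 2])
    )
    F2 = F2[keep]
    used = np.unique(F2)
    remap = np.full(len(Vn), -1, dtype=int)
    remap[used] = np.arange(used.size)
    return Vn[used], remap[F2]


def _flip_edges_for_valence(V, F):
    m = trimesh.Trimesh(V, F, process=False)
    adj = m.face_adjacency
    if len(adj) == 0:
        return F
    shared = m.face_adjacency_edges
    unshared = m.face_adjacency_unshared
    Eu, counts = _edge_arrays(F)
    boundary = set(Eu[counts != 2].ravel().tolist())
    valence = np.bincount(Eu.ravel(), minlength=len(V))
    target = np.where(
        np.isin(np.arange(len(V)), np.fromiter(boundary, int, len(boundary))), 4, 6
    ) if boundary else np.full(len(V), 6)
    edge_set = {tuple(e) for e in Eu.tolist()}
    F2 = F.copy()
    dirty = np.zeros(len(F2), dtype=bool)
    normals, _ = face_geometry(V, F, orient_outward=False)

    def dev(v, val):
        return (val - target[v]) ** 2

    for (f1, f2), (a, b), (c, d) in zip(adj, shared, unshared):
        if dirty[f1] or dirty[f2]:
            continue
        a, b, c, d = int(a), int(b), int(c), int(d)
        if c == d or tuple(sorted((c, d))) in edge_set:
            continue
        before = (
            dev(a, valence[a]) + dev(b, valence[b])
            + dev(c, valence[c]) + dev(d, valence[d])
        )
        after = (
            dev(a, valence[a] - 1) + dev(b, valence[b] - 1)
            + dev(c, valence[c] + 1) + dev(d, valence[d] + 1)
        )
        if after >= before:
            continue
        ref_n = normals[f1] + normals[f2]
        new1, new2 = np.array([a, d, c]), np.array([b, c, d])
        tri1 = np.cross(V[new1[1]] - V[new1[0]], V[new1[2]] - V[new1[0]])
        tri2 = np.cross(V[new2[1]] - V[new2[0]], V[new2[2]] - V[new2[0]])
        n1, n2 = np.linalg.norm(tri1), np.linalg.norm(tri2)
        if n1 < 1e-10 or n2 < 1e-10:
            continue
        if np.dot(tri1, ref_n) < 0:
            new1 = new1[::-1]
            tri1 = -tri1
        if np.dot(tri2, ref_n) < 0:
            new2 = new2[::-1]
            tri2 = -tri2
        # reject folds: both new faces must roughly agree with the old pair
        if (np.dot(tri1 / n1, ref_n) <= 0.1 * np.linalg.norm(ref_n)
                or np.dot(tri2 / n2, ref_n) <= 0.1 * np.linalg.norm(ref_n)):
            continue
        F2[f1], F2[f2] = new1, new2
        dirty[f1] = dirty[f2] = True
        valence[a] -= 1
        valence[b] -= 1
        valence[c] += 1
        valence[d] += 1
        edge_set.discard((min(a, b), max(a, b)))
        edge_set.add((min(c, d), max(c, d)))
    return F2


def _tangential_relax(V, F, ref: trimesh.Trimesh, lam: float = 0.5):
    m = trimesh.Trimesh(V, F, process=False)
    Eu, counts = _edge_arrays(F)
    boundary = np.zeros(len(V), dtype=bool)
    boundary[Eu[counts != 2].ravel()] = True
    # neighbour centroid via sparse-free accumulation
    acc = np.zeros_like(V)
    deg = np.zeros(len(V))
    np.add.at(acc, Eu[:, 0], V[Eu[:, 1]])
    np.add.at(acc, Eu[:, 1], V[Eu[:, 0]])
    np.add.at(deg, Eu[:, 0], 1)
    np.add.at(deg, Eu[:, 1], 1)
    ok = deg > 0
    g = V.copy()
    g[ok] = acc[ok] / deg[ok, None]
    disp = g - V
    vn = np.asarray(m.vertex_normals)
    disp -= np.einsum("ij,ij->i", disp, vn)[:, None] * vn  # tangential part
    disp[boundary] = 0.0
    Vn = V + lam * disp
    proj, _ = closest_point_on_mesh(Vn[~boundary], ref)
    Vn[~boundary] = proj
    return Vn


def _drop_degenerate(V, F, area_tol: float = 1e-10):
    tri = V[F]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    F2 = F[areas > area_tol]
    used = np.unique(F2)
    remap = np.full(len(V), -1, dtype=int)
    remap[used] = np.arange(used.size)
    return V[used], remap[F2]


# ---------------------------------------------------------------------------
# Soft-tissue thickness and analysis area
# ---------------------------------------------------------------------------

def compute_soft_tissue_thickness(bone: trimesh.Trimesh,
                                  skin: trimesh.Trimesh) -> np.ndarray:
    """Per-face soft-tissue thickness eps_i (mm); NaN where undefined.

    For each bone face the thickness is the distance from the face centroid,
    along the outward face normal, to the first intersection with the skin
    surface.  Both meshes must live in the same (CT) frame.  Faces whose
    normal ray never reaches the skin get NaN.
    """
    if len(skin.faces) == 0:
        raise ValueError("skin mesh is empty")
    normals, centroids = face_geometry(bone.vertices, bone.faces)
    t = ray_mesh_first_hit(centroids, normals, skin)
    eps = np.where(np.isfinite(t), t, np.nan)
    if not np.any(np.isfinite(eps)):
        raise NoCoverageError("no bone face normal reaches the skin surface")
    return eps


def select_analysis_area(model: SurfaceModel,
                         threshold: tuple[float, float]) -> SurfaceModel:
    """Restrict the analysis area to faces with thickness in ``[lo, hi]`` mm.

    Idempotent: the mask is recomputed from ``epsilon`` alone.  Raises
    :class:`EmptyAnalysisAreaError` when no face qualifies (e.g. a threshold
    below the thinnest soft tissue leaves the analysis area empty).
    """
    lo, hi = float(threshold[0]), float(threshold[1])
    if not (lo < hi) or lo < 0:
        raise ValueError(f"threshold must satisfy 0 <= lo < hi, got ({lo}, {hi})")
    with np.errstate(invalid="ignore"):
        mask = np.isfinite(model.epsilon) & (model.epsilon >= lo) & (model.epsilon <= hi)
    if not mask.any():
        raise EmptyAnalysisAreaError(
            f"no face has soft-tissue thickness within [{lo}, {hi}] mm"
        )
    return replace(model, analysis_mask=mask, thickness_range=(lo, hi))


def prepare_surface_model(bone_ct: trimesh.Trimesh, skin_ct: trimesh.Trimesh,
                          lcs: RigidTransform, target_edge: float = 3.0,
                          thickness_range: tuple[float, float] = (0.0, 20.0),
                          ) -> SurfaceModel:
    """Full bone-model preparation: remesh, thickness, LCS transfer, area.

    ``lcs`` is the bone's local coordinate system expressed in the CT frame;
    the returned model stores the remeshed bone in LCS coordinates with the
    CT-measured thicknesses attached (thickness is pose-invariant).
    """
    bone = remesh_uniform(bone_ct, target_edge)
    eps = compute_soft_tissue_thickness(bone, skin_ct)
    inv = lcs.invert()
    bone_lcs = trimesh.Trimesh(inv.apply(bone.vertices), bone.faces, process=False)
    model = SurfaceModel(bone_lcs, eps, np.isfinite(eps))
    return select_analysis_area(model, thickness_range)


# ---------------------------------------------------------------------------
# Marker generation
# ---------------------------------------------------------------------------

def _sample_surface(mesh: trimesh.Trimesh, count: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Area-weighted uniform random points on a triangle mesh."""
    tri = np.asarray(mesh.vertices)[np.asarray(mesh.faces)]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    fi = rng.choice(len(areas), size=count, p=areas / areas.sum())
    r1, r2 = rng.random(count), rng.random(count)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    t = tri[fi]
    return t[:, 0] + r1[:, None] * (t[:, 1] - t[:, 0]) + r2[:, None] * (t[:, 2] - t[:, 0])


def generate_virtual_markers(skin: trimesh.Trimesh, min_distance: float,
                             seed: int | np.random.Generator = 0,
                             max_attempts: int = 20_000,
                             label_prefix: str = "V") -> MarkerSet:
    """Dart-throwing (Poisson-disk) virtual markers on a skin surface.

    Random candidate points are drawn area-uniformly on the surface and
    accepted whenever they keep all pairwise distances >= ``min_distance``;
    the process runs to saturation within a fixed attempt budget and is
    reproducible for a fixed seed.
    """
    if len(skin.faces) == 0:
        raise ValueError("skin mesh is empty")
    if not min_distance > 0:
        raise ValueError("min_distance must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = _sample_surface(skin, max_attempts, rng)
    accepted: list[np.ndarray] = [candidates[0]]
    pts = candidates[0][None, :]
    d2min = min_distance * min_distance
    for cand in candidates[1:]:
        if np.min(np.sum((pts - cand) ** 2, axis=1)) >= d2min:
            accepted.append(cand)
            pts = np.vstack([pts, cand])
    coords = np.array(accepted)
    labels = tuple(f"{label_prefix}{i:03d}" for i in range(len(accepted)))
    return MarkerSet(coords, labels, frame="ct")


def generate_grid_markers(patch: trimesh.Trimesh, spacing: float,
                          direction=None, label_prefix: str = "G") -> MarkerSet:
    """Regular-grid markers projected onto a skin patch.

    A square lattice with the given spacing (mm) is laid out in the plane
    orthogonal to ``direction`` (default: the patch's area-weighted mean
    normal, i.e. its anterior axis) and each lattice point is projected onto
    the patch along that direction; lattice points that miss the patch are
    dropped.  Emulates a grid of reflective markers stuck on the anterior
    knee at fixed intervals.
    """
    if len(patch.faces) == 0:
        raise ValueError("skin patch is empty")
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    normals, _ = face_geometry(patch.vertices, patch.faces, orient_outward=False)
    tri = np.asarray(patch.vertices)[np.asarray(patch.faces)]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    if direction is None:
        w = (normals * areas[:, None]).sum(axis=0)
    else:
        w = np.asarray(direction, dtype=float)
    w = w / np.linalg.norm(w)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, ref)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    Vp = np.asarray(patch.vertices)
    pu, pv, pw = Vp @ u, Vp @ v, Vp @ w
    eps = 1e-9
    us = np.arange(pu.min(), pu.max() + eps, spacing)
    vs = np.arange(pv.min(), pv.max() + eps, spacing)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    far = pw.max() + 10.0 * spacing
    origins = (
        uu.ravel()[:, None] * u + vv.ravel()[:, None] * v + far * w
    )
    dirs = np.broadcast_to(-w, origins.shape)
    t = ray_mesh_first_hit(origins, dirs, patch, min_t=1e-9)
    hit = np.isfinite(t)
    coords = origins[hit] - t[hit, None] * w
    if coords.shape[0] == 0:
        raise ValueError("no lattice point projects onto the patch")
    labels = tuple(f"{label_prefix}{i:03d}" for i in range(coords.shape[0]))
    return MarkerSet(coords, labels, frame="ct")


# ---------------------------------------------------------------------------
# Correspondence and vertical distances
# ---------------------------------------------------------------------------

def correspond_and_distance(model: SurfaceModel, pose: Pose6,
                            markers: MarkerSet) -> Correspondence:
    """Nearest-line marker and signed vertical distance for each analysis face.

    The bone is placed by ``pose`` (markers and posed bone share a frame).
    For every analysis face, the marker with the smallest perpendicular
    distance to the line through the face centroid along the outward normal
    is selected; the vertical distance d_i is the signed projection of
    (marker - centroid) on that normal, positive outside the bone.
    Correspondence is recomputed at every pose, as the normal lines move
    with the bone.
    """
    if model.n_analysis < 1:
        raise EmptyAnalysisAreaError("surface model has an empty analysis area")
    centroids, normals = model.posed_analysis_geometry(pose)
    diff = markers.coords[None, :, :] - centroids[:, None, :]  # (N, m, 3)
    t = np.einsum("nmk,nk->nm", diff, normals)                  # axial projection
    perp2 = np.einsum("nmk,nmk->nm", diff, diff) - t * t
    idx = np.argmin(perp2, axis=1)
    rows = np.arange(centroids.shape[0])
    return Correspondence(
        face_indices=model.analysis_faces,
        marker_indices=idx,
        distances=t[rows, idx],
    )
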