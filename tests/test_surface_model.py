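"""Bone-model preparation: remeshing, thickness, analysis area, markers."""

import numpy as np
import pytest
import trimesh

import patmap
from patmap.surface_model import (
    EmptyAnalysisAreaError,
    closest_point_on_mesh,
)


def _concentric_spheres(r_bone=15.0, r_skin=25.0):
    bone = trimesh.creation.icosphere(subdivisions=3, radius=r_bone)
    skin = trimesh.creation.icosphere(subdivisions=3, radius=r_skin)
    return bone, skin


def _ray_hit_oracle(origin, direction, mesh):
    """Per-ray brute force: loop every skin triangle with scalar math."""
    best = np.inf
    V, F = np.asarray(mesh.vertices), np.asarray(mesh.faces)
    for f in F:
        a, b, c = V[f]
        e1, e2 = b - a, c - a
        h = np.cross(direction, e2)
        det = e1 @ h
        if abs(det) < 1e-12:
            continue
        s = origin - a
        u = (s @ h) / det
        q = np.cross(s, e1)
        v = (direction @ q) / det
        t = (e2 @ q) / det
        if u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9 and t > 1e-6:
            best = min(best, t)
    return best


class TestRemeshUniform:
    @pytest.mark.parametrize("target", [2.0, 3.0, 4.0])
    def test_mean_edge_within_half_of_target(self, default_scene, target):
        out = patmap.remesh_uniform(default_scene.bone, target)
        mean_edge = out.edges_unique_length.mean()
        assert 0.5 * target <= mean_edge <= 1.5 * target

    def test_fixed_point_when_already_uniform(self, default_scene):
        once = patmap.remesh_uniform(default_scene.bone, 3.0)
        twice = patmap.remesh_uniform(once, 3.0, iterations=2)
        m1 = once.edges_unique_length.mean()
        m2 = twice.edges_unique_length.mean()
        assert abs(m2 - m1) / m1 < 0.1

    def test_sphere_face_count_near_analytic_estimate(self):
        r, edge = 20.0, 2.0
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=r)
        out = patmap.remesh_uniform(sphere, edge)
        expected = 4 * np.pi * r**2 / (np.sqrt(3) / 4 * edge**2)
        assert expected / 2 <= len(out.faces) <= expected * 2

    def test_surface_deviation_bounded(self, default_scene):
        target = 3.0
        out = patmap.remesh_uniform(default_scene.bone, target)
        _, d = closest_point_on_mesh(out.vertices, default_scene.bone)
        assert d.max() < target

    def test_no_degenerate_faces(self, default_scene):
        out = patmap.remesh_uniform(default_scene.bone, 3.0)
        assert out.area_faces.min() > 1e-8

    def test_empty_mesh_rejected(self):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                                process=False)
        with pytest.raises(ValueError):
            patmap.remesh_uniform(empty, 3.0)

    def test_out_of_range_target_warns(self, default_scene):
        with pytest.warns(UserWarning):
            patmap.remesh_uniform(default_scene.bone, 6.0, iterations=1)


class TestSoftTissueThickness:
    def test_concentric_spheres_constant_thickness(self):
        bone, skin = _concentric_spheres()
        eps = patmap.compute_soft_tissue_thickness(bone, skin)
        # centroids sit slightly inside the sphere; the discretization of
        # both spheres bounds the deviation well below a millimetre
        assert np.isfinite(eps).all()
        assert np.allclose(eps, 10.0, atol=0.5)

    def test_matches_per_ray_oracle(self, default_scene):
        bone = patmap.remesh_uniform(default_scene.bone, 4.0)
        eps = patmap.compute_soft_tissue_thickness(bone, default_scene.skin)
        normals, centroids = patmap.face_geometry(bone.vertices, bone.faces)
        idx = np.linspace(0, len(eps) - 1, 25).astype(int)
        for i in idx:
            oracle = _ray_hit_oracle(centroids[i], normals[i], default_scene.skin)
            if np.isnan(eps[i]):
                assert np.isinf(oracle)
            else:
                assert np.isclose(eps[i], oracle, atol=1e-9)

    def test_inward_looking_faces_undefined(self):
        # a bone next to (not inside) a small skin patch: faces looking away
        # from the patch never hit it
        bone = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        quad = trimesh.Trimesh(
            [[-20, -20, 10], [20, -20, 10], [20, 20, 10], [-20, 20, 10]],
            [[0, 1, 2], [0, 2, 3]], process=False,
        )
        eps = patmap.compute_soft_tissue_thickness(bone, quad)
        assert np.isnan(eps).any() and np.isfinite(eps).any()

    def test_empty_skin_rejected(self, default_scene):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                                process=False)
        with pytest.raises(ValueError):
            patmap.compute_soft_tissue_thickness(default_scene.bone, empty)


class TestAnalysisArea:
    def test_threshold_is_exact_filter_and_idempotent(self, prepared_model):
        model = patmap.select_analysis_area(prepared_model, (0.0, 12.5))
        eps = model.epsilon
        with np.errstate(invalid="ignore"):
            expected = np.isfinite(eps) & (eps >= 0) & (eps <= 12.5)
        assert np.array_equal(model.analysis_mask, expected)
        again = patmap.select_analysis_area(model, (0.0, 12.5))
        assert np.array_equal(again.analysis_mask, model.analysis_mask)

    def test_unbounded_threshold_keeps_all_defined(self, prepared_model):
        model = patmap.select_analysis_area(prepared_model, (0.0, np.inf))
        assert model.n_analysis == int(np.isfinite(model.epsilon).sum())

    def test_two_shell_phantom_selects_near_shell(self):
        bone, _ = _concentric_spheres()
        # skin at 4 mm over the +z hemisphere, 15 mm over the -z hemisphere
        vn = bone.vertex_normals
        off = np.where(bone.vertices[:, 2] >= 0, 4.0, 15.0)
        skin = trimesh.Trimesh(bone.vertices + off[:, None] * vn, bone.faces,
                               process=False)
        eps = patmap.compute_soft_tissue_thickness(bone, skin)
        model = patmap.SurfaceModel(bone, eps, np.isfinite(eps))
        near = patmap.select_analysis_area(model, (0.0, 5.0))
        _, centroids = patmap.face_geometry(bone.vertices, bone.faces)
        picked_z = centroids[near.analysis_mask][:, 2]
        # all faces clearly in the far hemisphere must be excluded
        assert (picked_z > -2.0).all()
        assert near.n_analysis > 0.3 * model.n_analysis

    def test_empty_selection_raises(self, prepared_model):
        with pytest.raises(EmptyAnalysisAreaError):
            patmap.select_analysis_area(prepared_model, (0.0, 1.0))

    def test_bad_threshold_rejected(self, prepared_model):
        with pytest.raises(ValueError):
            patmap.select_analysis_area(prepared_model, (5.0, 5.0))


class TestVirtualMarkers:
    def test_pairwise_distances_respect_minimum(self, default_scene):
        mk = patmap.generate_virtual_markers(default_scene.skin, 10.0, seed=3)
        # brute-force O(m^2) oracle
        d = np.linalg.norm(mk.coords[:, None] - mk.coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0

    def test_reproducible_for_fixed_seed(self, default_scene):
        a = patmap.generate_virtual_markers(default_scene.skin, 15.0, seed=7)
        b = patmap.generate_virtual_markers(default_scene.skin, 15.0, seed=7)
        assert np.array_equal(a.coords, b.coords)

    def test_huge_min_distance_gives_single_marker(self, default_scene):
        mk = patmap.generate_virtual_markers(default_scene.skin, 1000.0, seed=0)
        assert mk.m == 1

    def test_markers_lie_on_the_surface(self, default_scene):
        mk = patmap.generate_virtual_markers(default_scene.skin, 15.0, seed=1)
        _, d = closest_point_on_mesh(mk.coords, default_scene.skin)
        assert d.max() < 1e-6

    def test_denser_spacing_never_fewer_markers(self, default_scene):
        counts = {}
        for md in (10.0, 15.0, 20.0):
            counts[md] = patmap.generate_virtual_markers(
                default_scene.skin, md, seed=11
            ).m
        assert counts[10.0] >= counts[15.0] >= counts[20.0]


class TestGridMarkers:
    def test_flat_square_exact_lattice(self):
        quad = trimesh.Trimesh(
            [[0, 0, 0], [30, 0, 0], [30, 30, 0], [0, 30, 0]],
            [[0, 1, 2], [0, 2, 3]], process=False,
        )
        mk = patmap.generate_grid_markers(quad, 10.0, direction=[0, 0, 1])
        assert mk.m == 16  # 4 x 4

    def test_nearest_neighbor_spacing_on_curved_patch(self):
        # gently curved spherical cap
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=100.0)
        keep = sphere.vertices[sphere.faces].mean(axis=1)[:, 2] > 95.0
        cap = trimesh.Trimesh(sphere.vertices, sphere.faces[keep],
                              process=False)
        cap.remove_unreferenced_vertices()
        mk = patmap.generate_grid_markers(cap, 10.0, direction=[0, 0, 1])
        d = np.linalg.norm(mk.coords[:, None] - mk.coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert abs(np.median(nn) - 10.0) < 1.0

    def test_empty_patch_rejected(self):
        empty = trimesh.Trimesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                                process=False)
        with pytest.raises(ValueError):
            patmap.generate_grid_markers(empty, 10.0)


class TestCorrespondence:
    def test_marker_on_normal_line_selected_with_signed_distance(
        self, prepared_model
    ):
        model = prepared_model
        pose = patmap.Pose6(0, 0, 0, 0, 0, 0)
        centroids, normals = model.posed_analysis_geometry(pose)
        probe = 10  # an arbitrary analysis face
        for offset, expected in [(5.0, 5.0), (-4.0, -4.0)]:
            coords = np.vstack([
                centroids[probe] + offset * normals[probe],
                centroids[probe] + 60.0 * normals[probe] + [40, 40, 0],
            ])
            mk = patmap.MarkerSet(coords, ("on_line", "far"), "ct")
            corr = patmap.correspond_and_distance(model, pose, mk)
            assert corr.marker_indices[probe] == 0
            assert np.isclose(corr.distances[probe], expected, atol=1e-9)

    def test_matches_all_pairs_oracle(self, prepared_model, rng):
        model = prepared_model
        pose = patmap.Pose6(1.5, -2.0, 0.5, 4.0, -3.0, 2.0)
        mk = patmap.MarkerSet(rng.uniform(-40, 40, (25, 3)),
                              tuple(f"m{i}" for i in range(25)), "ct")
        corr = patmap.correspond_and_distance(model, pose, mk)
        centroids, normals = model.posed_analysis_geometry(pose)
        for row in range(0, corr.n, 17):
            perp = []
            for m in mk.coords:
                diff = m - centroids[row]
                along = diff @ normals[row]
                perp.append(diff @ diff - along**2)
            best = int(np.argmin(perp))
            assert corr.marker_indices[row] == best
            d = (mk.coords[best] - centroids[row]) @ normals[row]
            assert np.isclose(corr.distances[row], d, atol=1e-12)

    def test_epsilon_is_pose_invariant(self, prepared_model):
        # the stored thickness never changes with the pose used for matching
        eps_before = prepared_model.analysis_epsilon.copy()
        mk = patmap.MarkerSet(np.array([[0.0, 0.0, 40.0]]), ("m",), "ct")
        patmap.correspond_and_distance(
            prepared_model, patmap.Pose6(5, 5, 5, 30, 20, 10), mk
        )
        assert np.array_equal(prepared_model.analysis_epsilon, eps_before)


class TestMarkerSet:
    def test_frame_tag_validated(self):
        with pytest.raises(ValueError):
            patmap.MarkerSet(np.zeros((1, 3)), ("a",), "weird")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            patmap.MarkerSet(np.zeros((0, 3)), (), "ct")
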