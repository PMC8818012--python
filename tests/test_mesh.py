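"""Mesh geometry: refinement, areas, normals, geodesics, patch extraction."""

import numpy as np
import pytest
import trimesh

from epifield.mesh import (
    Electrode,
    MeshError,
    TriSurface,
    extract_patch,
    geodesic_distances,
    shortest_path_vertices,
    triangle_quadrisect,
    unique_edges,
    vertex_areas,
    vertex_normals,
)
from epifield.surrogates import grid_sheet


def _single_triangle(pts):
    return TriSurface(np.asarray(pts, float), [[0, 1, 2]])


class TestQuadrisect:
    def test_single_triangle_counts_and_area(self):
        s = _single_triangle([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        r = triangle_quadrisect(s)
        assert r.n_vertices == 6
        assert r.n_triangles == 4
        assert r.total_area == pytest.approx(s.total_area, abs=0)

    def test_vertex_count_is_vertices_plus_edges(self):
        # unit square split into two triangles: V=4, E=5 -> V'=9, T'=8
        s = TriSurface(
            [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)],
            [[0, 1, 2], [0, 2, 3]],
        )
        assert len(unique_edges(s.triangles)) == 5
        r = triangle_quadrisect(s)
        assert r.n_vertices == 9
        assert r.n_triangles == 8

    def test_quadrisect_twice_is_16x_and_conserves_area(self, small_sheet):
        r = triangle_quadrisect(triangle_quadrisect(small_sheet))
        assert r.n_triangles == 16 * small_sheet.n_triangles
        assert r.total_area == pytest.approx(small_sheet.total_area, rel=1e-14)
        assert vertex_areas(r).sum() == pytest.approx(small_sheet.total_area, rel=1e-12)

    def test_nonmanifold_edge_rejected(self):
        s = TriSurface(
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (0, -1, 0)],
            [[0, 1, 2], [0, 1, 3], [0, 1, 4]],
        )
        with pytest.raises(MeshError, match="non-manifold"):
            triangle_quadrisect(s)


class TestVertexAreasAndNormals:
    def test_equilateral_triangle_areas(self):
        s = _single_triangle([(0, 0, 0), (1, 0, 0), (0.5, np.sqrt(3) / 2, 0)])
        assert vertex_areas(s) == pytest.approx(np.full(3, np.sqrt(3) / 12), rel=1e-12)

    def test_right_triangle_areas(self):
        s = _single_triangle([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        assert vertex_areas(s) == pytest.approx(np.full(3, 1 / 6), rel=1e-12)

    def test_areas_sum_to_total(self, small_sheet):
        assert vertex_areas(small_sheet).sum() == pytest.approx(
            small_sheet.total_area, rel=1e-12
        )

    def test_flat_sheet_normals_and_winding_flip(self, small_sheet):
        n = vertex_normals(small_sheet)
        assert np.allclose(n, [0, 0, 1], atol=1e-12)
        flipped = TriSurface(small_sheet.vertices, small_sheet.triangles[:, ::-1])
        assert np.allclose(vertex_normals(flipped), -n, atol=1e-12)

    def test_sphere_normals_near_radial(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        s = TriSurface(np.asarray(ico.vertices), np.asarray(ico.faces))
        n = vertex_normals(s)
        radial = s.vertices / np.linalg.norm(s.vertices, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(np.clip(np.sum(n * radial, axis=1), -1, 1)))
        assert angles.max() < 2.0

    def test_unit_norm(self, small_sheet):
        assert np.linalg.norm(vertex_normals(small_sheet), axis=1) == pytest.approx(
            1.0, abs=1e-9
        )


class TestGeodesics:
    def test_zero_at_source_and_straight_line(self):
        sheet = grid_sheet(10, 4, 0.5)
        a = int(np.argmin(np.linalg.norm(sheet.vertices - [0, 2, 0], axis=1)))
        b = int(np.argmin(np.linalg.norm(sheet.vertices - [10, 2, 0], axis=1)))
        gf = geodesic_distances(sheet, a, method="graph")
        assert gf.distances[a] == 0.0
        assert gf.distances[b] == pytest.approx(10.0, abs=1e-9)

    def test_edge_graph_stretch_bounded(self):
        sheet = grid_sheet(8, 8, 0.4)
        c = int(np.argmin(np.linalg.norm(sheet.vertices - [4, 4, 0], axis=1)))
        gf = geodesic_distances(sheet, c, method="graph")
        eu = np.linalg.norm(sheet.vertices - sheet.vertices[c], axis=1)
        far = eu > 1.0
        ratio = gf.distances[far] / eu[far]
        assert ratio.min() >= 1.0 - 1e-9
        assert ratio.max() <= 1.1

    def test_steiner_backend_tighter_than_graph(self):
        sheet = grid_sheet(8, 8, 0.4)
        c = int(np.argmin(np.linalg.norm(sheet.vertices - [4, 4, 0], axis=1)))
        gf = geodesic_distances(sheet, c, method="steiner")
        eu = np.linalg.norm(sheet.vertices - sheet.vertices[c], axis=1)
        far = eu > 1.0
        ratio = gf.distances[far] / eu[far]
        assert ratio.min() >= 1.0 - 1e-9
        assert ratio.max() <= 1.02

    def test_symmetry(self, small_sheet):
        a, b = 0, small_sheet.n_vertices // 2
        d_ab = geodesic_distances(small_sheet, a).distances[b]
        d_ba = geodesic_distances(small_sheet, b).distances[a]
        assert d_ab == pytest.approx(d_ba, rel=1e-12)

    def test_triangle_inequality_on_sampled_triples(self):
        sheet = grid_sheet(6, 6, 0.6)
        rng = np.random.default_rng(0)
        ids = rng.choice(sheet.n_vertices, size=6, replace=False)
        D = np.vstack(
            [geodesic_distances(sheet, int(i)).distances[ids] for i in ids]
        )
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_cutoff_marks_unreachable(self, small_sheet):
        gf = geodesic_distances(small_sheet, 0, cutoff=3.0)
        assert not gf.reachable_mask.all()
        assert np.all(gf.distances[gf.reachable_mask] <= 3.0 + 1e-9)


class TestExtractPatch:
    def _electrode_at(self, pts):
        pts = np.asarray(pts, float)
        return Electrode(pts, [f"c{i+1}" for i in range(len(pts))])

    def test_fully_within_radius_unchanged(self):
        sheet = grid_sheet(10, 10, 1.0)
        e = self._electrode_at([(5, 5, 1), (8, 5, 1)])
        out = extract_patch(sheet, e, radius=15.0)
        assert out.n_vertices == sheet.n_vertices

    def test_far_corner_removed_matches_brute_force(self):
        sheet = grid_sheet(30, 30, 1.0)
        e = self._electrode_at([(0, 0, 1), (3.5, 0, 1)])
        out = extract_patch(sheet, e, radius=15.0)
        d = np.linalg.norm(
            sheet.vertices[:, None, :] - e.contact_positions[None], axis=2
        ).min(axis=1)
        kept_exact = d <= 15.0
        tri_keep = kept_exact[sheet.triangles].all(axis=1)
        expected = np.unique(sheet.triangles[tri_keep]).size
        assert out.n_vertices == expected

    def test_disjoint_smaller_sheet_dropped(self):
        big = grid_sheet(10, 10, 1.0)
        small = grid_sheet(4, 4, 1.0)
        sv = small.vertices + np.array([0, 0, 5.0])
        merged = TriSurface(
            np.vstack([big.vertices, sv]),
            np.vstack([big.triangles, small.triangles + big.n_vertices]),
        )
        e = self._electrode_at([(5, 5, 2.5), (8.5, 5, 2.5)])
        out = extract_patch(merged, e, radius=15.0)
        assert out.n_vertices == big.n_vertices

    def test_idempotent(self):
        sheet = grid_sheet(30, 30, 1.0)
        e = self._electrode_at([(15, 15, 1), (18.5, 15, 1)])
        once = extract_patch(sheet, e, radius=10.0)
        twice = extract_patch(once, e, radius=10.0)
        assert twice.n_vertices == once.n_vertices
        assert np.array_equal(twice.triangles, once.triangles)

    def test_empty_result_errors(self):
        sheet = grid_sheet(5, 5, 1.0)
        e = self._electrode_at([(100, 100, 0), (103.5, 100, 0)])
        with pytest.raises(MeshError):
            extract_patch(sheet, e, radius=15.0)


class TestShortestPath:
    def test_straight_line_spacing(self):
        sheet = grid_sheet(29, 3, 1.0)
        a = int(np.argmin(np.linalg.norm(sheet.vertices - [0, 2, 0], axis=1)))
        b = int(np.argmin(np.linalg.norm(sheet.vertices - [29, 2, 0], axis=1)))
        ids, cum = shortest_path_vertices(sheet, a, b, n_points=30)
        assert ids[0] == a and ids[-1] == b
        assert cum[-1] == pytest.approx(29.0, abs=1e-9)
        assert np.diff(cum) == pytest.approx(np.full(29, 1.0), abs=1e-9)

    def test_degenerate_start_equals_end(self):
        sheet = grid_sheet(5, 5, 1.0)
        with pytest.warns(UserWarning):
            ids, cum = shortest_path_vertices(sheet, 3, 3, n_points=5)
        assert np.all(ids == 3)
        assert np.all(cum == 0.0)

    def test_cumulative_length_matches_distance_field(self, small_sheet):
        a, b = 0, small_sheet.n_vertices - 1
        ids, cum = shortest_path_vertices(small_sheet, a, b, n_points=10)
        d = geodesic_distances(small_sheet, a, method="graph").distances[b]
        assert cum[-1] == pytest.approx(d, rel=1e-12)
        assert np.all(np.diff(cum) >= 0)


class TestRefinementProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(1, 4), st.integers(1, 4), st.floats(0.5, 2.0))
    def test_quadrisect_combinatorics_on_grids(self, nx, ny, h):
        sheet = grid_sheet(nx * h, ny * h, h)
        edges = unique_edges(sheet.triangles)
        refined = triangle_quadrisect(sheet)
        assert refined.n_vertices == sheet.n_vertices + len(edges)
        assert refined.n_triangles == 4 * sheet.n_triangles
        assert refined.total_area == pytest.approx(sheet.total_area, rel=1e-12)
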