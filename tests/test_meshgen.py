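"""Mesh generation: neighbor detection, common edges, junctions, fan
triangulation, boundary-cell discretization and skew repair."""

import math

import numpy as np
import pytest

import morphosim.meshgen as mg
from morphosim.mechanics import MEMBRANE, NodeSet
from morphosim.meshgen import (MeshParams, TriMesh, boundary_vertex_count,
                               build_mesh, common_edge, find_neighbors,
                               junction_vertices, repair_skewed, strip_mesh)

from conftest import make_honeycomb, single_cell


PARAMS = MeshParams(neighbor_threshold=0.45)


class TestFindNeighbors:
    def test_distant_cells_are_not_neighbors(self):
        n1, _ = single_cell(center=(0, 0), cell_id=0)
        n2, _ = single_cell(center=(10 * PARAMS.neighbor_threshold + 2, 0), cell_id=1)
        nodes = NodeSet(np.vstack([n1.pos, n2.pos]),
                        np.concatenate([n1.kind, n2.kind]),
                        np.concatenate([n1.cell_id, n2.cell_id]),
                        np.concatenate([n1.membrane_order, n2.membrane_order]))
        adj = find_neighbors(nodes, PARAMS)
        assert adj[0] == set() and adj[1] == set()

    def test_touching_cells_are_neighbors(self):
        gap = 0.5 * PARAMS.neighbor_threshold
        n1, _ = single_cell(center=(0, 0), cell_id=0, radius=1.0, n_mem=24)
        n2, _ = single_cell(center=(2.0 + gap, 0), cell_id=1, radius=1.0, n_mem=24)
        nodes = NodeSet(np.vstack([n1.pos, n2.pos]),
                        np.concatenate([n1.kind, n2.kind]),
                        np.concatenate([n1.cell_id, n2.cell_id]),
                        np.concatenate([n1.membrane_order, n2.membrane_order]))
        adj = find_neighbors(nodes, PARAMS)
        assert adj[0] == {1} and adj[1] == {0}

    def test_honeycomb_interior_cell_has_six_neighbors(self, honeycomb):
        nodes, _ = honeycomb
        adj = find_neighbors(nodes, PARAMS)
        # brute-force oracle for the central cell
        mem0 = nodes.pos[nodes.nodes_of(0, MEMBRANE)]
        expected = set()
        for c in nodes.cell_ids():
            if c == 0:
                continue
            memc = nodes.pos[nodes.nodes_of(c, MEMBRANE)]
            dmin = min(np.linalg.norm(a - b) for a in mem0 for b in memc)
            if dmin < PARAMS.neighbor_threshold:
                expected.add(int(c))
        assert adj[0] == expected
        assert len(adj[0]) == 6


class TestCommonEdge:
    def _mirrored_segments(self, gap):
        """Two cells with straight vertical membrane runs facing each other."""
        ys = np.linspace(-1, 1, 8)
        left = np.column_stack([np.full(8, -gap / 2), ys])
        right = np.column_stack([np.full(8, gap / 2), ys[::-1]])
        # close each membrane with a distant arc
        far_l = np.array([[-3, 1.5], [-3, -1.5]])
        far_r = np.array([[3, 1.5], [3, -1.5]])
        pos = np.vstack([left, far_l, right, far_r])
        kind = [MEMBRANE] * len(pos)
        cid = [0] * 10 + [1] * 10
        order = list(range(10)) + list(range(10))
        # one internal node each keeps the NodeSet invariants satisfied
        pos = np.vstack([pos, [[-1.5, 0]], [[1.5, 0]]])
        kind += [0, 0]
        cid += [0, 1]
        order += [-1, -1]
        return NodeSet(pos, kind, cid, order)

    def test_midpoints_on_bisector(self):
        nodes = self._mirrored_segments(gap=0.5 * PARAMS.neighbor_threshold)
        poly = common_edge(0, 1, nodes, PARAMS)
        assert len(poly) >= 2
        assert np.allclose(poly[:, 0], 0.0, atol=1e-12)

    def test_matches_exhaustive_pairing_oracle(self):
        nodes = self._mirrored_segments(gap=0.3)
        poly = common_edge(0, 1, nodes, PARAMS)
        # oracle: all near pairs by brute force, their midpoints' y-extent
        pa = nodes.pos[nodes.nodes_of(0, MEMBRANE)]
        pb = nodes.pos[nodes.nodes_of(1, MEMBRANE)]
        thr = PARAMS.pairing_factor * PARAMS.neighbor_threshold
        mids = [(a + b) / 2 for a in pa for b in pb
                if np.linalg.norm(a - b) < thr]
        mids = np.array(mids)
        assert poly[:, 1].min() == pytest.approx(mids[:, 1].min(), abs=0.3)
        assert poly[:, 1].max() == pytest.approx(mids[:, 1].max(), abs=0.3)

    def test_far_cells_give_empty_edge(self):
        nodes = self._mirrored_segments(gap=10.0)
        poly = common_edge(0, 1, nodes, PARAMS)
        assert len(poly) == 0


class TestJunctions:
    def test_three_symmetric_cells_junction_at_origin(self):
        edges = {}
        for k, pair in enumerate([(0, 1), (1, 2), (0, 2)]):
            ang = 2 * math.pi * k / 3
            d = np.array([math.cos(ang), math.sin(ang)])
            edges[pair] = np.array([0.05 * d, 2.0 * d])
        pts, assign = junction_vertices(edges, PARAMS)
        d0 = np.linalg.norm(pts, axis=1)
        assert d0.min() < 0.06
        near = int(np.argmin(d0))
        inner_ends = [assign[(p, 0)] for p in edges]
        assert all(j == near for j in inner_ends)

    def test_two_cell_tissue_has_two_end_junctions(self):
        edges = {(0, 1): np.array([[0.0, -1.0], [0.0, 0.0], [0.0, 1.0]])}
        pts, assign = junction_vertices(edges, PARAMS)
        assert len(pts) == 2
        assert assign[((0, 1), 0)] != assign[((0, 1), 1)]

    def test_honeycomb_junctions_near_lattice_vertices(self, honeycomb):
        nodes, _ = honeycomb
        adj = find_neighbors(nodes, PARAMS)
        edges = {}
        for a in adj:
            for b in adj[a]:
                if a < b:
                    poly = common_edge(a, b, nodes, PARAMS)
                    if len(poly) >= 2:
                        edges[(a, b)] = poly
        centers = {c: nodes.membrane_centroid(c) for c in adj}
        pts, _ = junction_vertices(edges, PARAMS, adjacency=adj,
                                   cell_centers=centers)
        # interior lattice vertices of the hexagonal packing (circum radius 1)
        lattice = []
        for c in [centers[k] for k in range(7)]:   # central cell + first ring
            for k in range(6):
                a = math.pi / 6 + 0  # corners of hexagons at radius 1 from centers
            for k in range(6):
                lattice.append(c + np.array([math.cos(k * math.pi / 3),
                                             math.sin(k * math.pi / 3)]))
        lattice = np.array(lattice)
        # every junction of the central cell should be near a lattice vertex
        c0 = centers[0]
        near0 = pts[np.linalg.norm(pts - c0, axis=1) < 1.3]
        assert len(near0) >= 6
        for p in near0:
            assert np.linalg.norm(lattice - p, axis=1).min() < 0.25


class TestBoundaryVertexCount:
    @pytest.mark.parametrize("theta,expected", [
        (math.pi / 3, 1),
        (math.pi, 3),
        (2 * math.pi / 3, 2),
        (2 * math.pi, 6),
    ])
    def test_count_follows_arc_angle(self, theta, expected):
        assert boundary_vertex_count(theta) == expected

    def test_small_angle_still_one_vertex(self):
        assert boundary_vertex_count(0.01) == 1

    def test_nonpositive_angle_rejected(self):
        with pytest.raises(ValueError):
            boundary_vertex_count(0.0)


class TestBuildMesh:
    def test_isolated_cell_fan(self):
        nodes, _ = single_cell(n_mem=24, n_internal=6)
        mesh = build_mesh(nodes, PARAMS)
        # full-circle free arc: 6 boundary vertices (one per pi/3), 6 triangles
        assert mesh.n_triangles == 6
        assert np.all(mesh.tri_cell == 0)
        assert mesh.boundary_tri.all()

    def test_honeycomb_interior_cell_six_triangles(self, honeycomb):
        nodes, _ = honeycomb
        mesh = build_mesh(nodes, PARAMS)
        assert np.sum(mesh.tri_cell == 0) == 6
        # contact length of intra-cell fan neighbors equals the measured
        # center-to-vertex edge they share
        assert mesh.euler_characteristic() == 1

    def test_honeycomb_watertight_and_area(self):
        # tight gap: the mesh spans the intercellular space, so the area
        # comparison to the membrane polygons is only meaningful when the
        # membranes nearly tile the tissue
        nodes, _ = make_honeycomb(n_rings=2, gap=0.03)
        mesh = build_mesh(nodes, PARAMS)
        assert mesh.euler_characteristic() == 1   # triangulated disc
        from morphosim.mechanics import cell_polygon_area
        poly = sum(cell_polygon_area(nodes, c) for c in nodes.cell_ids())
        assert mesh.areas().sum() == pytest.approx(poly, rel=0.05)

    def test_contact_lengths_match_direct_measurement(self, honeycomb):
        nodes, _ = honeycomb
        mesh = build_mesh(nodes, PARAMS)
        cent = mesh.centroids()
        for (i, j), A, L in zip(mesh.adjacency[:20], mesh.contact_A[:20],
                                mesh.center_l[:20]):
            shared = set(mesh.triangles[i]) & set(mesh.triangles[j])
            assert len(shared) == 2
            a, b = sorted(shared)
            assert A == pytest.approx(
                np.linalg.norm(mesh.vertices[a] - mesh.vertices[b]))
            assert L == pytest.approx(np.linalg.norm(cent[i] - cent[j]))
            assert A > 0 and L > 0

    def test_translation_equivariance(self, honeycomb):
        nodes, _ = honeycomb
        mesh1 = build_mesh(nodes, PARAMS)
        shifted = nodes.copy()
        shifted.pos = shifted.pos + np.array([13.5, -7.25])
        mesh2 = build_mesh(shifted, PARAMS)
        assert np.array_equal(mesh1.triangles, mesh2.triangles)
        assert np.allclose(mesh2.vertices - mesh1.vertices,
                           [13.5, -7.25], atol=1e-9)


class TestRepairSkewed:
    def _skewed_fan(self, eps):
        """Three fan triangles whose middle outer edge has length eps."""
        verts = np.array([
            [0.0, 0.0],            # 0: cell center
            [-1.0, 1.0],           # 1
            [-eps / 2, 1.0],       # 2 ┐ short edge
            [eps / 2, 1.0],        # 3 ┘
            [1.0, 1.0],            # 4
        ])
        tris = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 4]])
        mesh = TriMesh(verts, tris, np.zeros(3, dtype=np.int64))
        mesh.finalize()
        return mesh

    def test_three_to_two_conversion(self):
        params = MeshParams(l_intersect=0.2)
        mesh = self._skewed_fan(eps=0.02)
        out = repair_skewed(mesh, params)
        assert out.n_triangles == 2

    def test_merged_vertex_at_midpoint(self):
        params = MeshParams(l_intersect=0.2)
        mesh = self._skewed_fan(eps=0.02)
        out = repair_skewed(mesh, params)
        assert any(np.allclose(v, [0.0, 1.0], atol=1e-12) for v in out.vertices)

    def test_clean_mesh_unchanged(self):
        params = MeshParams(l_intersect=0.2)
        mesh = self._skewed_fan(eps=0.9)
        out = repair_skewed(mesh, params)
        assert out.n_triangles == 3

    def test_quality_improves_on_tissue(self, honeycomb):
        nodes, _ = honeycomb
        mesh = build_mesh(nodes, PARAMS, repair=False)
        out = repair_skewed(mesh, PARAMS)
        short = PARAMS.l_intersect
        centers = {int(t[0]) for t in out.triangles}
        for t in out.triangles:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                if a in centers or b in centers:
                    continue
                assert np.linalg.norm(out.vertices[a] - out.vertices[b]) >= short


class TestSplitPass:
    def test_long_edge_bisected_watertight(self):
        # isoceles fan with one very long outer edge
        verts = np.array([[0.0, 0.0], [-2.0, 1.0], [-1.9, 1.0],
                          [1.9, 1.0], [2.0, 1.0]])
        tris = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 4]])
        mesh = TriMesh(verts, tris, np.zeros(3, dtype=np.int64))
        mesh.finalize()
        out = mg.split_long_edges(mesh, MeshParams(), factor=1.5)
        assert out.n_triangles == 4           # the long middle edge split once
        assert out.areas().sum() == pytest.approx(mesh.areas().sum())
        assert any(np.allclose(v, [0.0, 1.0]) for v in out.vertices)

    def test_regular_mesh_untouched(self):
        mesh = strip_mesh(8)
        out = mg.split_long_edges(mesh, MeshParams())
        assert out.n_triangles == 8


class TestStripMesh:
    def test_watertight_chain(self):
        mesh = strip_mesh(20, side=1.0)
        assert len(mesh.adjacency) == 19    # chain of 20 triangles
        assert mesh.boundary_tri.sum() == 2

    def test_equilateral_geometry(self):
        mesh = strip_mesh(10, side=2.0)
        assert np.allclose(np.degrees(mesh.min_angles()), 60.0, atol=1e-9)
        assert np.allclose(mesh.contact_A, 2.0)
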