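"""Dynamic triangular mesh over a packing of subcellular-element cells.

The mesh couples the mechanical and chemical submodels.  Construction:

1. Two cells are *neighbors* when the shortest distance between their
   membrane nodes is below a threshold.
2. Close membrane-node pairs of two neighbors define a *common edge*: the
   ordered polyline of pair midpoints.
3. Common-edge endpoints cluster into *junction vertices* (centroid of the
   endpoints meeting at each junction).
4. Each cell is fan-triangulated from its center (centroid of its membrane
   nodes) to its perimeter vertices; neighboring cells share the
   junction-junction edge exactly, so the mesh is watertight.
5. Membrane arcs not adjacent to any cell (tissue boundary) get evenly
   spaced *boundary vertices*, the count set by the arc's subtended angle
   (one vertex per pi/3 of arc, rounded).
6. Shared edges shorter than ``l_intersect`` are collapsed to their
   midpoint, absorbing the skewed triangles they induce.

Finite-volume quantities stored per adjacent triangle pair: contact edge
length A and center-to-center distance l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mechanics import MEMBRANE, NodeSet

__all__ = [
    "MeshParams",
    "TriMesh",
    "MeshingError",
    "find_neighbors",
    "common_edge",
    "junction_vertices",
    "boundary_vertex_count",
    "free_arcs",
    "fan_triangulate",
    "build_mesh",
    "repair_skewed",
    "strip_mesh",
]


class MeshingError(RuntimeError):
    pass


@dataclass(frozen=True)
class MeshParams:
    """Mesh-construction parameters.

    neighbor_threshold : membrane-membrane distance (µm) below which two
        cells are adjacent; also the pairing distance for common-edge nodes.
        Default is the equilibrium membrane gap of two adhered cells under
        the default mechanics (measured once on a two-cell fixture).
    l_intersect : shared edges shorter than this are collapsed (µm).
    min_angle_deg : triangle quality bound (minimum interior angle).
    """

    neighbor_threshold: float = 0.45
    l_intersect: float = 0.2
    min_angle_deg: float = 15.0
    pairing_factor: float = 1.5   # common-edge node pairing uses factor * threshold
    split_pass: bool = False      # optional midpoint bisection of oversized edges
    max_repair_iter: int = 50
    drop_sliver_angle_deg: float = 5.0   # discard triangles thinner than this

    def __post_init__(self):
        if self.neighbor_threshold <= 0 or self.l_intersect <= 0:
            raise ValueError("mesh thresholds must be positive")


@dataclass
class TriMesh:
    """Triangulation of the tissue.

    vertices : (V, 2) float
    triangles : (T, 3) int vertex triples
    tri_cell : (T,) int owning cell of each triangle
    boundary_tri : (T,) bool, True when the triangle has an edge on the
        tissue boundary
    adjacency : (P, 2) int triangle pairs sharing an edge
    contact_A : (P,) float shared-edge lengths
    center_l : (P,) float triangle-centroid distances
    """

    vertices: np.ndarray
    triangles: np.ndarray
    tri_cell: np.ndarray
    boundary_tri: np.ndarray = field(default=None)
    adjacency: np.ndarray = field(default=None)
    contact_A: np.ndarray = field(default=None)
    center_l: np.ndarray = field(default=None)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def min_angles(self) -> np.ndarray:
        """Minimum interior angle (radians) of each triangle."""
        p = self.vertices[self.triangles]
        out = np.empty(len(p))
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            na = np.linalg.norm(a, axis=1)
            nb = np.linalg.norm(b, axis=1)
            cosang = np.clip((a * b).sum(axis=1) / np.maximum(na * nb, 1e-300), -1, 1)
            ang = np.arccos(cosang)
            out = ang if i == 0 else np.minimum(out, ang)
        return out

    def euler_characteristic(self) -> int:
        """V - E + F counting each undirected edge once (2 for a disc with
        the outer face, 1 without)."""
        edges = set()
        for t in self.triangles:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edges.add((min(a, b), max(a, b)))
        used = np.unique(self.triangles)
        return len(used) - len(edges) + len(self.triangles)

    def finalize(self) -> "TriMesh":
        """Compute adjacency, contact lengths, centroid distances and
        boundary flags from the triangle table."""
        edge_map: dict[tuple[int, int], list[int]] = {}
        for ti, t in enumerate(self.triangles):
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edge_map.setdefault((min(a, b), max(a, b)), []).append(ti)
        pairs, A, L = [], [], []
        boundary = np.zeros(len(self.triangles), dtype=bool)
        cent = self.centroids()
        for (a, b), tris in edge_map.items():
            if len(tris) == 2:
                i, j = tris
                pairs.append((i, j))
                A.append(float(np.linalg.norm(self.vertices[a] - self.vertices[b])))
                L.append(float(np.linalg.norm(cent[i] - cent[j])))
            elif len(tris) == 1:
                boundary[tris[0]] = True
            else:
                raise MeshingError(f"edge {(a, b)} shared by {len(tris)} triangles")
        self.adjacency = (np.array(pairs, dtype=np.int64)
                          if pairs else np.empty((0, 2), dtype=np.int64))
        self.contact_A = np.array(A)
        self.center_l = np.array(L)
        self.boundary_tri = boundary
        if np.any(self.areas() <= 0):
            bad = int(np.argmin(self.areas()))
            raise MeshingError(f"degenerate triangle {bad} (area <= 0)")
        return self


# ---------------------------------------------------------------------------
# neighbor detection and common edges
# ---------------------------------------------------------------------------

def find_neighbors(nodes: NodeSet, params: MeshParams) -> dict[int, set[int]]:
    """Symmetric cell-adjacency map from minimum membrane-node distances."""
    mem = np.nonzero(nodes.kind == MEMBRANE)[0]
    pos = nodes.pos[mem]
    cid = nodes.cell_id[mem]
    adj: dict[int, set[int]] = {int(c): set() for c in nodes.cell_ids()}
    if len(mem) == 0:
        return adj
    tree = cKDTree(pos)
    pairs = tree.query_pairs(params.neighbor_threshold, output_type="ndarray")
    for a, b in pairs:
        ca, cb = int(cid[a]), int(cid[b])
        if ca != cb:
            adj[ca].add(cb)
            adj[cb].add(ca)
    return adj


def common_edge(cell_a: int, cell_b: int, nodes: NodeSet,
                params: MeshParams) -> np.ndarray:
    """Ordered midpoint polyline of the interface between two neighbor cells.

    Membrane nodes of the two cells closer than the neighbor threshold are
    paired (each node of A with its nearest qualifying node of B and vice
    versa); pair midpoints, ordered along the interface direction, form the
    common edge.  Returns an (n, 2) array; empty (0, 2) when fewer than two
    midpoints exist.
    """
    pa = nodes.pos[nodes.nodes_of(cell_a, MEMBRANE)]
    pb = nodes.pos[nodes.nodes_of(cell_b, MEMBRANE)]
    if len(pa) == 0 or len(pb) == 0:
        return np.empty((0, 2))
    tree_b = cKDTree(pb)
    d_ab, j_ab = tree_b.query(pa)
    tree_a = cKDTree(pa)
    d_ba, j_ba = tree_a.query(pb)
    mids = []
    thr = params.pairing_factor * params.neighbor_threshold
    for i in np.nonzero(d_ab < thr)[0]:
        mids.append(0.5 * (pa[i] + pb[j_ab[i]]))
    for j in np.nonzero(d_ba < thr)[0]:
        mids.append(0.5 * (pb[j] + pa[j_ba[j]]))
    if len(mids) < 2:
        return np.empty((0, 2))
    mids = np.unique(np.round(np.array(mids), 12), axis=0)
    if len(mids) < 2:
        return np.empty((0, 2))
    # order along the dominant direction of the midpoint cloud
    centered = mids - mids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    order = np.argsort(centered @ vt[0])
    return mids[order]


def junction_vertices(common_edges: dict[tuple[int, int], np.ndarray],
                      params: MeshParams,
                      adjacency: dict[int, set[int]] | None = None,
                      cell_centers: dict[int, np.ndarray] | None = None):
    """Cluster common-edge endpoints into junction vertices.

    Endpoints within the neighbor threshold of each other are grouped by
    single linkage.  When the cell adjacency and centers are supplied, the
    grouping is additionally topology-driven: for every mutually adjacent
    cell triple, the endpoint of each of the three pair interfaces nearest
    the triple's corner is merged into one junction even when the distance
    criterion alone would keep them apart.  Each group's centroid is one
    junction vertex.

    Returns ``(points, assignment)`` where ``points`` is (J, 2) and
    ``assignment[(pair, end)]`` maps each edge end (end in {0, 1}) to its
    junction index.
    """
    keys: list[tuple[tuple[int, int], int]] = []
    pts: list[np.ndarray] = []
    for pair, poly in common_edges.items():
        if len(poly) < 2:
            continue
        keys.append((pair, 0))
        pts.append(poly[0])
        keys.append((pair, 1))
        pts.append(poly[-1])
    if not pts:
        return np.empty((0, 2)), {}
    pts_arr = np.array(pts)
    key_index = {k: i for i, k in enumerate(keys)}
    parent = list(range(len(pts_arr)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    tree = cKDTree(pts_arr)
    for a, b in tree.query_pairs(params.neighbor_threshold):
        union(a, b)

    if adjacency is not None and cell_centers is not None:
        for a in adjacency:
            for b in adjacency[a]:
                if b <= a:
                    continue
                for c in adjacency[a] & adjacency[b]:
                    if c <= b:
                        continue
                    corner = (cell_centers[a] + cell_centers[b]
                              + cell_centers[c]) / 3.0
                    ends = []
                    for pair in ((a, b), (a, c), (b, c)):
                        pair = (min(pair), max(pair))
                        if pair not in common_edges:
                            continue
                        i0 = key_index.get((pair, 0))
                        i1 = key_index.get((pair, 1))
                        if i0 is None or i1 is None:
                            continue
                        d0 = np.linalg.norm(pts_arr[i0] - corner)
                        d1 = np.linalg.norm(pts_arr[i1] - corner)
                        ends.append(i0 if d0 <= d1 else i1)
                    for e in ends[1:]:
                        union(ends[0], e)
    roots = {}
    for i in range(len(pts_arr)):
        roots.setdefault(find(i), []).append(i)
    points = np.array([pts_arr[m].mean(axis=0) for m in roots.values()])
    assignment = {}
    for jidx, members in enumerate(roots.values()):
        for m in members:
            assignment[keys[m]] = jidx
    return points, assignment


# ---------------------------------------------------------------------------
# boundary cells
# ---------------------------------------------------------------------------

def boundary_vertex_count(theta_boundary: float) -> int:
    """Number of new vertices on a free membrane arc subtending angle theta:
    Round[theta / (pi/3)], at least 1."""
    if theta_boundary <= 0 or theta_boundary > 2 * math.pi + 1e-9:
        raise ValueError("theta_boundary must be in (0, 2*pi]")
    return max(1, int(round(theta_boundary / (math.pi / 3.0))))


def free_arcs(cell: int, nodes: NodeSet, covered: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of this cell's membrane cycle not adjacent to any other
    cell.  ``covered`` is a boolean mask over all nodes (True = within the
    neighbor threshold of some other cell's membrane)."""
    cyc = nodes.membrane_cycle(cell)
    is_free = ~covered[cyc]
    if not is_free.any():
        return []
    if is_free.all():
        return [cyc]
    n = len(cyc)
    # rotate so position 0 is covered, then collect free runs
    start = int(np.argmin(is_free))
    rot = np.roll(np.arange(n), -start)
    runs, cur = [], []
    for k in rot:
        if is_free[k]:
            cur.append(cyc[k])
        elif cur:
            runs.append(np.array(cur))
            cur = []
    if cur:
        runs.append(np.array(cur))
    return runs


def _arc_angle(arc_pts: np.ndarray, center: np.ndarray) -> float:
    """Total angle the polyline subtends at the cell center."""
    v = arc_pts - center
    ang = np.arctan2(v[:, 1], v[:, 0])
    steps = np.diff(ang)
    steps = (steps + math.pi) % (2 * math.pi) - math.pi
    return float(abs(steps.sum()))


def select_boundary_vertices(arc_pts: np.ndarray, center: np.ndarray,
                             closed: bool = False) -> np.ndarray:
    """Choose evenly spaced membrane nodes on a free arc as mesh vertices.

    The count follows the arc angle (one per pi/3).  For a fully free
    membrane (isolated cell) the arc is closed and spans 2*pi.
    """
    theta = 2 * math.pi if closed else _arc_angle(arc_pts, center)
    theta = min(theta, 2 * math.pi)
    if theta <= 0:
        theta = 1e-6
    n = boundary_vertex_count(theta)
    m = len(arc_pts)
    if closed:
        sel = np.linspace(0, m, n, endpoint=False).astype(int)
    else:
        sel = np.linspace(0, m - 1, n).astype(int)
    return arc_pts[np.unique(sel)]


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def fan_triangulate(center: np.ndarray, perim: np.ndarray):
    """Fan triangles (center, v_k, v_{k+1}) over perimeter points ordered
    counter-clockwise by angle around the center (ties broken by radius)."""
    if len(perim) < 3:
        raise MeshingError("cell has fewer than 3 perimeter vertices")
    v = perim - center
    ang = np.arctan2(v[:, 1], v[:, 0])
    rad = np.linalg.norm(v, axis=1)
    order = np.lexsort((rad, ang))
    return perim[order]


def build_mesh(nodes: NodeSet, params: MeshParams, repair: bool = True) -> TriMesh:
    """Construct the full tissue mesh from the current node configuration."""
    adj = find_neighbors(nodes, params)
    cells = sorted(adj.keys())

    edges: dict[tuple[int, int], np.ndarray] = {}
    for a in cells:
        for b in adj[a]:
            if a < b:
                poly = common_edge(a, b, nodes, params)
                if len(poly) >= 2:
                    edges[(a, b)] = poly
    centers = {c: nodes.membrane_centroid(c) for c in cells}
    jpts, jassign = junction_vertices(edges, params, adjacency=adj,
                                      cell_centers=centers)

    # which membrane nodes are covered by a neighboring cell
    mem = np.nonzero(nodes.kind == MEMBRANE)[0]
    covered = np.zeros(len(nodes), dtype=bool)
    if len(mem):
        tree = cKDTree(nodes.pos[mem])
        for a, b in tree.query_pairs(params.pairing_factor * params.neighbor_threshold):
            ia, ib = mem[a], mem[b]
            if nodes.cell_id[ia] != nodes.cell_id[ib]:
                covered[ia] = True
                covered[ib] = True

    verts: list[np.ndarray] = [p for p in jpts]
    vkey = {i: i for i in range(len(jpts))}   # junction index -> vertex index

    def add_vertex(p: np.ndarray) -> int:
        verts.append(np.asarray(p, dtype=float))
        return len(verts) - 1

    triangles: list[tuple[int, int, int]] = []
    tri_cell: list[int] = []

    for c in cells:
        center = nodes.membrane_centroid(c)
        perim_idx: list[int] = []
        for pair in edges:
            if c in pair:
                for end in (0, 1):
                    j = jassign.get((pair, end))
                    if j is not None:
                        vi = vkey[j]
                        if vi not in perim_idx:
                            perim_idx.append(vi)
        is_isolated = len(adj[c]) == 0
        for arc in free_arcs(c, nodes, covered):
            pts = select_boundary_vertices(nodes.pos[arc], center, closed=is_isolated)
            for p in pts:
                perim_idx.append(add_vertex(p))
        if len(perim_idx) < 3:
            # degenerate junction clustering left too few vertices: fall back
            # to the cell's own membrane nodes so the cell stays meshed
            cyc = nodes.membrane_cycle(c)
            if len(cyc) < 3:
                raise MeshingError(f"cell {c} has fewer than 3 membrane nodes")
            need = 3 - len(perim_idx) + 1
            sel = np.linspace(0, len(cyc), max(need, 3), endpoint=False).astype(int)
            for p in nodes.pos[cyc[sel]]:
                perim_idx.append(add_vertex(p))
        pv = np.array([verts[i] for i in perim_idx])
        vloc = pv - center
        ang = np.arctan2(vloc[:, 1], vloc[:, 0])
        order = np.lexsort((np.linalg.norm(vloc, axis=1), ang))
        ordered = [perim_idx[i] for i in order]
        ci = add_vertex(center)
        n = len(ordered)
        for k in range(n):
            triangles.append((ci, ordered[k], ordered[(k + 1) % n]))
            tri_cell.append(c)

    mesh = TriMesh(vertices=np.array(verts),
                   triangles=np.array(triangles, dtype=np.int64),
                   tri_cell=np.array(tri_cell, dtype=np.int64))
    _drop_degenerate(mesh)
    _dedup_overshared(mesh)
    mesh.finalize()
    if repair:
        mesh = repair_skewed(mesh, params)
    # discard residual slivers the short-edge merge cannot reach (their
    # near-coincident centroids would otherwise cripple the explicit
    # chemistry step); the crack left behind is of near-zero area
    if params.drop_sliver_angle_deg > 0:
        thin = mesh.min_angles() < math.radians(params.drop_sliver_angle_deg)
        if thin.any():
            mesh.triangles = mesh.triangles[~thin]
            mesh.tri_cell = mesh.tri_cell[~thin]
            mesh.finalize()
    # absorbing BC acts on the outer rim: triangles of tissue-boundary cells
    # that also have an unshared (outer) edge.  Restricting to boundary
    # cells keeps interior micro-cracks (from sliver dropping) unflagged.
    boundary_cells = {c for c in cells
                      if len(adj[c]) == 0 or bool(np.any(~covered[nodes.membrane_cycle(c)]))}
    mesh.boundary_tri &= np.isin(mesh.tri_cell, list(boundary_cells))
    return mesh


def _dedup_overshared(mesh: TriMesh) -> None:
    """Drop sliver triangles on edges claimed by more than two triangles.

    Near-degenerate corners (two very short interfaces whose endpoints
    cluster into the same junction pair) can fan the same junction-junction
    edge from three cells; the smallest-area claimant is the sliver and is
    removed until every edge has multiplicity <= 2.
    """
    while True:
        edge_map: dict[tuple[int, int], list[int]] = {}
        for ti, t in enumerate(mesh.triangles):
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edge_map.setdefault((min(a, b), max(a, b)), []).append(ti)
        areas = mesh.areas()
        drop = set()
        for tris in edge_map.values():
            if len(tris) > 2:
                tris = sorted(tris, key=lambda ti: areas[ti])
                drop.update(tris[:len(tris) - 2])
        if not drop:
            return
        keep = np.ones(len(mesh.triangles), dtype=bool)
        keep[list(drop)] = False
        mesh.triangles = mesh.triangles[keep]
        mesh.tri_cell = mesh.tri_cell[keep]


def _drop_degenerate(mesh: TriMesh, eps: float = 1e-12) -> None:
    t = mesh.triangles
    distinct = ((t[:, 0] != t[:, 1]) & (t[:, 1] != t[:, 2]) & (t[:, 0] != t[:, 2]))
    p = mesh.vertices[t]
    area = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    keep = distinct & (area > eps)
    mesh.triangles = mesh.triangles[keep]
    mesh.tri_cell = mesh.tri_cell[keep]


# ---------------------------------------------------------------------------
# skew repair
# ---------------------------------------------------------------------------

def _cell_center_vertices(mesh: TriMesh) -> set[int]:
    """Vertex indices used as cell centers (apex of every fan triangle)."""
    return set(int(t[0]) for t in mesh.triangles)


def repair_skewed(mesh: TriMesh, params: MeshParams) -> TriMesh:
    """Collapse shared edges shorter than ``l_intersect`` to their midpoint.

    Each collapse degenerates the skewed triangles bordering that edge, so
    three connected triangles (skewed one in the middle) become two.  The
    pass repeats until no short edge remains; cell-center vertices are
    never moved.  Adjacency and boundary data are recomputed.  Residual
    skew not caused by short edges is left in place (``min_angle_deg`` is a
    diagnostic bound for it).
    """
    verts = mesh.vertices.copy()
    tris = mesh.triangles.copy()
    tcell = mesh.tri_cell.copy()
    centers = _cell_center_vertices(mesh)

    for it in range(params.max_repair_iter):
        m = TriMesh(verts, tris, tcell)
        _drop_degenerate(m)
        verts, tris, tcell = m.vertices, m.triangles, m.tri_cell
        # shortest perimeter-perimeter edge below the merge threshold
        target = None
        best_len = params.l_intersect
        for t in tris:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                if a in centers or b in centers:
                    continue
                ln = float(np.linalg.norm(verts[a] - verts[b]))
                if ln < best_len:
                    best_len = ln
                    target = (a, b)
        if target is None:
            break
        a, b = target
        mid = 0.5 * (verts[a] + verts[b])
        verts[a] = mid
        tris = np.where(tris == b, a, tris)
    else:
        m = TriMesh(verts, tris, tcell)
        _drop_degenerate(m)
        worst = float(np.degrees(m.min_angles().min())) if len(m.triangles) else 0.0
        raise MeshingError(
            f"skew repair did not converge in {params.max_repair_iter} iterations; "
            f"worst remaining min-angle {worst:.2f} deg")

    out = TriMesh(verts, tris, tcell)
    _drop_degenerate(out)
    _dedup_overshared(out)
    # drop vertices no longer referenced and reindex
    used = np.unique(out.triangles)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    out.vertices = verts[used]
    out.triangles = remap[out.triangles]
    out.finalize()
    if params.split_pass:
        out = split_long_edges(out, params)
    return out


def split_long_edges(mesh: TriMesh, params: MeshParams,
                     factor: float = 2.0) -> TriMesh:
    """Optional refinement pass: bisect shared perimeter edges longer than
    ``factor`` times the median edge length at their midpoint, splitting
    each adjacent triangle in two.  Off by default (``split_pass``)."""
    verts = [v for v in mesh.vertices]
    tris = [tuple(t) for t in mesh.triangles]
    tcell = list(mesh.tri_cell)
    centers = _cell_center_vertices(mesh)

    lengths = []
    for t in mesh.triangles:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            lengths.append(float(np.linalg.norm(mesh.vertices[a]
                                                - mesh.vertices[b])))
    if not lengths:
        return mesh
    limit = factor * float(np.median(lengths))

    edge_map: dict[tuple[int, int], list[int]] = {}
    for ti, t in enumerate(mesh.triangles):
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            edge_map.setdefault((min(a, b), max(a, b)), []).append(ti)

    replaced: dict[int, list[tuple[tuple[int, int, int], int]]] = {}
    candidates = sorted(
        (e for e in edge_map
         if e[0] not in centers and e[1] not in centers),
        key=lambda e: -float(np.linalg.norm(mesh.vertices[e[0]]
                                            - mesh.vertices[e[1]])))
    for (a, b) in candidates:
        if float(np.linalg.norm(mesh.vertices[a] - mesh.vertices[b])) <= limit:
            break
        owners = edge_map[(a, b)]
        # both sides must split around the same midpoint to stay watertight
        if any(ti in replaced for ti in owners):
            continue
        mid = len(verts)
        verts.append(0.5 * (mesh.vertices[a] + mesh.vertices[b]))
        for ti in owners:
            t = tris[ti]
            other = [v for v in t if v not in (a, b)][0]
            replaced[ti] = [((other, a, mid), tcell[ti]),
                            ((other, mid, b), tcell[ti])]
    if not replaced:
        return mesh
    new_tris, new_cells = [], []
    for ti, t in enumerate(tris):
        if ti in replaced:
            for tt, c in replaced[ti]:
                new_tris.append(tt)
                new_cells.append(c)
        else:
            new_tris.append(t)
            new_cells.append(tcell[ti])
    out = TriMesh(np.array(verts), np.array(new_tris, dtype=np.int64),
                  np.array(new_cells, dtype=np.int64))
    _drop_degenerate(out)
    out.finalize()
    return out


# ---------------------------------------------------------------------------
# synthetic validation meshes
# ---------------------------------------------------------------------------

def strip_mesh(n_tris: int, side: float = 1.0,
               absorbing_ends: str = "x") -> TriMesh:
    """Ribbon of ``n_tris`` alternating up/down equilateral triangles of the
    given side length, for 1D validation of the finite-volume solver
    (synthetic; not produced by the cell-based mesh generator).

    Equilateral triangles make the centroid connector perpendicular to each
    shared edge, so the two-point flux is consistent — the same property
    the tissue mesher's quality treatment aims for.  Each triangle is its
    own cell; the strip spans x in [0, (n_tris+1) * side / 2].

    ``absorbing_ends``: "x" flags only the two end triangles as boundary
    (transverse walls no-flux, the 1D analogue), "all" flags every
    geometric boundary triangle, "none" flags none.
    """
    if n_tris < 2:
        raise ValueError("need at least 2 triangles")
    h = side * math.sqrt(3) / 2.0
    n_bot = n_tris // 2 + 2
    bot = [(i * side, 0.0) for i in range(n_bot)]
    top = [((i + 0.5) * side, h) for i in range(n_bot - 1)]
    verts = np.array(bot + top, dtype=float)
    tris = []
    for k in range(n_tris):
        i = k // 2
        if k % 2 == 0:   # up triangle
            tris.append((i, i + 1, n_bot + i))
        else:            # down triangle
            tris.append((n_bot + i, i + 1, n_bot + i + 1))
    mesh = TriMesh(verts, np.array(tris, dtype=np.int64),
                   np.arange(n_tris, dtype=np.int64))
    mesh.finalize()
    if absorbing_ends == "x":
        flags = np.zeros(mesh.n_triangles, dtype=bool)
        flags[0] = True
        flags[-1] = True
        mesh.boundary_tri = flags
    elif absorbing_ends == "none":
        mesh.boundary_tri = np.zeros(mesh.n_triangles, dtype=bool)
    return mesh
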