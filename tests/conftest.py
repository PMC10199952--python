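"""Shared synthetic fixtures: toy cells and honeycomb tissues built
programmatically (no stored data files)."""

from __future__ import annotations

import math

import numpy as np
import pytest

from morphosim.mechanics import INTERNAL, MEMBRANE, CellState, MechParams, NodeSet


def hexagon_points(center, radius, n_per_side=4, phase=0.0):
    """Points along the perimeter of a regular hexagon (flat-topped),
    n_per_side per edge, in cyclic order."""
    corners = [
        (center[0] + radius * math.cos(phase + k * math.pi / 3),
         center[1] + radius * math.sin(phase + k * math.pi / 3))
        for k in range(6)
    ]
    pts = []
    for k in range(6):
        a = np.array(corners[k])
        b = np.array(corners[(k + 1) % 6])
        for t in (np.arange(n_per_side) + 0.5) / n_per_side:
            pts.append(a + t * (b - a))
    return np.array(pts)


def make_honeycomb(n_rings: int = 2, circum_radius: float = 1.0,
                   gap: float = 0.2, n_per_side: int = 4,
                   n_internal: int = 6, rng=None) -> tuple[NodeSet, list[CellState]]:
    """Synthetic honeycomb tissue: hexagonal cells on a triangular lattice.

    Cell membranes are hexagons shrunk by gap/2 so neighboring membranes
    sit ``gap`` apart.  ``n_rings`` rings around a central cell
    (1 + 3 n (n+1) cells).
    """
    rng = rng or np.random.default_rng(0)
    pitch = circum_radius * math.sqrt(3)   # center-to-center distance
    centers = [(0.0, 0.0)]
    for ring in range(1, n_rings + 1):
        for k in range(6):
            a0 = math.pi / 6 + k * math.pi / 3
            a1 = math.pi / 6 + (k + 1) * math.pi / 3
            c0 = np.array([math.cos(a0), math.sin(a0)]) * pitch * ring
            c1 = np.array([math.cos(a1), math.sin(a1)]) * pitch * ring
            for t in range(ring):
                centers.append(tuple(c0 + (c1 - c0) * t / ring))
    r_mem = circum_radius - gap / (2 * math.cos(math.pi / 6))
    pos, kind, cid, order = [], [], [], []
    for c, ctr in enumerate(centers):
        ring_pts = hexagon_points(ctr, r_mem, n_per_side, phase=math.pi / 6)
        for k, p in enumerate(ring_pts):
            pos.append(p)
            kind.append(MEMBRANE)
            cid.append(c)
            order.append(k)
        idx = np.arange(n_internal) + 0.5
        rr = 0.55 * r_mem * np.sqrt(idx / n_internal)
        ang = idx * math.pi * (3 - math.sqrt(5)) + rng.uniform(0, 2 * math.pi)
        for p in np.column_stack([ctr[0] + rr * np.cos(ang),
                                  ctr[1] + rr * np.sin(ang)]):
            pos.append(p)
            kind.append(INTERNAL)
            cid.append(c)
            order.append(-1)
    nodes = NodeSet(np.array(pos), kind, cid, order)
    cells = [CellState(cell_id=c, n_internal_birth=n_internal)
             for c in range(len(centers))]
    return nodes, cells


def single_cell(n_mem=12, n_internal=5, radius=1.0, center=(0.0, 0.0),
                cell_id=0, rng=None):
    """One polygonal cell with membrane nodes on a circle and internal
    nodes inside."""
    rng = rng or np.random.default_rng(0)
    ang = np.linspace(0, 2 * math.pi, n_mem, endpoint=False)
    pos = [np.array(center) + radius * np.array([math.cos(a), math.sin(a)])
           for a in ang]
    kind = [MEMBRANE] * n_mem
    order = list(range(n_mem))
    rr = 0.5 * radius * np.sqrt(rng.uniform(0.05, 1, n_internal))
    th = rng.uniform(0, 2 * math.pi, n_internal)
    for r, t in zip(rr, th):
        pos.append(np.array(center) + r * np.array([math.cos(t), math.sin(t)]))
        kind.append(INTERNAL)
        order.append(-1)
    nodes = NodeSet(np.array(pos), kind, [cell_id] * len(pos), order)
    return nodes, CellState(cell_id=cell_id, n_internal_birth=n_internal)


@pytest.fixture
def honeycomb():
    return make_honeycomb(n_rings=2)


@pytest.fixture
def mech_params():
    return MechParams()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
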