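"""Tissue fixtures, snapshot files and mesh export.

Snapshots are plain CSV/JSON: a node table (node_id, cell_id, kind, x, y,
membrane_order), a cell table (cell_id, phase, generation, g,
dpp_div_memory, ...) and a JSON sidecar with simulation time and the
random-generator state, so a run can be resumed bit-for-bit.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanics import (INTERNAL, MEMBRANE, CellPhase, CellState, MechParams,
                        NodeSet, relax)
from .meshgen import TriMesh

__all__ = [
    "make_initial_tissue",
    "write_snapshot",
    "read_snapshot",
    "export_mesh",
    "SnapshotError",
]

SNAPSHOT_VERSION = 1


class SnapshotError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# initial tissue
# ---------------------------------------------------------------------------

def _hex_centers(n_cells: int, spacing: float) -> np.ndarray:
    """Centers of a hexagonally packed, near-circular patch of n_cells."""
    r = int(math.ceil(math.sqrt(n_cells))) + 2
    pts = []
    for i in range(-r, r + 1):
        for j in range(-r, r + 1):
            x = spacing * (i + 0.5 * (j % 2))
            y = spacing * (math.sqrt(3) / 2) * j
            pts.append((x, y))
    pts = np.array(pts)
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    chosen = pts[order[:n_cells]]
    return chosen - chosen.mean(axis=0)


def make_initial_tissue(n_cells: int, nodes_per_cell_membrane: int = 16,
                        internal_nodes_per_cell: int = 8,
                        rng: np.random.Generator | None = None,
                        cell_radius: float = 1.0,
                        relax_steps: int = 300,
                        params: MechParams | None = None):
    """Near-circular, hexagonally packed tissue of polygonal cells,
    mechanically pre-relaxed.  Deterministic under a seeded rng.

    Returns ``(NodeSet, list[CellState])``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if nodes_per_cell_membrane < 3 or internal_nodes_per_cell < 1:
        raise ValueError("infeasible per-cell node counts")
    rng = rng if rng is not None else np.random.default_rng(0)
    params = params if params is not None else MechParams()

    spacing = 2.0 * cell_radius + params.adh.r_eq
    centers = _hex_centers(n_cells, spacing)

    pos, kind, cid, order = [], [], [], []
    for c, ctr in enumerate(centers):
        ang = np.linspace(0, 2 * math.pi, nodes_per_cell_membrane, endpoint=False)
        ang = ang + rng.uniform(0, 2 * math.pi / nodes_per_cell_membrane)
        ring = ctr + cell_radius * np.column_stack([np.cos(ang), np.sin(ang)])
        for k, p in enumerate(ring):
            pos.append(p)
            kind.append(MEMBRANE)
            cid.append(c)
            order.append(k)
        # sunflower layout for internal nodes
        idx = np.arange(internal_nodes_per_cell) + 0.5
        rr = 0.65 * cell_radius * np.sqrt(idx / internal_nodes_per_cell)
        th = idx * math.pi * (3 - math.sqrt(5)) + rng.uniform(0, 2 * math.pi)
        pts = ctr + np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        pts += rng.normal(0, 0.02 * cell_radius, pts.shape)
        for p in pts:
            pos.append(p)
            kind.append(INTERNAL)
            cid.append(c)
            order.append(-1)

    nodes = NodeSet(np.array(pos), kind, cid, order)
    cells = [CellState(cell_id=c, g=params.g0_max,
                       n_internal_birth=internal_nodes_per_cell)
             for c in range(n_cells)]
    if relax_steps > 0:
        relax(nodes, params, relax_steps, cells)
    nodes.validate()
    return nodes, cells


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------

def write_snapshot(path, nodes: NodeSet, cells: list[CellState],
                   time: float = 0.0, rng: np.random.Generator | None = None,
                   field_table: pd.DataFrame | None = None) -> None:
    """Write a lossless snapshot directory (nodes.csv, cells.csv, meta.json,
    optionally field.csv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "node_id": np.arange(len(nodes)),
        "cell_id": nodes.cell_id,
        "kind": np.where(nodes.kind == MEMBRANE, "membrane", "internal"),
        "x": nodes.pos[:, 0],
        "y": nodes.pos[:, 1],
        "membrane_order": nodes.membrane_order,
    }).to_csv(path / "nodes.csv", index=False, float_format="%.17g")
    pd.DataFrame([{
        "cell_id": c.cell_id, "phase": c.phase.value, "generation": c.generation,
        "g": c.g, "dpp_div_memory": c.dpp_div_memory,
        "n_internal_birth": c.n_internal_birth, "birth_time": c.birth_time,
        "mitotic_since": c.mitotic_since, "parent_id": c.parent_id,
    } for c in cells]).to_csv(path / "cells.csv", index=False, float_format="%.17g")
    meta = {"version": SNAPSHOT_VERSION, "time": time}
    if rng is not None:
        state = rng.bit_generator.state
        meta["rng_state"] = json.loads(json.dumps(state, default=int))
    (path / "meta.json").write_text(json.dumps(meta))
    if field_table is not None:
        field_table.to_csv(path / "field.csv", index=False, float_format="%.17g")


def read_snapshot(path):
    """Read a snapshot directory back into (nodes, cells, time, rng)."""
    path = Path(path)
    if not (path / "meta.json").exists():
        raise SnapshotError(f"no snapshot at {path}")
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("version") != SNAPSHOT_VERSION:
        raise SnapshotError(f"snapshot version {meta.get('version')} != "
                            f"{SNAPSHOT_VERSION}")
    nt = pd.read_csv(path / "nodes.csv", float_precision="round_trip")
    nodes = NodeSet(
        np.column_stack([nt["x"].to_numpy(), nt["y"].to_numpy()]),
        np.where(nt["kind"].to_numpy() == "membrane", MEMBRANE, INTERNAL),
        nt["cell_id"].to_numpy(), nt["membrane_order"].to_numpy())
    ct = pd.read_csv(path / "cells.csv", float_precision="round_trip")
    cells = [CellState(
        cell_id=int(r.cell_id), phase=CellPhase(r.phase),
        generation=int(r.generation), g=float(r.g),
        dpp_div_memory=float(r.dpp_div_memory),
        n_internal_birth=int(r.n_internal_birth),
        birth_time=float(r.birth_time), mitotic_since=float(r.mitotic_since),
        parent_id=int(r.parent_id)) for r in ct.itertuples()]
    rng = None
    if "rng_state" in meta:
        state = meta["rng_state"]
        rng = np.random.default_rng()
        if state.get("bit_generator") == "PCG64":
            st = state.copy()
            st["state"] = {k: int(v) for k, v in state["state"].items()}
            rng.bit_generator.state = st
    return nodes, cells, float(meta["time"]), rng


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def export_mesh(mesh: TriMesh, prefix) -> None:
    """Write the mesh as OFF plus CSV sidecars (triangle->cell table and the
    finite-volume adjacency table)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(str(prefix) + ".off", "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.triangles)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} 0\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
    pd.DataFrame({
        "triangle_id": np.arange(mesh.n_triangles),
        "cell_id": mesh.tri_cell,
        "boundary_flag": mesh.boundary_tri.astype(int),
    }).to_csv(str(prefix) + "_triangles.csv", index=False)
    pd.DataFrame({
        "tri_i": mesh.adjacency[:, 0], "tri_j": mesh.adjacency[:, 1],
        "A": mesh.contact_A, "l": mesh.center_l,
    }).to_csv(str(prefix) + "_adjacency.csv", index=False)
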