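"""Orchestration of the mechanical and chemical submodels.

The two submodels run on separate clocks.  Mechanics advances in small
explicit steps; every ``exchange_interval`` units of mechanical time the
tissue is re-meshed, the previous cell-level concentrations are transferred
onto the new mesh as the initial condition, the chemical network is run to
quasi-steady state, and cell averages of the signals are handed back to the
mechanical submodel, where they drive the division rule: a cell divides
when its signal has risen by ``rule_threshold`` (default 50%) relative to
the level remembered at the start of its cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import mechanics as mech
from . import meshgen
from . import signaling
from .mechanics import CellPhase, CellState, NodeSet, PairCache
from .signaling import ChemField

__all__ = [
    "CouplingConfig",
    "CellSignals",
    "DivisionEvent",
    "Snapshot",
    "cell_average",
    "transfer_initial_condition",
    "division_rule",
    "exchange_schedule",
    "run_coupled",
]


@dataclass(frozen=True)
class CouplingConfig:
    """Temporal-coupling and division-rule settings.

    exchange_interval : mechanical time units between chemical updates.
    rule_signal : species the division rule reads; "auto" resolves to Dpp
        in simplified mode and pMad in full mode.
    rule_threshold : relative signal increase triggering division.
    """

    exchange_interval: float = 200.0
    rule_signal: str = "auto"       # "auto" | "dpp" | "pmad"
    rule_threshold: float = 0.5
    L_update: bool = True
    t_end: float = 2000.0
    max_cells: int = 100000
    save_every: int = 1             # record a snapshot every k exchanges
    growth_substep: float = 1.0     # mechanical time between growth draws

    @property
    def f_exch(self) -> float:
        return 1.0 / self.exchange_interval

    def __post_init__(self):
        if self.exchange_interval <= 0:
            raise ValueError("exchange_interval must be positive")
        if self.rule_threshold <= 0:
            raise ValueError("rule_threshold must be positive")
        if self.rule_signal not in ("auto", "dpp", "pmad"):
            raise ValueError(f"unknown rule_signal {self.rule_signal!r}")


@dataclass
class CellSignals:
    """Per-cell area-weighted average concentrations."""

    values: dict[str, dict[int, float]]    # species -> cell -> average

    def get(self, species: str, cell: int, default: float = 0.0) -> float:
        return self.values.get(species, {}).get(cell, default)

    def cells(self):
        for d in self.values.values():
            return sorted(d.keys())
        return []


@dataclass
class DivisionEvent:
    time: float
    cell_id: int
    position: np.ndarray
    signal_value: float
    daughters: tuple[int, int]


@dataclass
class Snapshot:
    time: float
    n_cells: int
    n_nodes: int
    n_triangles: int
    circularity: float
    L: float
    signals: CellSignals
    cell_positions: dict[int, np.ndarray]
    nodes: NodeSet | None = None


def cell_average(field: ChemField, mesh: meshgen.TriMesh,
                 mode: str = "simplified") -> CellSignals:
    """Area-weighted mean of each species over every cell's triangles."""
    areas = mesh.areas()
    out: dict[str, dict[int, float]] = {}
    cells = np.unique(mesh.tri_cell)
    for name, arr in field.species(mode).items():
        per: dict[int, float] = {}
        for c in cells:
            m = mesh.tri_cell == c
            w = areas[m]
            if w.sum() <= 0:
                raise ValueError(f"cell {int(c)} has zero mesh area")
            per[int(c)] = float(np.average(arr[m], weights=w))
        out[name] = per
    if not len(cells):
        raise ValueError("mesh contains no triangles")
    return CellSignals(out)


def transfer_initial_condition(old: CellSignals | None, mesh: meshgen.TriMesh,
                               parent_map: dict[int, int] | None = None,
                               mode: str = "simplified") -> ChemField:
    """Initial condition on a fresh mesh from the previous cell averages.

    Every triangle starts at its cell's last average; cells born since the
    last update inherit the parent's value via ``parent_map``; cells with
    no recorded value start at zero.
    """
    n = mesh.n_triangles
    f = ChemField.zeros(n)
    parent_map = parent_map or {}
    if old is not None:
        names = ("dpp",) if mode == "simplified" else ("dpp", "tkv", "dpp_tkv", "pmad")
        for name in names:
            arr = getattr(f, name)
            for t in range(n):
                c = int(mesh.tri_cell[t])
                while c not in old.values.get(name, {}) and c in parent_map:
                    c = parent_map[c]
                arr[t] = old.get(name, c, 0.0)
    return f


def division_rule(signals: CellSignals, cell: CellState,
                  config: CouplingConfig, mode: str = "simplified") -> bool:
    """True when the cell's signal rose by >= rule_threshold relative to its
    cycle-start memory.  A memory of zero (or unset) never triggers."""
    name = config.rule_signal
    if name == "auto":
        name = "dpp" if mode == "simplified" else "pmad"
    mem = cell.dpp_div_memory
    if mem <= 0:
        return False
    now = signals.get(name, cell.cell_id, 0.0)
    return (now - mem) / mem >= config.rule_threshold


def exchange_schedule(g0_max: float, exchange_interval: float):
    """Derived coupling quantities: the shortest cell-cycle time 1/g0
    (floored), the exchange frequency, and the number of chemical updates
    per shortest cycle."""
    if g0_max <= 0:
        raise ValueError("g0_max must be positive")
    min_cycle = math.floor(1.0 / g0_max)
    f_exch = 1.0 / exchange_interval
    updates = math.floor(min_cycle / exchange_interval)
    return min_cycle, f_exch, updates


# ---------------------------------------------------------------------------
# the coupled loop
# ---------------------------------------------------------------------------

def _resolve_signal(coupling: CouplingConfig, mode: str) -> str:
    if coupling.rule_signal != "auto":
        return coupling.rule_signal
    return "dpp" if mode == "simplified" else "pmad"


def run_coupled(cfg, nodes: NodeSet | None = None,
                cells: list[CellState] | None = None,
                rng: np.random.Generator | None = None,
                start_time: float = 0.0):
    """Run the coupled simulation defined by a SimConfig.

    Returns ``(snapshots, division_events, final_state)`` where final_state
    is a dict with the nodes, cells, signals and rng needed to resume.
    """
    from .io import make_initial_tissue   # deferred: io imports mechanics only

    mp: mech.MechParams = cfg.mechanics
    meshp: meshgen.MeshParams = cfg.mesh
    chem: signaling.ChemParams = cfg.signaling
    coup: CouplingConfig = cfg.coupling

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if nodes is None or cells is None:
        nodes, cells = make_initial_tissue(
            cfg.tissue.n_cells, cfg.tissue.nodes_per_cell_membrane,
            cfg.tissue.internal_nodes_per_cell, rng,
            cell_radius=cfg.tissue.cell_radius,
            relax_steps=cfg.tissue.relax_steps, params=mp)
    for c in cells:
        if c.g <= 0:
            c.g = mp.g0_max
    signal_name = _resolve_signal(coup, chem.mode)
    midline = float(nodes.pos[:, 0].mean())    # AP midline fixed at t=0 centroid

    t = start_time
    signals: CellSignals | None = None
    parent_map: dict[int, int] = {}
    next_id = int(max(c.cell_id for c in cells)) + 1
    snapshots: list[Snapshot] = []
    events: list[DivisionEvent] = []
    cache = PairCache()
    n_steps = max(1, int(round(coup.exchange_interval / mp.dt_mech)))
    grow_every = max(1, int(round(coup.growth_substep / mp.dt_mech)))
    exchange = 0

    while t < coup.t_end and len(cells) < coup.max_cells:
        # ---- mechanics for one exchange interval (with interphase growth)
        for s in range(n_steps):
            mech.step_mechanics(nodes, mp, cells, cache, clip=True)
            if (s + 1) % grow_every == 0:
                dt_g = grow_every * mp.dt_mech
                for c in cells:
                    mech.grow_cell(c, nodes, mp, dt_g, rng)
        t += n_steps * mp.dt_mech
        exchange += 1

        # ---- remesh and solve chemistry to quasi-steady state
        mesh = meshgen.build_mesh(nodes, meshp)
        x = signaling.midline_x(mesh, midline)
        L = float(x.max()) if coup.L_update or not snapshots else snapshots[-1].L
        f = transfer_initial_condition(signals, mesh, parent_map, chem.mode)
        f.x = x
        f, _ = signaling.run_to_quasi_steady(f, mesh, chem, L)
        new_signals = cell_average(f, mesh, chem.mode)
        if signals is not None:
            # cells the mesher missed keep their previous averages
            for name, per in signals.values.items():
                tgt = new_signals.values.setdefault(name, {})
                for cid, v in per.items():
                    if cid not in tgt and any(c.cell_id == cid for c in cells):
                        tgt[cid] = v
        signals = new_signals

        # ---- cycle bookkeeping: memories, flags, mitosis, splits
        for c in cells:
            if c.dpp_div_memory < 0:
                c.dpp_div_memory = signals.get(signal_name, c.cell_id, 0.0)
        new_cells: list[CellState] = []
        for c in cells:
            flag = (c.phase == CellPhase.INTERPHASE
                    and division_rule(signals, c, coup, chem.mode))
            pos_before = nodes.centroid(c.cell_id) if c.phase == CellPhase.MITOTIC else None
            out = mech.advance_cycle_and_divide(c, nodes, flag, t, mp, rng, next_id)
            if len(out) == 2:
                d0, d1 = out
                parent_map[d0.cell_id] = c.cell_id
                parent_map[d1.cell_id] = c.cell_id
                next_id += 2
                events.append(DivisionEvent(
                    time=t, cell_id=c.cell_id, position=pos_before,
                    signal_value=signals.get(signal_name, c.cell_id, 0.0),
                    daughters=(d0.cell_id, d1.cell_id)))
            new_cells.extend(out)
        if len(new_cells) != len(cells):
            cache = PairCache()     # topology changed; rebuild pair lists
        cells = new_cells

        if exchange % coup.save_every == 0 or t >= coup.t_end:
            from .metrics import circularity as _circ
            snapshots.append(Snapshot(
                time=t, n_cells=len(cells), n_nodes=len(nodes),
                n_triangles=mesh.n_triangles, circularity=_circ(nodes),
                L=L, signals=signals,
                cell_positions={c.cell_id: nodes.centroid(c.cell_id) for c in cells}))

    final = {"nodes": nodes, "cells": cells, "signals": signals,
             "rng": rng, "time": t, "parent_map": parent_map}
    return snapshots, events, final
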