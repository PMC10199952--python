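"""Subcellular-element mechanics of an epithelial cell monolayer.

Each cell is a cloud of *internal* nodes (cytoplasm) enclosed by a closed
cycle of *membrane* nodes (plasma membrane + cortex).  Five interaction
classes act between nodes:

=====  ====================================  ==========================
class  node pair                             energy form
=====  ====================================  ==========================
II     internal-internal, same cell          Morse (cytoplasmic pressure)
MI     internal-membrane, same cell          Morse (pressure on cortex)
MMS    consecutive membrane, same cell       linear spring (cortical stiffness)
MMD    membrane-membrane, different cells    repulsive-only Morse (excluded volume)
Adh    membrane-membrane, different cells    Morse (cell-cell adhesion)
=====  ====================================  ==========================

Node motion is overdamped: ``eta * dx/dt = F`` integrated with explicit
Euler.  Growth adds internal nodes at a constant rate during interphase;
division splits a cell along the plane through its centroid perpendicular
to its long axis (Hertwig-type rule) with a small random angular jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

INTERNAL = 0
MEMBRANE = 1

__all__ = [
    "INTERNAL",
    "MEMBRANE",
    "MorseParams",
    "SpringParams",
    "MechParams",
    "CellPhase",
    "CellState",
    "NodeSet",
    "StabilityError",
    "pair_energy",
    "total_forces",
    "total_energy",
    "step_mechanics",
    "grow_cell",
    "advance_cycle_and_divide",
    "relax",
]


class StabilityError(RuntimeError):
    """A node moved farther than the configured guard in one step (dt too large)."""


class ConfigurationError(ValueError):
    """Unknown interaction class or inconsistent parameters."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseParams:
    """Morse well U(r) = u0 * (exp(-2(r-r_eq)/xi) - 2 exp(-(r-r_eq)/xi)).

    ``repulsive_only=True`` truncates the well at its minimum and shifts it
    up so the interaction is purely repulsive (zero for r >= r_eq).
    """

    u0: float
    r_eq: float
    xi: float
    cutoff: float
    repulsive_only: bool = False


@dataclass(frozen=True)
class SpringParams:
    """Harmonic spring U(r) = 0.5 * k * (r - l0)**2 between consecutive membrane nodes."""

    k: float
    l0: float


@dataclass(frozen=True)
class MechParams:
    """All mechanical parameters.  Defaults are the package's own calibration
    (uncalibrated against any published table) tuned so that a ~100-cell
    tissue of unit-radius cells is mechanically stable and a single cell
    relaxes to a near-circular shape."""

    eta: float = 1.0
    # cytoplasmic pressure and membrane pressure: Morse truncated at the well
    # (repulsive-only) so the cytoplasm cannot condense under the attractive tail
    ii: MorseParams = field(
        default_factory=lambda: MorseParams(0.35, 0.60, 0.25, 0.60, repulsive_only=True))
    mi: MorseParams = field(
        default_factory=lambda: MorseParams(0.30, 0.70, 0.30, 0.70, repulsive_only=True))
    adh: MorseParams = field(default_factory=lambda: MorseParams(0.08, 0.18, 0.15, 0.8))
    mmd: MorseParams = field(
        default_factory=lambda: MorseParams(0.50, 0.15, 0.08, 0.15, repulsive_only=True)
    )
    mms: SpringParams = field(default_factory=lambda: SpringParams(10.0, 0.20))
    dt_mech: float = 0.02
    max_displacement: float = 0.25
    # growth / cycle
    g0_max: float = 1.1e-4          # node-addition rate: doubling time 1/g
    growth_jitter: float = 0.25     # sd (length units) of new-node placement around centroid
    generation_decay: float = 0.9   # g_daughter = g_parent * decay
    decay_law: str = "generation"   # "generation" | "time"
    time_decay_rate: float = 0.0    # only for decay_law == "time": g(t) = g0*exp(-rate*t)
    growth_cap_factor: float = 2.0  # interphase growth stops at cap * birth count
    mitotic_duration: float = 20.0  # mechanical time spent rounding before the split
    rounding_mms_factor: float = 3.0
    rounding_mi_factor: float = 1.5
    neighbor_skin: float = 0.3      # Verlet skin added to cutoffs when caching pairs
    rebuild_every: int = 10         # pair-cache rebuild interval (steps)

    def __post_init__(self):
        if self.eta <= 0 or self.dt_mech <= 0:
            raise ConfigurationError("eta and dt_mech must be positive")
        for m in (self.ii, self.mi, self.adh, self.mmd):
            if m.cutoff <= 0:
                raise ConfigurationError("all interaction cutoffs must be positive")


class CellPhase(str, Enum):
    INTERPHASE = "interphase"
    MITOTIC = "mitotic"


@dataclass
class CellState:
    """Per-cell bookkeeping: cycle phase, growth rate and division memory."""

    cell_id: int
    phase: CellPhase = CellPhase.INTERPHASE
    g: float = 1.1e-4               # current node-addition rate (fraction of birth count / time)
    generation: int = 0
    dpp_div_memory: float = -1.0    # signal level at cycle start; <0 means "not yet set"
    n_internal_birth: int = 0       # internal count at cycle start (sets the linear growth rate)
    birth_time: float = 0.0
    mitotic_since: float = -1.0     # sim time the cell entered mitosis; <0 in interphase
    parent_id: int = -1
    growth_residual: float = 0.0    # fractional node accumulator for deterministic part


# ---------------------------------------------------------------------------
# node container
# ---------------------------------------------------------------------------

class NodeSet:
    """Struct-of-arrays container for all subcellular nodes of a tissue.

    Attributes
    ----------
    pos : (N, 2) float array of positions (µm)
    kind : (N,) uint8 array, INTERNAL or MEMBRANE
    cell_id : (N,) int array, owning cell
    membrane_order : (N,) int array, cyclic index within the owning cell's
        membrane (-1 for internal nodes)
    """

    def __init__(self, pos, kind, cell_id, membrane_order):
        self.pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        self.kind = np.asarray(kind, dtype=np.uint8)
        self.cell_id = np.asarray(cell_id, dtype=np.int64)
        self.membrane_order = np.asarray(membrane_order, dtype=np.int64)
        n = len(self.pos)
        if not (len(self.kind) == len(self.cell_id) == len(self.membrane_order) == n):
            raise ValueError("NodeSet arrays must have equal length")

    def __len__(self):
        return len(self.pos)

    @property
    def n_nodes(self):
        return len(self.pos)

    def copy(self) -> "NodeSet":
        return NodeSet(self.pos.copy(), self.kind.copy(),
                       self.cell_id.copy(), self.membrane_order.copy())

    def cell_ids(self) -> np.ndarray:
        return np.unique(self.cell_id)

    def nodes_of(self, cell: int, kind: int | None = None) -> np.ndarray:
        mask = self.cell_id == cell
        if kind is not None:
            mask &= self.kind == kind
        return np.nonzero(mask)[0]

    def membrane_cycle(self, cell: int) -> np.ndarray:
        """Indices of the cell's membrane nodes in cyclic order."""
        idx = self.nodes_of(cell, MEMBRANE)
        return idx[np.argsort(self.membrane_order[idx])]

    def centroid(self, cell: int) -> np.ndarray:
        return self.pos[self.cell_id == cell].mean(axis=0)

    def membrane_centroid(self, cell: int) -> np.ndarray:
        return self.pos[self.membrane_cycle(cell)].mean(axis=0)

    def validate(self) -> None:
        """Check the structural invariants (one owner per node, closed membrane
        cycles with >= 3 nodes, >= 1 internal node per cell)."""
        for c in self.cell_ids():
            n_int = len(self.nodes_of(c, INTERNAL))
            cyc = self.membrane_cycle(c)
            if n_int < 1:
                raise ValueError(f"cell {c} has no internal nodes")
            if len(cyc) < 3:
                raise ValueError(f"cell {c} has fewer than 3 membrane nodes")
            orders = np.sort(self.membrane_order[cyc])
            if not np.array_equal(orders, np.arange(len(cyc))):
                raise ValueError(f"cell {c} membrane orders are not 0..{len(cyc)-1}")

    def append(self, pos, kind, cell, order=-1) -> int:
        self.pos = np.vstack([self.pos, np.asarray(pos, dtype=float).reshape(1, 2)])
        self.kind = np.append(self.kind, np.uint8(kind))
        self.cell_id = np.append(self.cell_id, np.int64(cell))
        self.membrane_order = np.append(self.membrane_order, np.int64(order))
        return len(self.pos) - 1


# ---------------------------------------------------------------------------
# pair energies
# ---------------------------------------------------------------------------

_MORSE_CLASSES = {"II": "ii", "MI": "mi", "Adh": "adh", "MMD": "mmd"}


def _morse_u_f(r: np.ndarray, p: MorseParams):
    """Morse energy and scalar force (-dU/dr) at separation r (vectorized)."""
    e1 = np.exp(-(r - p.r_eq) / p.xi)
    u = p.u0 * (e1 * e1 - 2.0 * e1)
    f = (2.0 * p.u0 / p.xi) * (e1 * e1 - e1)   # -dU/dr
    if p.repulsive_only:
        inside = r < p.r_eq
        u = np.where(inside, u + p.u0, 0.0)    # shift so U(r_eq) = 0
        f = np.where(inside, f, 0.0)
    beyond = r > p.cutoff
    u = np.where(beyond, 0.0, u)
    f = np.where(beyond, 0.0, f)
    return u, f


def _spring_u_f(r: np.ndarray, p: SpringParams):
    d = r - p.l0
    return 0.5 * p.k * d * d, -p.k * d


def pair_energy(cls: str, r, params: MechParams):
    """Energy U(r) and scalar force -dU/dr for one interaction class.

    Positive force = repulsion (acts to increase r).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    if cls in _MORSE_CLASSES:
        return _morse_u_f(r, getattr(params, _MORSE_CLASSES[cls]))
    if cls == "MMS":
        return _spring_u_f(r, params.mms)
    raise ConfigurationError(f"unknown interaction class {cls!r}")


# ---------------------------------------------------------------------------
# pair caching (Verlet-style neighbor lists)
# ---------------------------------------------------------------------------

class PairCache:
    """Cached interaction pair lists, rebuilt every ``rebuild_every`` steps.

    Cutoffs are padded by ``neighbor_skin`` at build time; exact cutoffs are
    re-applied on every evaluation, so forces are unaffected by the cache.
    """

    def __init__(self):
        self.intra = None       # (P,2) same-cell candidate pairs (II/MI classes)
        self.inter = None       # (Q,2) different-cell membrane pairs (MMD/Adh)
        self.mms = None         # (S,2) consecutive membrane pairs
        self.mms_cell = None    # (S,) owning cell of each spring
        self.mi_cell = None
        self.age = 10 ** 9
        self.n_nodes = -1

    def rebuild(self, nodes: NodeSet, params: MechParams) -> None:
        pos = nodes.pos
        skin = params.neighbor_skin
        r_intra = max(params.ii.cutoff, params.mi.cutoff) + skin
        r_inter = max(params.adh.cutoff, params.mmd.cutoff) + skin
        tree = cKDTree(pos)
        pairs = tree.query_pairs(max(r_intra, r_inter), output_type="ndarray")
        if len(pairs) == 0:
            pairs = np.empty((0, 2), dtype=np.int64)
        same = nodes.cell_id[pairs[:, 0]] == nodes.cell_id[pairs[:, 1]]
        d = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)

        intra = pairs[same & (d <= r_intra)]
        # drop consecutive-membrane pairs handled by MMS springs
        k0, k1 = nodes.kind[intra[:, 0]], nodes.kind[intra[:, 1]]
        both_mem = (k0 == MEMBRANE) & (k1 == MEMBRANE)
        self.intra = intra[~both_mem]

        inter = pairs[~same & (d <= r_inter)]
        kin = (nodes.kind[inter[:, 0]] == MEMBRANE) & (nodes.kind[inter[:, 1]] == MEMBRANE)
        self.inter = inter[kin]

        springs = []
        cells = []
        for c in nodes.cell_ids():
            cyc = nodes.membrane_cycle(c)
            nxt = np.roll(cyc, -1)
            sp = np.column_stack([cyc, nxt])
            if len(cyc) == 2:
                sp = sp[:1]   # a 2-node cycle has one spring, not two
            springs.append(sp)
            cells.append(np.full(len(sp), c))
        self.mms = np.vstack(springs) if springs else np.empty((0, 2), dtype=np.int64)
        self.mms_cell = np.concatenate(cells) if cells else np.empty(0, dtype=np.int64)
        self.age = 0
        self.n_nodes = len(nodes)

    def ensure(self, nodes: NodeSet, params: MechParams) -> None:
        if (self.age >= params.rebuild_every or self.n_nodes != len(nodes)
                or self.intra is None):
            self.rebuild(nodes, params)


# ---------------------------------------------------------------------------
# forces and integration
# ---------------------------------------------------------------------------

def _pair_r(pos, pairs):
    d = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    return d, np.sqrt((d * d).sum(axis=1))


def _accumulate(forces, pairs, dvec, r, scalar_f):
    """Add pairwise central forces to the per-node force array."""
    if len(pairs) == 0:
        return
    r_safe = np.where(r < 1e-12, 1.0, r)
    fvec = (scalar_f / r_safe)[:, None] * dvec
    n = len(forces)
    for k in (0, 1):
        s = 1.0 if k == 0 else -1.0
        forces[:, 0] += np.bincount(pairs[:, k], weights=s * fvec[:, 0], minlength=n)
        forces[:, 1] += np.bincount(pairs[:, k], weights=s * fvec[:, 1], minlength=n)


def _cell_factor(cells_map: dict[int, CellState], params: MechParams,
                 ids: np.ndarray, which: str) -> np.ndarray:
    """Per-pair stiffness multiplier implementing mitotic rounding."""
    if not cells_map:
        return np.ones(len(ids))
    fac = np.ones(len(ids))
    mitotic = {c for c, s in cells_map.items() if s.phase == CellPhase.MITOTIC}
    if mitotic:
        mult = params.rounding_mms_factor if which == "mms" else params.rounding_mi_factor
        fac[np.isin(ids, list(mitotic))] = mult
    return fac


def total_forces(nodes: NodeSet, params: MechParams,
                 cells: Iterable[CellState] = (),
                 cache: PairCache | None = None) -> np.ndarray:
    """Per-node force vectors from all five interaction classes.

    Internal nodes feel II + MI; membrane nodes feel MI + MMS + MMD + Adh.
    Forces are pairwise central, so Newton's third law holds by construction.
    """
    if cache is None:
        cache = PairCache()
    cache.ensure(nodes, params)
    cmap = {c.cell_id: c for c in cells}
    pos = nodes.pos
    forces = np.zeros_like(pos)

    ip = cache.intra
    if len(ip):
        k0, k1 = nodes.kind[ip[:, 0]], nodes.kind[ip[:, 1]]
        dvec, r = _pair_r(pos, ip)
        is_ii = (k0 == INTERNAL) & (k1 == INTERNAL)
        _, f_ii = _morse_u_f(r, params.ii)
        _, f_mi = _morse_u_f(r, params.mi)
        fac = _cell_factor(cmap, params, nodes.cell_id[ip[:, 0]], "mi")
        scal = np.where(is_ii, f_ii, f_mi * fac)
        _accumulate(forces, ip, dvec, r, scal)

    ep = cache.inter
    if len(ep):
        dvec, r = _pair_r(pos, ep)
        _, f_mmd = _morse_u_f(r, params.mmd)
        _, f_adh = _morse_u_f(r, params.adh)
        _accumulate(forces, ep, dvec, r, f_mmd + f_adh)

    sp = cache.mms
    if len(sp):
        dvec, r = _pair_r(pos, sp)
        _, f_s = _spring_u_f(r, params.mms)
        fac = _cell_factor(cmap, params, cache.mms_cell, "mms")
        _accumulate(forces, sp, dvec, r, f_s * fac)

    return forces


def total_energy(nodes: NodeSet, params: MechParams,
                 cells: Iterable[CellState] = (),
                 cache: PairCache | None = None) -> float:
    """Total interaction energy (oracle counterpart of :func:`total_forces`)."""
    if cache is None:
        cache = PairCache()
    cache.ensure(nodes, params)
    cmap = {c.cell_id: c for c in cells}
    pos = nodes.pos
    e = 0.0
    ip = cache.intra
    if len(ip):
        k0, k1 = nodes.kind[ip[:, 0]], nodes.kind[ip[:, 1]]
        r = np.linalg.norm(pos[ip[:, 0]] - pos[ip[:, 1]], axis=1)
        is_ii = (k0 == INTERNAL) & (k1 == INTERNAL)
        u_ii, _ = _morse_u_f(r, params.ii)
        u_mi, _ = _morse_u_f(r, params.mi)
        fac = _cell_factor(cmap, params, nodes.cell_id[ip[:, 0]], "mi")
        e += float(np.sum(np.where(is_ii, u_ii, u_mi * fac)))
    ep = cache.inter
    if len(ep):
        r = np.linalg.norm(pos[ep[:, 0]] - pos[ep[:, 1]], axis=1)
        u_mmd, _ = _morse_u_f(r, params.mmd)
        u_adh, _ = _morse_u_f(r, params.adh)
        e += float(np.sum(u_mmd + u_adh))
    sp = cache.mms
    if len(sp):
        r = np.linalg.norm(pos[sp[:, 0]] - pos[sp[:, 1]], axis=1)
        u_s, _ = _spring_u_f(r, params.mms)
        fac = _cell_factor(cmap, params, cache.mms_cell, "mms")
        e += float(np.sum(u_s * fac))
    return e


def step_mechanics(nodes: NodeSet, params: MechParams,
                   cells: Iterable[CellState] = (),
                   cache: PairCache | None = None,
                   dt: float | None = None, clip: bool = False) -> NodeSet:
    """One explicit-Euler step of the overdamped dynamics, in place.

    x <- x + (dt/eta) * F.  By default raises :class:`StabilityError` if any
    node would move farther than ``params.max_displacement``; with
    ``clip=True`` the step is instead rescaled globally so the largest
    displacement equals the guard (used during fixture relaxation and
    growth, where freshly inserted nodes can transiently overlap).  The
    global rescale keeps the net displacement of the tissue at zero, so
    clipping cannot make the tissue drift.
    """
    dt = params.dt_mech if dt is None else dt
    forces = total_forces(nodes, params, cells, cache)
    disp = (dt / params.eta) * forces
    mags = np.linalg.norm(disp, axis=1)
    if mags.size and mags.max() > params.max_displacement:
        if not clip:
            raise StabilityError(
                f"max displacement {mags.max():.3g} exceeds guard "
                f"{params.max_displacement:.3g}; reduce dt_mech")
        disp *= params.max_displacement / mags.max()
    nodes.pos += disp
    if cache is not None:
        cache.age += 1
    return nodes


def relax(nodes: NodeSet, params: MechParams, n_steps: int,
          cells: Iterable[CellState] = ()) -> NodeSet:
    """Run ``n_steps`` of pure mechanical relaxation (no growth, no division)."""
    cache = PairCache()
    for _ in range(n_steps):
        step_mechanics(nodes, params, cells, cache, clip=True)
    return nodes


# ---------------------------------------------------------------------------
# growth and division
# ---------------------------------------------------------------------------

def grow_cell(cell: CellState, nodes: NodeSet, params: MechParams,
              dt: float, rng: np.random.Generator) -> None:
    """Add internal nodes at expected rate g * N_birth * dt (in place).

    The rate is anchored to the internal count at cycle start, so node count
    grows linearly and the doubling time is 1/g.  Growth stops at
    ``growth_cap_factor`` times the birth count (the cell then waits in
    interphase for the division trigger).
    """
    if cell.phase != CellPhase.INTERPHASE or cell.g <= 0:
        return
    n_now = len(nodes.nodes_of(cell.cell_id, INTERNAL))
    cap = int(round(params.growth_cap_factor * max(cell.n_internal_birth, 1)))
    if n_now >= cap:
        return
    lam = cell.g * max(cell.n_internal_birth, 1) * dt
    n_add = int(rng.poisson(lam))
    n_add = min(n_add, cap - n_now)
    if n_add == 0:
        return
    c = nodes.centroid(cell.cell_id)
    for _ in range(n_add):
        jitter = rng.normal(0.0, params.growth_jitter, size=2)
        nodes.append(c + jitter, INTERNAL, cell.cell_id)


def _long_axis(points: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest second-moment eigenvalue."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / max(len(points), 1)
    w, v = np.linalg.eigh(cov)
    return v[:, int(np.argmax(w))]


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points, even in arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    j = 0
    for i, t in enumerate(targets):
        while j < len(seg) - 1 and s[j + 1] < t:
            j += 1
        denom = seg[j] if seg[j] > 1e-12 else 1.0
        frac = (t - s[j]) / denom
        out[i] = closed[j] + frac * (closed[j + 1] - closed[j])
    return out


def _daughter_membrane(cycle_pts: np.ndarray, centroid: np.ndarray,
                       axis: np.ndarray, side: int, n_mem: int,
                       offset: float) -> np.ndarray | None:
    """Closed membrane polygon for one daughter: the parent's membrane arc on
    one side of the division line plus the chord, resampled evenly."""
    proj = (cycle_pts - centroid) @ axis
    keep = proj * side > 0
    if keep.sum() < 2:
        return None
    # walk the cycle; insert intersection points where the division line is crossed
    n = len(cycle_pts)
    poly: list[np.ndarray] = []
    for i in range(n):
        j = (i + 1) % n
        if keep[i]:
            poly.append(cycle_pts[i])
        if keep[i] != keep[j]:
            t = proj[i] / (proj[i] - proj[j])
            poly.append(cycle_pts[i] + t * (cycle_pts[j] - cycle_pts[i]))
    arr = np.array(poly)
    # nudge chord points off the division line toward this daughter's side
    on_line = np.abs((arr - centroid) @ axis) < 1e-9
    arr[on_line] += side * offset * axis
    target_area = _polygon_area(arr)
    out = _resample_closed(arr, n_mem)
    # resampling cuts corners; rescale about the centroid to keep the area
    a = _polygon_area(out)
    if a > 1e-12:
        c = out.mean(axis=0)
        out = c + (out - c) * math.sqrt(target_area / a)
    return out


def advance_cycle_and_divide(cell: CellState, nodes: NodeSet,
                             division_flag: bool, sim_time: float,
                             params: MechParams, rng: np.random.Generator,
                             next_cell_id: int) -> list[CellState]:
    """Advance one cell through the mitosis pipeline (in place on ``nodes``).

    Interphase + flag -> enter mitosis (rounding).  Mitotic + elapsed
    duration -> split into two daughters; returns the daughter states.
    Otherwise returns ``[cell]`` unchanged.
    """
    if cell.phase == CellPhase.INTERPHASE:
        if division_flag:
            n_int = len(nodes.nodes_of(cell.cell_id, INTERNAL))
            if n_int < 2:
                return [cell]   # refused: too few internal nodes to split
            cell.phase = CellPhase.MITOTIC
            cell.mitotic_since = sim_time
        return [cell]

    if sim_time - cell.mitotic_since < params.mitotic_duration:
        return [cell]
    return _split(cell, nodes, params, rng, next_cell_id, sim_time)


def _split(cell: CellState, nodes: NodeSet, params: MechParams,
           rng: np.random.Generator, next_cell_id: int,
           sim_time: float) -> list[CellState]:
    cid = cell.cell_id
    internal = nodes.nodes_of(cid, INTERNAL)
    cyc = nodes.membrane_cycle(cid)
    all_pts = nodes.pos[np.concatenate([internal, cyc])]
    centroid = all_pts.mean(axis=0)

    axis = _long_axis(all_pts)
    ang = rng.normal(0.0, math.radians(5.0))
    rot = np.array([[math.cos(ang), -math.sin(ang)],
                    [math.sin(ang), math.cos(ang)]])
    axis = rot @ axis

    proj = (nodes.pos[internal] - centroid) @ axis
    side_a = internal[proj > 0]
    side_b = internal[proj <= 0]
    if len(side_a) == 0 or len(side_b) == 0:
        cell.phase = CellPhase.INTERPHASE   # degenerate split refused
        cell.mitotic_since = -1.0
        return [cell]

    n_mem = len(cyc)
    offset = 0.5 * params.mmd.r_eq
    mem_a = _daughter_membrane(nodes.pos[cyc], centroid, axis, +1, n_mem, offset)
    mem_b = _daughter_membrane(nodes.pos[cyc], centroid, axis, -1, n_mem, offset)
    if mem_a is None or mem_b is None:
        cell.phase = CellPhase.INTERPHASE
        cell.mitotic_since = -1.0
        return [cell]

    id_a, id_b = next_cell_id, next_cell_id + 1
    nodes.cell_id[side_a] = id_a
    nodes.cell_id[side_b] = id_b
    # replace the parent membrane with the two resampled daughter membranes
    keep = np.ones(len(nodes), dtype=bool)
    keep[cyc] = False
    nodes.pos = nodes.pos[keep]
    nodes.kind = nodes.kind[keep]
    nodes.cell_id = nodes.cell_id[keep]
    nodes.membrane_order = nodes.membrane_order[keep]
    for mem, did in ((mem_a, id_a), (mem_b, id_b)):
        for k, p in enumerate(mem):
            nodes.append(p, MEMBRANE, did, order=k)

    if params.decay_law == "time":
        g_new = cell.g * math.exp(-params.time_decay_rate * params.mitotic_duration)
    else:
        g_new = cell.g * params.generation_decay
    daughters = []
    for did, side in ((id_a, side_a), (id_b, side_b)):
        daughters.append(CellState(
            cell_id=did, phase=CellPhase.INTERPHASE, g=g_new,
            generation=cell.generation + 1, dpp_div_memory=-1.0,
            n_internal_birth=len(side), birth_time=sim_time,
            parent_id=cid))
    return daughters


# ---------------------------------------------------------------------------
# geometry helpers shared with metrics
# ---------------------------------------------------------------------------

def cell_polygon_area(nodes: NodeSet, cell: int) -> float:
    """Area of the membrane polygon of one cell (shoelace formula)."""
    return _polygon_area(nodes.pos[nodes.membrane_cycle(cell)])


def isoperimetric_ratio(nodes: NodeSet, cell: int) -> float:
    """4*pi*A / P^2 of the membrane polygon; 1 for a disc."""
    pts = nodes.pos[nodes.membrane_cycle(cell)]
    a = _polygon_area(pts)
    per = float(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum())
    return 4.0 * math.pi * a / (per * per)
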