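"""Morphogen reaction-diffusion network on the tissue triangle mesh.

Two modes:

* ``simplified`` — a single diffusible morphogen (Dpp) with a Hill-shaped
  midline source, linear degradation and diffusion:
  d[Dpp]/dt = D lap[Dpp] + v / (1 + (x / (r_s L))^n_s) - d [Dpp]
* ``full`` — Dpp plus its membrane receptor (Tkv), the bound complex
  (Dpp_Tkv) and the intracellular readout (pMad), with reversible binding,
  Hill activation of pMad by the complex, and negative feedback of pMad on
  Tkv synthesis.  Only Dpp diffuses.

Space is discretized on the dynamic triangular mesh; diffusion is the flux
across each contact edge, proportional to contact length A and inversely to
centroid distance l (finite volume).  Time stepping is explicit Euler, run
to a quasi-steady state defined by a relative-change criterion between
successive steps.

Two numerical dialects are exposed.  The default divides the flux sum by
the triangle area (dimensionally consistent, exactly mass-conserving); the
``literal`` dialect omits the area normalization.  Degradation of Dpp is
either ``uniform`` or ``source_modulated`` (multiplied by the same Hill
factor as production); ``auto`` picks uniform for simplified mode and
source-modulated for full mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshgen import TriMesh

__all__ = [
    "ChemParams",
    "ChemField",
    "ConvergenceError",
    "source_rate",
    "stability_dt",
    "diffusion_exchange",
    "step_simplified",
    "step_full_network",
    "apply_bc",
    "run_to_quasi_steady",
]

SPECIES = ("dpp", "tkv", "dpp_tkv", "pmad")


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChemParams:
    """Chemical-submodel parameters.  All rate defaults are this package's
    own calibration (no published table is reproduced): D and d give a decay
    length sqrt(D/d) of about 20% of the initial ~100-cell tissue
    half-width."""

    D_Dpp: float = 2.0          # diffusion coefficient (µm^2 / time)
    d_Dpp: float = 0.5          # Dpp degradation (1/time)
    v_Dpp: float = 1.0          # max Dpp production (conc/time)
    r_s: float = 0.2            # source half-width as a fraction of L(t)
    n_s: float = 4.0            # source Hill exponent
    # full-network rates
    d_Tkv: float = 1.0
    d_Dpp_Tkv: float = 1.0
    d_P: float = 1.0
    v_P: float = 1.0            # max pMad production
    v_min: float = 1.0          # min Tkv production
    v_max: float = 10.0         # max Tkv production
    k_on: float = 0.2
    k_off: float = 0.1
    k_P: float = 1.0            # pMad half-saturation of the Tkv feedback
    k_Dpp_Tkv: float = 0.5     # complex half-saturation in the pMad Hill
    n_1: float = 2.0
    n_2: float = 2.0
    pmad_hill: str = "repressive"   # "repressive" (as discretized) | "activating"
    dt_chem: float | None = None   # None -> dt_safety x the explicit stability bound
    dt_safety: float = 0.7      # fraction of the stability bound (steady state
                                # is a fixed point independent of dt)
    tol: float = 1e-4           # quasi-steady relative-change criterion
    bc: str = "absorbing"       # "absorbing" | "no_flux"
    mode: str = "simplified"    # "simplified" | "full"
    dialect: str = "default"    # flux normalization: "default" (1/area) | "literal"
    degradation: str = "auto"   # "auto" | "uniform" | "source_modulated"
    max_iter: int = 200_000

    def __post_init__(self):
        if self.bc not in ("absorbing", "no_flux"):
            raise ValueError(f"unknown bc {self.bc!r}")
        if self.mode not in ("simplified", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dialect not in ("default", "literal"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not (0 < self.r_s < 1):
            raise ValueError("r_s must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def degradation_mode(self) -> str:
        if self.degradation != "auto":
            return self.degradation
        return "uniform" if self.mode == "simplified" else "source_modulated"


@dataclass
class ChemField:
    """Per-triangle concentrations.  ``x`` is the unsigned distance of each
    triangle centroid from the AP midline (µm)."""

    dpp: np.ndarray
    tkv: np.ndarray = None
    dpp_tkv: np.ndarray = None
    pmad: np.ndarray = None
    x: np.ndarray = None

    @classmethod
    def zeros(cls, n: int, x: np.ndarray | None = None) -> "ChemField":
        return cls(dpp=np.zeros(n), tkv=np.zeros(n), dpp_tkv=np.zeros(n),
                   pmad=np.zeros(n), x=x if x is not None else np.zeros(n))

    def copy(self) -> "ChemField":
        return ChemField(*(None if a is None else a.copy()
                           for a in (self.dpp, self.tkv, self.dpp_tkv,
                                     self.pmad, self.x)))

    def species(self, mode: str):
        if mode == "simplified":
            return {"dpp": self.dpp}
        return {"dpp": self.dpp, "tkv": self.tkv,
                "dpp_tkv": self.dpp_tkv, "pmad": self.pmad}


def midline_x(mesh: TriMesh, midline: float | None = None) -> np.ndarray:
    """Unsigned distance of triangle centroids from the AP midline.  The
    midline defaults to the area-weighted x of the whole mesh."""
    cent = mesh.centroids()
    if midline is None:
        a = mesh.areas()
        midline = float(np.average(cent[:, 0], weights=a))
    return np.abs(cent[:, 0] - midline)


# ---------------------------------------------------------------------------
# elementary terms
# ---------------------------------------------------------------------------

def source_rate(x, L: float, params: ChemParams):
    """Midline production rate v / (1 + (|x| / (r_s L))^n_s)."""
    if L <= 0:
        raise ValueError("half-width L must be positive")
    x = np.abs(np.asarray(x, dtype=float))
    return params.v_Dpp / (1.0 + (x / (params.r_s * L)) ** params.n_s)


def _source_hill(x, L, params):
    x = np.abs(np.asarray(x, dtype=float))
    return 1.0 / (1.0 + (x / (params.r_s * L)) ** params.n_s)


def _fv_areas(mesh: TriMesh) -> np.ndarray:
    """Triangle areas with a mass-lumping floor (5% of the median) so that
    a rare near-degenerate sliver cannot crush the explicit time step.  On
    well-shaped meshes the floor is inactive and conservation is exact."""
    a = mesh.areas()
    if len(a) > 2:
        return np.maximum(a, 0.05 * float(np.median(a)))
    return a


def _fv_center_l(mesh: TriMesh) -> np.ndarray:
    """Centroid distances with a floor (25% of the median) so nearly
    coincident centroids of a degraded pair cannot make the explicit
    scheme arbitrarily stiff.  Inactive on well-shaped meshes."""
    l = mesh.center_l
    if len(l) > 2:
        return np.maximum(l, 0.25 * float(np.median(l)))
    return l


def stability_dt(mesh: TriMesh, params: ChemParams) -> float:
    """Explicit stability bound for the diffusion operator: per triangle the
    outflow coefficient D * sum(A/l) / V must satisfy coef * dt < 1."""
    n = mesh.n_triangles
    coef = np.zeros(n)
    if len(mesh.adjacency):
        w = params.D_Dpp * mesh.contact_A / _fv_center_l(mesh)
        np.add.at(coef, mesh.adjacency[:, 0], w)
        np.add.at(coef, mesh.adjacency[:, 1], w)
    if params.dialect == "default":
        coef /= _fv_areas(mesh)
    # reaction sinks also constrain dt; binding stiffness is bounded by the
    # largest attainable receptor level v_max / d_Tkv
    sink = params.d_Dpp
    if params.mode == "full":
        r_max = params.v_max / max(params.d_Tkv, 1e-12)
        sink = max(sink, params.d_Tkv, params.d_Dpp_Tkv, params.d_P,
                   params.k_off + params.d_Dpp_Tkv,
                   params.k_on * r_max + params.d_Dpp)
    m = max(float(coef.max(initial=0.0)), sink, 1e-12)
    return 1.0 / m


def effective_dt(mesh: TriMesh, params: ChemParams) -> float:
    return (params.dt_chem if params.dt_chem is not None
            else params.dt_safety * stability_dt(mesh, params))


def diffusion_exchange(c: np.ndarray, mesh: TriMesh, D: float, dt: float,
                       dialect: str = "default",
                       check_stability: bool = True) -> np.ndarray:
    """One explicit diffusion step of a scalar field across the mesh.

    default dialect: c_i += dt/V_i * D * sum_n A_in (c_n - c_i) / l_in
    (total mass sum(V_i c_i) is conserved exactly under no-flux).
    literal dialect omits 1/V_i.
    """
    if check_stability:
        probe = ChemParams(D_Dpp=D, d_Dpp=0.0, dialect=dialect)
        if dt > stability_dt(mesh, probe) + 1e-15:
            raise ValueError(
                f"dt={dt:g} exceeds the explicit stability bound "
                f"{stability_dt(mesh, probe):g}")
    flux = np.zeros_like(c)
    if len(mesh.adjacency):
        i, j = mesh.adjacency[:, 0], mesh.adjacency[:, 1]
        f = D * mesh.contact_A * (c[j] - c[i]) / _fv_center_l(mesh)
        np.add.at(flux, i, f)
        np.add.at(flux, j, -f)
    if dialect == "default":
        flux = flux / _fv_areas(mesh)
    return c + dt * flux


# ---------------------------------------------------------------------------
# steps
# ---------------------------------------------------------------------------

def step_simplified(field: ChemField, mesh: TriMesh, params: ChemParams,
                    L: float, dt: float) -> ChemField:
    """One explicit step of the single-morphogen model."""
    hill = _source_hill(field.x, L, params)
    deg = params.d_Dpp * (hill if params.degradation_mode() == "source_modulated"
                          else 1.0)
    c = diffusion_exchange(field.dpp, mesh, params.D_Dpp, dt,
                           params.dialect, check_stability=False)
    c = c + dt * (params.v_Dpp * hill - deg * field.dpp)
    out = field.copy()
    out.dpp = np.maximum(c, 0.0)
    return out


def step_full_network(field: ChemField, mesh: TriMesh, params: ChemParams,
                      L: float, dt: float) -> ChemField:
    """One explicit step of the Dpp / Tkv / Dpp_Tkv / pMad network.

    Only Dpp diffuses.  Dpp: diffusion + Hill source - degradation -
    binding + unbinding.  Tkv: feedback-limited production - degradation -
    binding + unbinding.  Complex: binding - unbinding - degradation.
    pMad: Hill activation by the complex - degradation.  Negative
    concentrations produced by explicit overshoot are clipped to zero.
    """
    M, R, MR, S = field.dpp, field.tkv, field.dpp_tkv, field.pmad
    hill = _source_hill(field.x, L, params)
    deg_M = params.d_Dpp * (hill if params.degradation_mode() == "source_modulated"
                            else 1.0)
    bind = params.k_on * M * R
    unbind = params.k_off * MR

    dM = diffusion_exchange(M, mesh, params.D_Dpp, dt, params.dialect,
                            check_stability=False) - M
    dM += dt * (params.v_Dpp * hill - deg_M * M - bind + unbind)
    tkv_prod = params.v_min + (params.v_max - params.v_min) / (
        1.0 + (S / params.k_P) ** params.n_1)
    dR = dt * (tkv_prod - params.d_Tkv * R - bind + unbind)
    dMR = dt * (bind - unbind - params.d_Dpp_Tkv * MR)
    hill_mr = (MR / params.k_Dpp_Tkv) ** params.n_2
    if params.pmad_hill == "activating":
        pmad_prod = params.v_P * hill_mr / (1.0 + hill_mr)
    else:
        pmad_prod = params.v_P / (1.0 + hill_mr)
    dS = dt * (pmad_prod - params.d_P * S)

    out = field.copy()
    out.dpp = np.maximum(M + dM, 0.0)
    out.tkv = np.maximum(R + dR, 0.0)
    out.dpp_tkv = np.maximum(MR + dMR, 0.0)
    out.pmad = np.maximum(S + dS, 0.0)
    return out


def apply_bc(field: ChemField, mesh: TriMesh, bc: str) -> ChemField:
    """Absorbing: pin Dpp to zero on boundary triangles.  No-flux: no
    action (the finite-volume scheme has zero flux across boundary edges)."""
    if bc == "absorbing":
        field.dpp[mesh.boundary_tri] = 0.0
    return field


def run_to_quasi_steady(field: ChemField, mesh: TriMesh, params: ChemParams,
                        L: float):
    """Iterate explicit steps until, for every triangle and species,
    |c_new - c_old| / (c_old * dt) < tol.  Triangles with c_old below 1e-12
    use the absolute difference instead.  Returns (field, iterations)."""
    dt = effective_dt(mesh, params)
    step = step_simplified if params.mode == "simplified" else step_full_network
    f = field.copy()
    apply_bc(f, mesh, params.bc)
    for it in range(1, params.max_iter + 1):
        g = step(f, mesh, params, L, dt)
        apply_bc(g, mesh, params.bc)
        worst = 0.0
        for name, old in f.species(params.mode).items():
            new = g.species(params.mode)[name]
            # guard against division by (near-)zero: concentrations below a
            # floor tied to the field scale use the absolute difference
            floor = max(1e-12, 1e-8 * float(old.max(initial=0.0)))
            denom = np.where(old > floor, old * dt, 1.0)
            rel = np.abs(new - old) / denom
            worst = max(worst, float(rel.max(initial=0.0)))
        f = g
        if worst < params.tol:
            return f, it
    raise ConvergenceError(
        f"quasi-steady iteration cap {params.max_iter} reached; "
        f"residual {worst:.3g} (tol {params.tol:g})")
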