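"""Interstitial fluid flow: Darcy/Brinkman pressure problem with Starling exchange.

The interstitial fluid pressure ``p_i`` satisfies, quasi-steadily,

    div(u) = Q_m,      u = -k_eff grad(p_i),
    Q_m = L_p S_v (p_v - p_i) - L_pl S_vl (p_i - p_l),

with ``k_eff = (1/k + Q_m / eps_p^2)**-1`` the Darcy drag corrected by the
momentum sink that the transvascular exchange exerts on the fluid.  At
tissue permeabilities the Brinkman shear term has a screening length of
order 1e-8 m -- four orders of magnitude below the mesh size -- so the
primal pressure formulation above is the whole story; see docs/methods.md.
The weak mass-sink coupling makes ``k_eff`` depend on the solution, which
is resolved by Picard (fixed-point) iteration on the pressure field.

Boundary conditions: prescribed normal inflow velocity ``U_0`` on the
catheter tip while the pump runs (``U_0 = Q_f / (pi r_c^2)``), no-flow on
the catheter wall and the symmetry axis, and zero pressure (zero normal
stress) on the outer surface.

``analytic_radial_ifp`` provides the classical closed-form pressure
profile of an isolated uniformly leaky sphere, used as the verification
oracle for the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse.linalg as spla

from . import geometry as geo
from .fem import BoundaryGroup, P1Basis, apply_dirichlet
from .geometry import Mesh

__all__ = [
    "RegionProperties",
    "FlowField",
    "starling_source",
    "inlet_velocity",
    "solve_flow",
    "analytic_radial_ifp",
    "default_region_properties",
]


@dataclass(frozen=True)
class RegionProperties:
    """Per-region physiological parameters (SI units).

    k : interstitial hydraulic conductivity, m^2/(Pa s)
    epsilon_p : porosity (0, 1)
    mu_i, rho : interstitial fluid viscosity (Pa s) and density (kg/m^3)
    Lp_Sv : vascular filtration coefficient L_p * S_v, 1/(Pa s)
    p_v : vascular pressure, Pa
    Lpl_Svl, p_l : lymphatic filtration coefficient and pressure
    S_v : vascular density, 1/m
    k_d, k_l : drug degradation and lymphatic drainage rates, 1/s
    """

    k: float
    epsilon_p: float
    Lp_Sv: float
    p_v: float
    S_v: float
    mu_i: float = 1.0e-3
    rho: float = 1000.0
    Lpl_Svl: float = 0.0
    p_l: float = 0.0
    k_d: float = 0.0
    k_l: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0 or not (0.0 < self.epsilon_p < 1.0) or self.mu_i <= 0 or self.rho <= 0:
            raise ValueError("k, mu_i, rho must be positive and 0 < epsilon_p < 1")
        if min(self.Lp_Sv, self.Lpl_Svl, self.S_v, self.k_d, self.k_l) < 0:
            raise ValueError("rate and filtration coefficients must be non-negative")


def default_region_properties(tumor_k: float = 2.0e-13, tumor_Lp: float = 6.25e-11) -> dict[str, RegionProperties]:
    """Literature-typical defaults; tumor lymphatics are dysfunctional (zero).

    The tumor filtration coefficient comes from pore theory (leaky tumor
    vessels); the healthy region models brain parenchyma with an intact
    blood-brain barrier, whose bulk water filtration is orders of
    magnitude below that of tumor vessels, and a white-matter-like
    interstitial conductivity so that fluid leaking from the high-pressure
    tumor rim percolates through the parenchyma at the 1e-7 to 1e-6 m/s
    interstitial velocities reported for brain tissue.
    """
    return {
        "tumor": RegionProperties(
            k=tumor_k, epsilon_p=0.3, Lp_Sv=tumor_Lp * 2.0e4, p_v=3330.0, S_v=2.0e4,
            Lpl_Svl=0.0, p_l=0.0, k_l=0.0,
        ),
        "healthy": RegionProperties(
            k=2.0e-12, epsilon_p=0.2, Lp_Sv=5.0e-10, p_v=2080.0, S_v=7.0e3,
            Lpl_Svl=2.0e-9, p_l=0.0, k_l=1.0e-4,
        ),
    }


@dataclass
class FlowField:
    """Converged interstitial flow state on a mesh."""

    p: np.ndarray  # nodal pressure, Pa
    u: np.ndarray  # per-cell Darcy velocity, m/s
    Qm: np.ndarray  # per-cell transvascular fluid source, 1/s
    balance: dict  # global fluid balance audit

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)


def cell_property(
    mesh: Mesh,
    props: dict[str, RegionProperties],
    expr,
    harmonic: bool = False,
) -> np.ndarray:
    """Per-cell coefficient blended by the tumor volume fraction.

    ``expr`` maps a RegionProperties to a scalar.  Cells cut by the tumor
    boundary get volume-fraction homogenized values: arithmetic by default
    (reaction/source coefficients), harmonic for the hydraulic
    conductivity, where transport across the interface is in series.
    """
    for name in geo.REGION_NAMES.values():
        if name not in props:
            raise KeyError(f"missing properties for region {name!r}")
    vt = float(expr(props["tumor"]))
    vh = float(expr(props["healthy"]))
    f = mesh.tumor_fraction
    if harmonic:
        if vt <= 0 or vh <= 0:
            raise ValueError("harmonic blending requires positive values")
        return 1.0 / (f / vt + (1.0 - f) / vh)
    return f * vt + (1.0 - f) * vh


def starling_source(p_cell: np.ndarray, mesh: Mesh, props: dict[str, RegionProperties]) -> np.ndarray:
    """Transvascular fluid source Q_m per cell from per-cell pressures (1/s)."""
    LpSv = cell_property(mesh, props, lambda r: r.Lp_Sv)
    LplSvl = cell_property(mesh, props, lambda r: r.Lpl_Svl)
    vasc = cell_property(mesh, props, lambda r: r.Lp_Sv * r.p_v)
    lymph = cell_property(mesh, props, lambda r: r.Lpl_Svl * r.p_l)
    return vasc - LpSv * p_cell - (LplSvl * p_cell - lymph)


def inlet_velocity(Q_f: float, catheter_radius: float) -> float:
    """Normal inlet velocity U_0 = Q_f / (pi r^2) at the catheter tip (m/s)."""
    if Q_f < 0:
        raise ValueError("Q_f must be non-negative")
    if catheter_radius <= 0:
        raise ValueError("catheter_radius must be positive")
    return Q_f / (np.pi * catheter_radius**2)


def solve_flow(
    mesh: Mesh,
    props: dict[str, RegionProperties],
    infusion_on: bool,
    U_0: float = 0.0,
    tol: float = 1.0e-6,
    max_iter: int = 50,
    basis: P1Basis | None = None,
) -> FlowField:
    """Solve the quasi-steady interstitial flow problem on ``mesh``.

    Picard iteration updates the drag coefficient (1/k + Q_m/eps_p^2)
    until the relative pressure change drops below ``tol``.
    """
    if U_0 < 0:
        raise ValueError("U_0 must be non-negative")
    basis = basis or P1Basis(mesh)
    n = mesh.n_points

    k_cell = cell_property(mesh, props, lambda r: r.k, harmonic=True)
    eps_cell = cell_property(mesh, props, lambda r: r.epsilon_p)
    LpSv = cell_property(mesh, props, lambda r: r.Lp_Sv)
    LplSvl = cell_property(mesh, props, lambda r: r.Lpl_Svl)
    vasc_src = cell_property(mesh, props, lambda r: r.Lp_Sv * r.p_v)
    lymph_src = cell_property(mesh, props, lambda r: r.Lpl_Svl * r.p_l)

    tip = BoundaryGroup(mesh, geo.TAG_TIP, basis)
    outer_nodes = np.unique(mesh.facets_by_tag(geo.TAG_OUTER))
    if len(outer_nodes) == 0:
        raise RuntimeError("mesh has no outer boundary to anchor the pressure")

    f_neumann = tip.load_vector(n, U_0) if infusion_on else np.zeros(n)
    # reaction (Starling) terms, lumped
    react = basis.lumped_mass(LpSv + LplSvl)
    source = basis.lumped_mass(vasc_src + lymph_src)

    p = np.zeros(n)
    Qm_cell = np.zeros(len(mesh.cells))
    history: list[float] = []
    for _ in range(max_iter):
        k_eff = 1.0 / (1.0 / k_cell + Qm_cell / eps_cell**2)
        if np.any(k_eff <= 0):
            raise RuntimeError("transvascular momentum sink produced non-positive drag")
        K = basis.stiffness(k_eff)
        A = K + _diag(react)
        b = source + f_neumann
        A_bc, b_bc = apply_dirichlet(A, b, outer_nodes, 0.0)
        if mesh.dim == 3:
            # SPD system: Jacobi-preconditioned CG scales to 3D meshes
            M = _diag(1.0 / A_bc.diagonal())
            p_new, info = spla.cg(A_bc, b_bc, x0=p, M=M, rtol=1e-10, atol=0.0, maxiter=5000)
            if info != 0:
                raise RuntimeError(f"CG did not converge (info={info})")
        else:
            p_new = spla.spsolve(A_bc.tocsc(), b_bc)
        denom = max(np.linalg.norm(p_new), 1e-300)
        change = np.linalg.norm(p_new - p) / denom
        history.append(change)
        p = p_new
        p_cell = p[mesh.cells].mean(axis=1)
        Qm_cell = vasc_src + lymph_src - (LpSv + LplSvl) * p_cell
        if change < tol:
            break
    else:
        raise RuntimeError(f"flow Picard iteration did not converge; history={history}")

    grads = np.einsum("eid,ei->ed", basis.grads, p[mesh.cells])
    u_cell = -k_eff[:, None] * grads

    # fluid balance: inflow + int Qm dV = outflow through the outer surface.
    # Outflow is measured from the Dirichlet reaction of the unconstrained
    # system, which is the discretely exact flux.
    scale = 2.0 * np.pi if mesh.dim == 2 else 1.0
    inflow = scale * float(U_0 * tip.total_weight) if infusion_on else 0.0
    residual_vec = A.dot(p) - b
    outflow = -scale * float(residual_vec[outer_nodes].sum())
    Qm_total = scale * float((source - react * p).sum())
    balance = {
        "inflow": inflow,
        "transvascular": Qm_total,
        "outer_outflow": outflow,
        "residual": inflow + Qm_total - outflow,
        "picard_iterations": len(history),
        "picard_history": history,
    }
    return FlowField(p=p, u=u_cell, Qm=Qm_cell, balance=balance)


def _diag(d: np.ndarray):
    import scipy.sparse as sp

    return sp.diags(d)


def analytic_radial_ifp(
    r: np.ndarray | float,
    tumor_radius: float,
    k: float,
    LpSv: float,
    p_v: float,
) -> np.ndarray:
    """Steady IFP of an isolated leaky sphere with zero edge pressure.

    p_i(r) = p_v [1 - (R/r) sinh(alpha r / R) / sinh(alpha)],
    alpha = R sqrt(L_p S_v / k), valid for r <= R; the r -> 0 limit is
    p_v [1 - alpha / sinh(alpha)].
    """
    if min(tumor_radius, k, LpSv) <= 0:
        raise ValueError("tumor_radius, k, LpSv must be positive")
    r = np.asarray(r, dtype=float)
    alpha = tumor_radius * np.sqrt(LpSv / k)
    out = np.empty_like(r)
    small = r < 1e-12 * tumor_radius
    x = np.where(small, 1.0, r / tumor_radius)
    out = p_v * (1.0 - np.sinh(alpha * x) / (x * np.sinh(alpha)))
    out = np.where(small, p_v * (1.0 - alpha / np.sinh(alpha)), out)
    return out
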