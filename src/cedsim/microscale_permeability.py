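"""Unit-cell permeability of aligned fibre bundles.

White-matter axons are idealized as parallel rigid cylinders of radius
r = 0.34 um on a triangular lattice; the extracellular space between them is
the fluid domain. Varying the centre-to-centre spacing sweeps the
extracellular volume fraction VF_ECS, and for each geometry the axial and
transverse permeabilities follow from creeping-flow solutions and Darcy's
law k = v_mean * mu * L / dp.

Numerics
--------
* Axial flow (along the fibres) is fully developed unidirectional Stokes
  flow, which reduces exactly to a 2-D Poisson problem for the axial
  velocity on the cell cross-section:  mu * lap(w) = -G, w = 0 on fibre
  walls. It is solved on the quarter cell with symmetry (Neumann) sides.
* Transverse flow is 2-D Stokes flow across the lattice, driven by a body
  force equivalent to the mean pressure gradient, on the periodic half cell
  with symmetry planes at y = 0 and y = sqrt(3) a / 2 (a MAC staggered
  grid). In fully periodic creeping flow this is identical to imposing a
  pressure drop across a long strip of cells, without entrance effects.
* Fibre walls are treated sharply in both solvers: finite-difference
  stencils next to a wall are shortened to the exact wall distance along
  each grid line (Shortley-Weller), which keeps the narrow inter-fibre gaps
  accurate at moderate resolution.

Both solvers work in units of the lattice pitch ``a`` with unit viscosity
and unit pressure gradient; creeping flow is linear, so the dimensional
velocity scales exactly by G a^2 / mu.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import least_squares

from .tissue_model import (KUWABARA_COEFFS, TAMAYOL_BAHRAMI_COEFFS,
                           _kuwabara_bracket, _tb_bracket)

__all__ = [
    "UnitCell",
    "FlowSolution",
    "build_unit_cell",
    "solve_axial_flow",
    "solve_transverse_flow",
    "permeability_from_darcy",
    "permeability_sweep",
    "fit_permeability_law",
    "PermeabilityLawFit",
    "DEFAULT_VF_SAMPLING",
    "VF_ECS_MIN",
]

#: Densest possible packing: touching fibres, vf_ecs = 1 - pi/(2 sqrt(3)).
VF_ECS_MIN = 1.0 - math.pi / (2.0 * math.sqrt(3.0))

#: Default VF_ECS sweep: denser below 0.40, the physiological range.
DEFAULT_VF_SAMPLING = (0.15, 0.175, 0.20, 0.225, 0.25, 0.30,
                       0.35, 0.40, 0.50, 0.60, 0.70, 0.80)

_SQRT3 = math.sqrt(3.0)


@dataclasses.dataclass
class UnitCell:
    """Triangular-lattice unit cell of the fibre bundle.

    ``a`` is the centre-to-centre spacing; the periodic rectangular cell
    a x sqrt(3) a holds two fibres, so the realized extracellular fraction
    is 1 - 2 pi r^2 / (sqrt(3) a^2).
    """

    r: float
    a: float
    vf_ecs_target: float
    resolution: int

    @property
    def vf_ecs(self) -> float:
        """Realized extracellular fraction of the continuous geometry."""
        return 1.0 - 2.0 * math.pi * self.r ** 2 / (_SQRT3 * self.a ** 2)

    @property
    def gap(self) -> float:
        """Smallest wall-to-wall distance between neighbouring fibres."""
        return self.a - 2.0 * self.r


def build_unit_cell(vf_ecs: float, r: float = 0.34e-6,
                    resolution: int | None = None) -> UnitCell:
    """Unit cell at a prescribed extracellular fraction.

    The spacing follows from inverting the packing formula:
    a = r sqrt(2 pi / (sqrt(3) (1 - vf_ecs))). The default grid resolution
    (cells across one pitch) is chosen so the inter-fibre gap is resolved by
    at least ~10 cells, within [160, 352].
    """
    if not VF_ECS_MIN < vf_ecs < 1.0:
        raise ValueError(
            f"vf_ecs={vf_ecs} infeasible for a triangular lattice; the "
            f"geometric range is ({VF_ECS_MIN:.4f}, 1)"
        )
    if r <= 0:
        raise ValueError("fibre radius must be positive")
    a = r * math.sqrt(2.0 * math.pi / (_SQRT3 * (1.0 - vf_ecs)))
    if resolution is None:
        gap_frac = (a - 2.0 * r) / a
        resolution = int(np.clip(math.ceil(10.0 / gap_frac), 160, 352))
    cell = UnitCell(r=r, a=a, vf_ecs_target=vf_ecs, resolution=int(resolution))
    assert abs(cell.vf_ecs - vf_ecs) < 1.0e-6
    return cell


@dataclasses.dataclass
class FlowSolution:
    """Creeping-flow solution through a unit cell.

    ``v_mean`` is the superficial mean velocity (averaged over the whole
    cell, fibres included); ``dp`` acts over length ``length`` along the
    flow. ``velocity`` is the main dimensionless velocity component on the
    solver grid (zero inside fibres), kept for inspection and symmetry
    tests; ``discrete_vf_ecs`` is the fluid fraction seen by the grid.
    """

    dp: float
    length: float
    mu: float
    v_mean: float
    velocity: np.ndarray
    fluid_fraction: float
    cell: UnitCell | None = None

    @property
    def discrete_vf_ecs(self) -> float:
        return self.fluid_fraction


def permeability_from_darcy(sol: FlowSolution) -> float:
    """Darcy's law: k = v_mean * mu * L / dp (m^2)."""
    return sol.v_mean * sol.mu * sol.length / sol.dp


# ---------------------------------------------------------------------------
# shared finite-difference machinery

def _neighbor(a: np.ndarray, axis: int, side: int, mode: str,
              fill=0.0) -> np.ndarray:
    """Neighbour values one step along ``axis`` with a boundary rule.

    mode: 'periodic' wraps; 'mirror_vertex' reflects about a boundary node
    (ghost = second node in); 'mirror_face' reflects about a boundary lying
    half a step outside (ghost = the node itself); 'zero' marks a known
    zero-valued boundary neighbour by inserting ``fill`` at the edge.
    """
    a0 = np.moveaxis(a, axis, 0)
    nb = np.empty_like(a0)
    if side == 1:
        nb[:-1] = a0[1:]
        edge = {"periodic": a0[0], "mirror_vertex": a0[-2],
                "mirror_face": a0[-1], "zero": fill}[mode]
        nb[-1] = edge
    else:
        nb[1:] = a0[:-1]
        edge = {"periodic": a0[-1], "mirror_vertex": a0[1],
                "mirror_face": a0[0], "zero": fill}[mode]
        nb[0] = edge
    return np.moveaxis(nb, 0, axis)


def _sw_laplacian(phi: np.ndarray, idx: np.ndarray, fluid: np.ndarray,
                  steps, modes, theta_min: float = 0.02):
    """Shortley-Weller 5-point Laplacian entries on an embedded geometry.

    For a fluid node with a solid neighbour, the stencil arm is shortened to
    the wall crossing (located by linear interpolation of the signed
    distance ``phi``) where the velocity is zero. Returns COO-style
    (rows, cols, vals) for the off-diagonal entries and the diagonal of -lap.

    ``steps`` is (hx, hy); ``modes`` gives the boundary rule per (axis, side),
    where the rule 'zero' means a known zero-valued neighbour one full step
    away (a no-slip/no-normal-flow line on the grid boundary).
    """
    diag = np.zeros(phi.shape)
    rows, cols, vals = [], [], []
    for axis in (0, 1):
        h = steps[axis]
        arm = {}
        for side in (-1, 1):
            mode = modes[(axis, side)]
            # 'zero': the boundary neighbour is a known zero value one full
            # step away -> treat as fluid (inf) with no matrix entry (-1)
            phi_nb = _neighbor(phi, axis, side, mode, fill=np.inf)
            idx_nb = _neighbor(idx, axis, side, mode, fill=-1)
            solid_nb = phi_nb <= 0
            with np.errstate(divide="ignore", invalid="ignore"):
                theta = phi / (phi - phi_nb)
            theta = np.where(solid_nb, theta, 1.0)
            theta = np.clip(np.nan_to_num(theta, nan=1.0), theta_min, 1.0)
            arm[side] = (theta * h, solid_nb, idx_nb)
        h1, solid1, idx1 = arm[-1]
        h2, solid2, idx2 = arm[1]
        diag += 2.0 / (h1 * h2)
        for hs, solid_nb, idx_nb in ((h1, solid1, idx1), (h2, solid2, idx2)):
            coef = 2.0 / (hs * (h1 + h2))
            use = fluid & ~solid_nb & (idx_nb >= 0)
            rows.append(idx[use])
            cols.append(idx_nb[use])
            vals.append(-coef[use])
    return rows, cols, vals, diag


# ---------------------------------------------------------------------------
# axial flow: Poisson on the quarter cell

def solve_poisson_axial(sdf, Lx: float, Ly: float, nx: int,
                        theta_min: float = 0.02):
    """Solve -lap(w) = 1 on {sdf > 0} in [0,Lx]x[0,Ly], w = 0 on sdf = 0.

    Rectangle edges are symmetry (Neumann) lines; the embedded boundary is
    handled with Shortley-Weller stencils. Returns (w, superficial_mean,
    fluid_fraction); ``w`` is vertex-centred, zero in the solid.

    This is the building block of :func:`solve_axial_flow` and doubles as
    an oracle hook: with a parallel-plate ``sdf`` the superficial mean over
    the channel is gap^2 / 12.
    """
    ny = max(int(round(Ly / (Lx / nx))), 2)
    hx, hy = Lx / nx, Ly / ny
    X, Y = np.meshgrid(np.linspace(0.0, Lx, nx + 1),
                       np.linspace(0.0, Ly, ny + 1), indexing="ij")
    phi = np.asarray(sdf(X, Y), dtype=float)
    fluid = phi > 0
    idx = np.arange(phi.size).reshape(phi.shape)

    modes = {(0, -1): "mirror_vertex", (0, 1): "mirror_vertex",
             (1, -1): "mirror_vertex", (1, 1): "mirror_vertex"}
    rows, cols, vals, diag = _sw_laplacian(phi, idx, fluid, (hx, hy), modes,
                                           theta_min)
    rows.append(idx[fluid]); cols.append(idx[fluid]); vals.append(diag[fluid])
    rows.append(idx[~fluid]); cols.append(idx[~fluid])
    vals.append(np.ones(int((~fluid).sum())))

    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(phi.size, phi.size))
    b = np.where(fluid, 1.0, 0.0).ravel()
    w = spla.spsolve(A.tocsc(), b).reshape(phi.shape)
    w = np.where(fluid, w, 0.0)

    wt_x = np.ones(nx + 1); wt_x[[0, -1]] = 0.5
    wt_y = np.ones(ny + 1); wt_y[[0, -1]] = 0.5
    wts = wt_x[:, None] * wt_y[None, :]
    mean_w = float((w * wts).sum() / wts.sum())
    fluid_frac = float((fluid * wts).sum() / wts.sum())
    return w, mean_w, fluid_frac


def _lattice_sdf(rho: float):
    """Signed distance to the fibre walls, in units of the pitch a.

    Fibre centres: the rows y = 0 (x integer) and y = sqrt(3)/2
    (x half-integer), periodic in x with period 1.
    """
    def sdf(x, y):
        d = np.full(np.broadcast(x, y).shape, np.inf)
        for cy, xoff in ((0.0, 0.0), (_SQRT3 / 2.0, 0.5), (_SQRT3, 0.0),
                         (-_SQRT3 / 2.0, 0.5)):
            dx = np.abs(((x - xoff + 0.5) % 1.0) - 0.5)
            d = np.minimum(d, np.hypot(dx, y - cy))
        return d - rho
    return sdf


def solve_axial_flow(cell: UnitCell, dp: float = 5.0,
                     length: float = 0.15e-6, mu: float = 1.0e-3,
                     resolution: int | None = None) -> FlowSolution:
    """Fully developed creeping flow along the fibres.

    ``dp`` over ``length`` sets the axial pressure gradient (defaults: 5 Pa
    over 0.15 um). The permeability extracted through Darcy's law is
    independent of both, and of mu, as it must be for creeping flow.
    """
    n = resolution or cell.resolution
    rho = cell.r / cell.a
    # quarter cell [0, 1/2] x [0, sqrt(3)/2] in units of a
    w, mean_w, frac = solve_poisson_axial(_lattice_sdf(rho), 0.5, _SQRT3 / 2.0,
                                          max(n // 2, 40))
    G = dp / length
    v_mean = mean_w * G * cell.a ** 2 / mu
    return FlowSolution(dp=dp, length=length, mu=mu, v_mean=v_mean,
                        velocity=w, fluid_fraction=frac, cell=cell)


# ---------------------------------------------------------------------------
# transverse flow: Stokes on the periodic half cell (MAC grid)

def _solve_stokes_transverse(rho: float, nx: int, theta_min: float = 0.02,
                             sdf=None, forcing=None):
    """Body-force-driven Stokes flow across the lattice, dimensionless.

    Domain [0,1] x [0, sqrt(3)/2] in units of a, periodic in x, symmetry
    (free-slip) lines at y = 0 and y = sqrt(3)/2; unit force along x, unit
    viscosity. Returns (u, mean_u, fluid_fraction) with ``u`` on the MAC
    u-grid; the dimensionless permeability is mean_u (in units of a^2).
    """
    Ly = _SQRT3 / 2.0
    hx = 1.0 / nx
    ny = max(int(round(Ly / hx)), 4)
    hy = Ly / ny
    if sdf is None:
        sdf = _lattice_sdf(rho)

    xu = np.arange(nx) * hx
    yu = (np.arange(ny) + 0.5) * hy
    xv = (np.arange(nx) + 0.5) * hx
    yv = np.arange(1, ny) * hy
    xp = (np.arange(nx) + 0.5) * hx
    yp = (np.arange(ny) + 0.5) * hy

    phi_u = sdf(*np.meshgrid(xu, yu, indexing="ij"))
    phi_v = sdf(*np.meshgrid(xv, yv, indexing="ij"))
    phi_p = sdf(*np.meshgrid(xp, yp, indexing="ij"))

    p_fluid = phi_p > 0
    # a velocity node is active only if it separates two fluid pressure cells
    u_fluid = (phi_u > 0) & p_fluid & np.roll(p_fluid, 1, axis=0)
    v_fluid = (phi_v > 0) & p_fluid[:, 1:] & p_fluid[:, :-1]

    nu, nv, npr = phi_u.size, phi_v.size, phi_p.size
    iu = np.arange(nu).reshape(phi_u.shape)
    iv = (nu + np.arange(nv)).reshape(phi_v.shape)
    ip = (nu + nv + np.arange(npr)).reshape(phi_p.shape)
    N = nu + nv + npr

    rows, cols, vals = [], [], []

    def add(r, c, v):
        r = np.asarray(r).ravel()
        rows.append(r)
        cols.append(np.asarray(c).ravel())
        vals.append(np.broadcast_to(np.asarray(v, dtype=float), r.shape).ravel())

    # --- u momentum: -lap(u) + dp/dx = 1
    modes_u = {(0, -1): "periodic", (0, 1): "periodic",
               (1, -1): "mirror_face", (1, 1): "mirror_face"}
    r_, c_, v_, diag_u = _sw_laplacian(phi_u, iu, u_fluid, (hx, hy), modes_u,
                                       theta_min)
    rows += r_; cols += c_; vals += v_
    add(iu[u_fluid], iu[u_fluid], diag_u[u_fluid])
    # pressure gradient (p[i] - p[i-1]) / hx at u node i
    add(iu[u_fluid], ip[u_fluid], 1.0 / hx)
    ip_w = np.roll(ip, 1, axis=0)
    add(iu[u_fluid], ip_w[u_fluid], -1.0 / hx)
    add(iu[~u_fluid], iu[~u_fluid], np.ones(int((~u_fluid).sum())))

    # --- v momentum: -lap(v) + dp/dy = 0  (v = 0 on the symmetry lines)
    modes_v = {(0, -1): "periodic", (0, 1): "periodic",
               (1, -1): "zero", (1, 1): "zero"}
    r_, c_, v_, diag_v = _sw_laplacian(phi_v, iv, v_fluid, (hx, hy), modes_v,
                                       theta_min)
    rows += r_; cols += c_; vals += v_
    add(iv[v_fluid], iv[v_fluid], diag_v[v_fluid])
    add(iv[v_fluid], ip[:, 1:][v_fluid], 1.0 / hy)
    add(iv[v_fluid], ip[:, :-1][v_fluid], -1.0 / hy)
    add(iv[~v_fluid], iv[~v_fluid], np.ones(int((~v_fluid).sum())))

    # --- continuity at fluid pressure cells
    iu_e = np.roll(iu, -1, axis=0)          # u at the east face of cell i
    ue_fluid = np.roll(u_fluid, -1, axis=0)
    m = p_fluid & ue_fluid
    add(ip[m], iu_e[m], 1.0 / hx)
    m = p_fluid & u_fluid
    add(ip[m], iu[m], -1.0 / hx)
    # north/south faces: v rows j=1..ny-1 sit between p cells j-1 and j
    vn_fluid = np.zeros_like(p_fluid); vn_fluid[:, :-1] = v_fluid
    iv_n = np.zeros_like(ip); iv_n[:, :-1] = iv
    m = p_fluid & vn_fluid
    add(ip[m], iv_n[m], 1.0 / hy)
    vs_fluid = np.zeros_like(p_fluid); vs_fluid[:, 1:] = v_fluid
    iv_s = np.zeros_like(ip); iv_s[:, 1:] = iv
    m = p_fluid & vs_fluid
    add(ip[m], iv_s[m], -1.0 / hy)
    add(ip[~p_fluid], ip[~p_fluid], np.ones(int((~p_fluid).sum())))

    A = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(N, N)).tocsr()
    # fix the pressure gauge: overwrite one continuity row with p = 0
    gauge = int(ip[p_fluid][0])
    A = A.tolil()
    A.rows[gauge] = [gauge]
    A.data[gauge] = [1.0]
    A = A.tocsc()

    b = np.zeros(N)
    if forcing is None:
        b[iu[u_fluid]] = 1.0
    else:
        fx, fy = forcing
        bx = fx(*np.meshgrid(xu, yu, indexing="ij"))
        by = fy(*np.meshgrid(xv, yv, indexing="ij"))
        b[iu[u_fluid]] = bx[u_fluid]
        b[iv[v_fluid]] = by[v_fluid]
    sol = spla.splu(A).solve(b)
    u = np.where(u_fluid, sol[:nu].reshape(phi_u.shape), 0.0)
    mean_u = float(u.mean())
    fluid_frac = float(p_fluid.mean())
    return u, mean_u, fluid_frac


def solve_transverse_flow(cell: UnitCell, dp: float = 5.0,
                          length: float | None = None, mu: float = 1.0e-3,
                          resolution: int | None = None) -> FlowSolution:
    """Creeping flow perpendicular to the fibres.

    ``dp`` over ``length`` (default: one lattice pitch) sets the mean
    transverse pressure gradient; in the periodic creeping regime the
    extracted permeability is independent of both and of mu.
    """
    n = resolution or cell.resolution
    rho = cell.r / cell.a
    u, mean_u, frac = _solve_stokes_transverse(rho, n)
    length = cell.a if length is None else length
    G = dp / length
    v_mean = mean_u * G * cell.a ** 2 / mu
    return FlowSolution(dp=dp, length=length, mu=mu, v_mean=v_mean,
                        velocity=u, fluid_fraction=frac, cell=cell)


# ---------------------------------------------------------------------------
# sweep + law fitting

def permeability_sweep(vf_values=DEFAULT_VF_SAMPLING, r: float = 0.34e-6,
                       dp: float = 5.0, mu: float = 1.0e-3,
                       resolution: int | None = None) -> pd.DataFrame:
    """Simulated (vf_ecs, k_parallel, k_perpendicular) over a VF_ECS sweep."""
    records = []
    for vf in vf_values:
        cell = build_unit_cell(vf, r, resolution)
        ax = solve_axial_flow(cell, dp=dp, mu=mu)
        tr = solve_transverse_flow(cell, dp=dp, mu=mu)
        records.append({"vf_ecs": vf,
                        "spacing": cell.a,
                        "resolution": cell.resolution,
                        "k_parallel": permeability_from_darcy(ax),
                        "k_perpendicular": permeability_from_darcy(tr)})
    return pd.DataFrame.from_records(records)


_FORMS = {
    "tamayol_bahrami": {
        "names": ("leading", "const", "log", "lin", "quad", "quart"),
        "bracket": _tb_bracket,
        "printed": TAMAYOL_BAHRAMI_COEFFS,
    },
    "kuwabara": {
        "names": ("leading", "const", "log", "lin", "quad"),
        "bracket": _kuwabara_bracket,
        "printed": KUWABARA_COEFFS,
    },
}


@dataclasses.dataclass
class PermeabilityLawFit:
    """Result of fitting a closed-form permeability law to sweep data."""

    form: str
    coefficients: tuple
    free: tuple
    rms_log_residual: float
    residuals: np.ndarray
    n_points: int
    excluded_vf: tuple

    def evaluate(self, vf_ecs, r: float) -> np.ndarray:
        spec = _FORMS[self.form]
        phi = 1.0 - np.asarray(vf_ecs, dtype=float)
        c = self.coefficients
        return r ** 2 / (c[0] * phi) * spec["bracket"](phi, c)


def fit_permeability_law(points, form: str, free_coeffs=("leading",),
                         r: float = 0.34e-6, init=None,
                         coeff_precision: float | None = 0.01) -> PermeabilityLawFit:
    """Least-squares fit of a permeability-law functional form.

    ``points`` is a sequence of (vf_ecs, k) pairs (or a DataFrame with
    ``vf_ecs`` and a ``k_*`` column). The fit minimizes residuals of
    log-permeability, since k spans orders of magnitude across the sweep.
    Any subset of coefficients may be fitted, the rest staying fixed (by
    default at the tabulated refit values): the leading denominator
    coefficient and the bracket coefficients share an overall scale, so at
    least one of them must be held fixed — freeing all of them is
    rank-deficient and raises.

    Both functional forms evaluate a bracket that is a small difference of
    O(1) terms at low VF_ECS, where it crosses zero. When the bracket
    coefficients are held fixed, sweep points where the fixed bracket is
    smaller than its own rounding uncertainty — the tabulated coefficients
    carry two decimals, so each contributes up to ``coeff_precision / 2``
    times its basis term — are excluded and reported in ``excluded_vf``:
    there the model value is rounding noise and would dominate the fit with
    meaningless residuals. Pass ``coeff_precision=None`` to exclude only
    non-positive brackets.
    """
    spec = _FORMS[form]
    names = spec["names"]
    if isinstance(points, pd.DataFrame):
        kcol = [c for c in points.columns if c.startswith("k_")][0]
        pts = list(zip(points["vf_ecs"], points[kcol]))
    else:
        pts = list(points)
    free = tuple(free_coeffs)
    unknown = set(free) - set(names)
    if unknown:
        raise ValueError(f"unknown coefficient name(s) {sorted(unknown)}; "
                         f"form '{form}' has {names}")
    if set(free) == set(names):
        raise ValueError(
            "rank-deficient fit: the leading coefficient and the bracket "
            "coefficients share an overall scale; fix at least one "
            "coefficient (e.g. free_coeffs without 'leading')"
        )
    if len(pts) < len(free) + 1:
        raise ValueError(
            f"need at least {len(free) + 1} points to fit {len(free)} "
            f"coefficient(s), got {len(pts)}"
        )

    full0 = np.asarray(init if init is not None else spec["printed"], float)
    free_idx = [names.index(f) for f in free]
    bracket_free = any(i > 0 for i in free_idx)

    vf = np.asarray([p[0] for p in pts], dtype=float)
    k = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(k <= 0):
        raise ValueError("permeability data must be strictly positive")
    phi = 1.0 - vf

    keep = np.ones(vf.size, dtype=bool)
    if not bracket_free:
        tol = 0.0
        if coeff_precision is not None:
            basis = 1.0 + np.abs(np.log(phi)) + phi + phi ** 2
            if form == "tamayol_bahrami":
                basis = basis + phi ** 4
            tol = 0.5 * coeff_precision * basis
        keep = spec["bracket"](phi, full0) > tol
        if not keep.any():
            raise ValueError("fixed bracket is non-positive (or below its "
                             "rounding uncertainty) at every point")

    logk = np.log(k[keep])
    phik = phi[keep]

    def residual(free_vals):
        c = full0.copy()
        c[free_idx] = free_vals
        br = spec["bracket"](phik, c)
        model = r ** 2 * br / (c[0] * phik)
        bad = (model <= 0) | ~np.isfinite(model)
        res = np.where(bad, 1.0e3 * (1.0 + np.abs(br)),
                       np.log(np.where(bad, 1.0, model)) - logk)
        return res

    out = least_squares(residual, full0[free_idx], method="lm")
    coeff = full0.copy()
    coeff[free_idx] = out.x
    res = residual(out.x)
    return PermeabilityLawFit(
        form=form,
        coefficients=tuple(coeff),
        free=free,
        rms_log_residual=float(np.sqrt(np.mean(res ** 2))),
        residuals=res,
        n_points=int(keep.sum()),
        excluded_vf=tuple(np.round(vf[~keep], 6)),
    )
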