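"""Desk-scale 2-D incompressible laminar Navier-Stokes solver.

Fractional-step (projection) scheme on a uniform staggered MAC grid with
a direct-forcing immersed moving boundary: the no-slip condition on the
swimmer surface is imposed by interpolating the provisional velocity at
Lagrangian markers with a smoothed (Roma 3-point) delta kernel, adding
the momentum forcing that drives it to the prescribed marker velocity,
and spreading that forcing back to the grid.

The pressure is kinematic (divided by the reference density), matching
the incompressible-flow convention.  Time stepping: 2nd-order explicit
Adams-Bashforth advection and diffusion, then forcing, then a pressure
Poisson solve and projection.  At the Reynolds numbers this package
targets (<= a few thousand) the explicit diffusive stability limit is
far slacker than the advective CFL at the default step, so an implicit
diffusion solve would buy nothing; the step() precondition checks both
limits.

Boundary-condition modes:

* ``periodic`` — doubly periodic box, FFT Poisson solve (validation
  cases: Taylor-Green decay, convergence studies).
* ``tank``     — inflow at the left face (the body-frame far field of a
  self-propelled swimmer), convective outflow at the right, free-slip
  lateral walls; the outflow is flux-corrected every step so the
  pressure problem is compatible.
* ``cavity``   — no-slip box with a moving lid (classical validation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "FlowState",
    "ImmersedBoundary",
    "ForceRecord",
    "init_flow",
    "step",
    "surface_forces",
    "vorticity",
    "q_criterion",
    "divergence",
    "kinetic_energy",
    "StepSizeError",
    "InvalidGridError",
]


class InvalidGridError(ValueError):
    pass


class StepSizeError(RuntimeError):
    """dt violates the advective CFL or diffusive stability limit."""


class PoissonError(RuntimeError):
    pass


@dataclass
class ImmersedBoundary:
    """Lagrangian marker representation of the moving swimmer surface.

    points, velocities: (M, 2) arrays, m and m/s.  element_lengths:
    (M,) arc length per marker, m (should stay within [0.5h, 1.5h] for
    forcing stability).  tags: per-marker region labels.  tangents:
    optional (M, 2) unit tangents, used for the normal/tangential
    (pressure-like/friction-like) force split diagnostic.
    """

    points: np.ndarray
    velocities: np.ndarray
    element_lengths: np.ndarray
    tags: np.ndarray = None
    tangents: np.ndarray = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, float))
        self.element_lengths = np.asarray(self.element_lengths, float)
        if self.tags is None:
            self.tags = np.array(["boundary"] * len(self.points))

    def __len__(self):
        return len(self.points)


@dataclass
class ForceRecord:
    """Surface forces from the immersed-boundary momentum exchange.

    Per-element forces are kinematic and per unit depth (m^3/s^2);
    multiply by fluid density and an effective depth for newtons.  The
    net force equals the per-element sum exactly by construction.
    ``normal``/``tangential`` give a pressure-like/friction-like split
    along stored marker tangents (diagnostic; zeros if no tangents).
    """

    fx: np.ndarray
    fy: np.ndarray
    tags: np.ndarray
    t: float
    normal: np.ndarray = None
    tangential: np.ndarray = None

    @property
    def net_x(self) -> float:
        return float(self.fx.sum())

    @property
    def net_y(self) -> float:
        return float(self.fy.sum())


@dataclass
class FlowState:
    nx: int
    ny: int
    h: float
    lx: float
    ly: float
    nu: float
    bc: str
    u: np.ndarray          # (nx+1, ny) x-velocity on vertical faces
    v: np.ndarray          # (nx, ny+1) y-velocity on horizontal faces
    p: np.ndarray          # (nx, ny) kinematic pressure at centers
    t: float = 0.0
    inflow: float = 0.0    # tank far-field speed (time-dependent, settable)
    lid: float = 0.0       # cavity lid speed
    cfl: float = 0.5
    div_tol: float = 1e-8  # scaled by max speed / h in the check
    n_force_iter: int = 1
    poisson: str = "direct"   # 'direct' (sparse LU) or 'cg'
    _lu: object = field(default=None, repr=False)
    _lap: object = field(default=None, repr=False)
    last_forces: ForceRecord = field(default=None, repr=False)

    def copy_fields(self):
        return self.u.copy(), self.v.copy(), self.p.copy(), self.t

    def restore_fields(self, saved):
        self.u, self.v, self.p, self.t = (
            saved[0].copy(), saved[1].copy(), saved[2].copy(), saved[3])


# ----------------------------------------------------------------------
# initialisation

def init_flow(nx: int, ny: int, lx: float, ly: float, nu: float,
              bc: str = "tank", init: str = "quiescent",
              U: float = 0.0, **kw) -> FlowState:
    """Create a divergence-free initial flow state.

    ``init``: 'quiescent' (all zero), 'uniform' (u = U everywhere), or
    'taylor_green' (one-wavelength analytic vortex array; periodic only).
    """
    if nx < 16 or ny < 16:
        raise InvalidGridError("grid must be at least 16 x 16 cells")
    if nu <= 0:
        raise InvalidGridError("kinematic viscosity must be positive")
    hx, hy = lx / nx, ly / ny
    if abs(hx - hy) > 1e-12 * max(hx, hy):
        raise InvalidGridError("cells must be square (lx/nx == ly/ny)")
    if bc not in ("periodic", "tank", "cavity"):
        raise InvalidGridError(f"unknown bc {bc!r}")
    h = hx
    if bc == "periodic":
        u = np.zeros((nx, ny))
        v = np.zeros((nx, ny))
    else:
        u = np.zeros((nx + 1, ny))
        v = np.zeros((nx, ny + 1))
    p = np.zeros((nx, ny))
    state = FlowState(nx=nx, ny=ny, h=h, lx=lx, ly=ly, nu=nu, bc=bc,
                      u=u, v=v, p=p, **kw)
    if init == "uniform":
        state.u[:] = U
        state.inflow = U
    elif init == "taylor_green":
        if bc != "periodic":
            raise InvalidGridError("taylor_green init requires periodic bc")
        k = 2 * np.pi / lx
        xu, yu = _u_coords(state)
        xv, yv = _v_coords(state)
        state.u[:] = np.sin(k * xu) * np.cos(k * yu)
        state.v[:] = -np.cos(k * xv) * np.sin(k * yv)
    elif init != "quiescent":
        raise InvalidGridError(f"unknown init {init!r}")
    return state


def _u_coords(s: FlowState):
    if s.bc == "periodic":
        x = np.arange(s.nx) * s.h
    else:
        x = np.arange(s.nx + 1) * s.h
    y = (np.arange(s.ny) + 0.5) * s.h
    return x[:, None], y[None, :]


def _v_coords(s: FlowState):
    x = (np.arange(s.nx) + 0.5) * s.h
    if s.bc == "periodic":
        y = np.arange(s.ny) * s.h
    else:
        y = np.arange(s.ny + 1) * s.h
    return x[:, None], y[None, :]


# ----------------------------------------------------------------------
# diagnostics

def divergence(state: FlowState) -> np.ndarray:
    """Cell-centred discrete divergence, 1/s."""
    h = state.h
    if state.bc == "periodic":
        du = (np.roll(state.u, -1, 0) - state.u) / h
        dv = (np.roll(state.v, -1, 1) - state.v) / h
    else:
        du = np.diff(state.u, axis=0) / h
        dv = np.diff(state.v, axis=1) / h
    return du + dv


def kinetic_energy(state: FlowState) -> float:
    """Domain-integrated kinetic energy per unit depth/density, m^4/s^2."""
    h2 = state.h ** 2
    return 0.5 * h2 * (float((state.u ** 2).sum()) + float((state.v ** 2).sum()))


def center_velocity(state: FlowState):
    """Velocities interpolated to cell centres (nx, ny)."""
    if state.bc == "periodic":
        uc = 0.5 * (state.u + np.roll(state.u, -1, 0))
        vc = 0.5 * (state.v + np.roll(state.v, -1, 1))
    else:
        uc = 0.5 * (state.u[:-1] + state.u[1:])
        vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    return uc, vc


def _center_gradients(state: FlowState):
    h = state.h
    uc, vc = center_velocity(state)
    if state.bc == "periodic":
        ddx = lambda f: (np.roll(f, -1, 0) - np.roll(f, 1, 0)) / (2 * h)
        ddy = lambda f: (np.roll(f, -1, 1) - np.roll(f, 1, 1)) / (2 * h)
        return ddx(uc), ddy(uc), ddx(vc), ddy(vc)
    ux = np.gradient(uc, h, axis=0, edge_order=2)
    uy = np.gradient(uc, h, axis=1, edge_order=2)
    vx = np.gradient(vc, h, axis=0, edge_order=2)
    vy = np.gradient(vc, h, axis=1, edge_order=2)
    return ux, uy, vx, vy


def vorticity(state: FlowState) -> np.ndarray:
    """Out-of-plane vorticity dv/dx - du/dy at cell centres, 1/s."""
    ux, uy, vx, vy = _center_gradients(state)
    return vx - uy


def q_criterion(state: FlowState) -> np.ndarray:
    """Q = (||Omega||^2 - ||S||^2)/2 at cell centres, 1/s^2.

    For 2-D incompressible flow this reduces to det(grad u) =
    ux*vy - uy*vx; positive where rotation dominates strain.
    """
    ux, uy, vx, vy = _center_gradients(state)
    return ux * vy - uy * vx


# ----------------------------------------------------------------------
# Poisson solvers

def _build_neumann_laplacian(state: FlowState):
    """Pinned all-Neumann 5-point Laplacian at cell centres."""
    nx, ny, h = state.nx, state.ny, state.h
    n = nx * ny
    idx = np.arange(n).reshape(nx, ny)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r.ravel())
        cols.append(c.ravel())
        vals.append(np.broadcast_to(v, r.shape).ravel().astype(float))

    diag = np.zeros((nx, ny))
    for shift_axis, sl_from, sl_to in (
            (0, np.s_[:-1, :], np.s_[1:, :]),
            (0, np.s_[1:, :], np.s_[:-1, :]),
            (1, np.s_[:, :-1], np.s_[:, 1:]),
            (1, np.s_[:, 1:], np.s_[:, :-1])):
        add(idx[sl_from], idx[sl_to], 1.0 / h ** 2)
        diag[sl_from] -= 1.0 / h ** 2
    add(idx, idx, 0.0)  # placeholder to keep pattern; diag added below
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    # pin cell 0 (pure-Neumann nullspace): replace its row with identity
    A = A.tolil()
    A.rows[0] = [0]
    A.data[0] = [1.0]
    return A.tocsc()


def _solve_poisson(state: FlowState, rhs: np.ndarray) -> np.ndarray:
    nx, ny, h = state.nx, state.ny, state.h
    if state.bc == "periodic":
        rhs_hat = np.fft.rfft2(rhs)
        kx = np.arange(nx)
        ky = np.arange(rhs_hat.shape[1])
        lam = ((2 * np.cos(2 * np.pi * kx / nx) - 2)[:, None]
               + (2 * np.cos(2 * np.pi * ky / ny) - 2)[None, :]) / h ** 2
        lam[0, 0] = 1.0
        p_hat = rhs_hat / lam
        p_hat[0, 0] = 0.0
        return np.fft.irfft2(p_hat, s=rhs.shape)
    if state._lap is None:
        state._lap = _build_neumann_laplacian(state)
        if state.poisson == "direct":
            state._lu = spla.splu(state._lap)
    b = rhs.ravel().copy()
    b[0] = 0.0  # pinned reference cell
    if state.poisson == "direct":
        x = state._lu.solve(b)
    else:
        M = spla.LinearOperator(
            state._lap.shape,
            matvec=lambda r: r / state._lap.diagonal())
        x, info = spla.cg(state._lap, b, rtol=1e-10, atol=0.0, M=M,
                          maxiter=10 * len(b))
        if info != 0:
            res = np.linalg.norm(state._lap @ x - b)
            raise PoissonError(f"CG did not converge (info={info}, residual={res:.3e})")
    return x.reshape(nx, ny)


# ----------------------------------------------------------------------
# advection-diffusion right-hand sides

def _rhs_periodic(s: FlowState):
    h, nu = s.h, s.nu
    u, v = s.u, s.v
    roll = np.roll
    # u-momentum
    uce = 0.5 * (u + roll(u, -1, 0))                  # u at centres
    uco = 0.5 * (u + roll(u, 1, 1))                   # u at corners (i, j)
    vco = 0.5 * (v + roll(v, 1, 0))                   # v at corners
    duu = (uce ** 2 - roll(uce, 1, 0) ** 2) / h
    duv = (roll(uco * vco, -1, 1) - uco * vco) / h
    lap_u = (roll(u, -1, 0) + roll(u, 1, 0) + roll(u, -1, 1) + roll(u, 1, 1)
             - 4 * u) / h ** 2
    rhs_u = -(duu + duv) + nu * lap_u
    # v-momentum
    vce = 0.5 * (v + roll(v, -1, 1))
    dvv = (vce ** 2 - roll(vce, 1, 1) ** 2) / h
    duv2 = (roll(uco * vco, -1, 0) - uco * vco) / h
    lap_v = (roll(v, -1, 0) + roll(v, 1, 0) + roll(v, -1, 1) + roll(v, 1, 1)
             - 4 * v) / h ** 2
    rhs_v = -(dvv + duv2) + nu * lap_v
    return rhs_u, rhs_v


def _ghosted(s: FlowState):
    """u with ghost rows in y, v with ghost columns in x (BC-dependent)."""
    nx, ny = s.nx, s.ny
    ug = np.empty((nx + 1, ny + 2))
    ug[:, 1:-1] = s.u
    vg = np.empty((nx + 2, ny + 1))
    vg[1:-1, :] = s.v
    if s.bc == "tank":
        ug[:, 0] = s.u[:, 0]       # free-slip bottom: du/dy = 0
        ug[:, -1] = s.u[:, -1]     # free-slip top
        vg[0, :] = -s.v[0, :]      # inflow: v = 0 at x = 0
        vg[-1, :] = s.v[-1, :]     # outflow: dv/dx = 0
    else:  # cavity: no-slip walls, moving lid
        ug[:, 0] = -s.u[:, 0]
        ug[:, -1] = 2.0 * s.lid - s.u[:, -1]
        vg[0, :] = -s.v[0, :]
        vg[-1, :] = -s.v[-1, :]
    return ug, vg


def _rhs_nonperiodic(s: FlowState):
    h, nu = s.h, s.nu
    u, v = s.u, s.v
    ug, vg = _ghosted(s)
    # --- u-momentum at interior faces i = 1..nx-1, all j
    uce = 0.5 * (u[:-1] + u[1:])                      # (nx, ny) at centres
    duu = (uce[1:] ** 2 - uce[:-1] ** 2) / h          # (nx-1, ny)
    # corners (i, jc) for i = 1..nx-1, jc = 0..ny
    uco = 0.5 * (ug[1:-1, :-1] + ug[1:-1, 1:])        # (nx-1, ny+1)
    vco = 0.5 * (v[:-1, :] + v[1:, :])                # (nx-1, ny+1)
    uv = uco * vco
    duv = (uv[:, 1:] - uv[:, :-1]) / h                # (nx-1, ny)
    lap_u = ((u[2:, :] - 2 * u[1:-1, :] + u[:-2, :])
             + (ug[1:-1, 2:] - 2 * ug[1:-1, 1:-1] + ug[1:-1, :-2])) / h ** 2
    rhs_u = -(duu + duv) + nu * lap_u                 # (nx-1, ny)
    # --- v-momentum at interior faces j = 1..ny-1, all i
    vce = 0.5 * (v[:, :-1] + v[:, 1:])                # (nx, ny)
    dvv = (vce[:, 1:] ** 2 - vce[:, :-1] ** 2) / h    # (nx, ny-1)
    vco2 = 0.5 * (vg[:-1, 1:-1] + vg[1:, 1:-1])       # (nx+1, ny-1) corners
    uco2 = 0.5 * (u[:, :-1] + u[:, 1:])               # (nx+1, ny-1)
    uv2 = uco2 * vco2
    duv2 = (uv2[1:, :] - uv2[:-1, :]) / h             # (nx, ny-1)
    lap_v = ((vg[2:, 1:-1] - 2 * vg[1:-1, 1:-1] + vg[:-2, 1:-1])
             + (v[:, 2:] - 2 * v[:, 1:-1] + v[:, :-2])) / h ** 2
    rhs_v = -(dvv + duv2) + nu * lap_v                # (nx, ny-1)
    return rhs_u, rhs_v


# ----------------------------------------------------------------------
# immersed boundary kernels

def _roma_delta(r):
    """Roma-Peskin 3-point regularised delta (times h)."""
    a = np.abs(r)
    phi = np.zeros_like(a)
    m1 = a <= 0.5
    phi[m1] = (1.0 + np.sqrt(np.maximum(1.0 - 3.0 * a[m1] ** 2, 0.0))) / 3.0
    m2 = (a > 0.5) & (a <= 1.5)
    phi[m2] = (5.0 - 3.0 * a[m2]
               - np.sqrt(np.maximum(1.0 - 3.0 * (1.0 - a[m2]) ** 2, 0.0))) / 6.0
    return phi


def _stencil(coord, h, n_nodes, offset):
    """3-point stencil indices and weights along one axis.

    ``offset``: grid-node coordinate of index 0 (0 for face nodes,
    h/2 for centre nodes).
    """
    s = (coord - offset) / h
    base = np.round(s).astype(int)
    ids = base[:, None] + np.array([-1, 0, 1])[None, :]
    w = _roma_delta(s[:, None] - ids)
    ids = np.clip(ids, 0, n_nodes - 1)
    return ids, w


def _interp(field, ix, wx, iy, wy):
    vals = field[ix[:, :, None], iy[:, None, :]]
    return (vals * wx[:, :, None] * wy[:, None, :]).sum(axis=(1, 2))


def _spread(field, ix, wx, iy, wy, q):
    contrib = q[:, None, None] * wx[:, :, None] * wy[:, None, :]
    np.add.at(field, (ix[:, :, None].repeat(3, 2), iy[:, None, :].repeat(3, 1)),
              contrib)


def _apply_ib_forcing(s: FlowState, boundary: ImmersedBoundary, dt: float):
    """Direct forcing on the provisional velocity; returns marker forces.

    Returned per-marker forces are the kinematic force exerted by the
    fluid on the boundary per unit depth (sign-reversed spread forcing),
    units m^3/s^2.
    """
    h = s.h
    X = boundary.points
    Ub = boundary.velocities
    dV = boundary.element_lengths * h
    spacing = boundary.element_lengths
    if ((spacing < 0.5 * h) | (spacing > 1.5 * h)).any():
        warnings.warn("marker spacing outside [0.5h, 1.5h]; forcing may be unstable")
    ixu, wxu = _stencil(X[:, 0], h, s.u.shape[0], 0.0)
    iyu, wyu = _stencil(X[:, 1], h, s.u.shape[1], 0.5 * h)
    ixv, wxv = _stencil(X[:, 0], h, s.v.shape[0], 0.5 * h)
    iyv, wyv = _stencil(X[:, 1], h, s.v.shape[1], 0.0)
    fx_tot = np.zeros(len(X))
    fy_tot = np.zeros(len(X))
    for _ in range(max(1, s.n_force_iter)):
        u_m = _interp(s.u, ixu, wxu, iyu, wyu)
        v_m = _interp(s.v, ixv, wxv, iyv, wyv)
        Fx = (Ub[:, 0] - u_m) / dt            # acceleration applied to fluid
        Fy = (Ub[:, 1] - v_m) / dt
        _spread(s.u, ixu, wxu, iyu, wyu, dt * Fx * dV / h ** 2)
        _spread(s.v, ixv, wxv, iyv, wyv, dt * Fy * dV / h ** 2)
        fx_tot += -Fx * dV
        fy_tot += -Fy * dV
    normal = tangential = None
    if boundary.tangents is not None:
        tx, ty = boundary.tangents[:, 0], boundary.tangents[:, 1]
        tangential = fx_tot * tx + fy_tot * ty
        normal = -fx_tot * ty + fy_tot * tx
    return ForceRecord(fx=fx_tot, fy=fy_tot, tags=boundary.tags,
                       t=s.t + dt, normal=normal, tangential=tangential)


# ----------------------------------------------------------------------
# time stepping

def admissible_dt(state: FlowState, boundary: ImmersedBoundary | None = None) -> float:
    """Largest stable step: min(advective CFL, explicit diffusion limit)."""
    umax = max(float(np.abs(state.u).max()), float(np.abs(state.v).max()),
               abs(state.inflow), abs(state.lid), 1e-12)
    if boundary is not None and len(boundary):
        umax = max(umax, float(np.abs(boundary.velocities).max()))
    dt_adv = state.cfl * state.h / umax
    dt_diff = 0.25 * state.h ** 2 / state.nu
    return min(dt_adv, dt_diff)


def _project(state: FlowState, dt: float, p_scale: float = 1.0):
    """Make the field divergence-free; store the physical pressure.

    In a Runge-Kutta stage whose Euler increment enters the combined
    field with coefficient ``b``, the projection potential equals
    ``b`` times the physical pressure, so the stored field is rescaled
    by ``p_scale = 1/b`` (the velocity correction always uses the raw
    potential).
    """
    h = state.h
    rhs = divergence(state) / dt
    p = _solve_poisson(state, rhs)
    state.p = p_scale * p
    if state.bc == "periodic":
        state.u -= dt * (p - np.roll(p, 1, 0)) / h
        state.v -= dt * (p - np.roll(p, 1, 1)) / h
    else:
        state.u[1:-1, :] -= dt * np.diff(p, axis=0) / h
        state.v[:, 1:-1] -= dt * np.diff(p, axis=1) / h


#: Shu-Osher SSP-RK3 stage combinations (a*u^n + b*Euler(current)) and the
#: coefficient with which each stage's forcing (applied after the convex
#: combination) propagates into the end-of-step field: stage-1 forcing is
#: multiplied by 1/4 then 2/3 by the later combinations, stage-2 by 2/3,
#: stage-3 by 1.
_RK3_STAGES = ((0.0, 1.0, 1.0 / 6.0),
               (0.75, 0.25, 2.0 / 3.0),
               (1.0 / 3.0, 2.0 / 3.0, 1.0))


def step(state: FlowState, boundary: ImmersedBoundary | None, dt: float) -> FlowState:
    """Advance the flow one time step of size ``dt`` (in place).

    Three-stage SSP Runge-Kutta on advection + diffusion; each stage
    ends with boundary-condition imposition, direct forcing on the
    immersed boundary, and a pressure projection, so the returned field
    is divergence-free and satisfies no-slip at the markers to forcing
    tolerance.  Raises :class:`StepSizeError` (naming the admissible dt)
    on a CFL or diffusive-stability violation, and asserts the
    post-projection divergence against the scaled tolerance.
    """
    dt_ok = admissible_dt(state, boundary)
    if dt > dt_ok * (1 + 1e-9):
        raise StepSizeError(
            f"dt={dt:.3e} exceeds the stability limit; admissible dt <= {dt_ok:.3e}")
    h = state.h
    u0, v0 = state.u.copy(), state.v.copy()
    force_acc = None

    for a, b, w in _RK3_STAGES:
        if state.bc == "periodic":
            rhs_u, rhs_v = _rhs_periodic(state)
            state.u = a * u0 + b * (state.u + dt * rhs_u)
            state.v = a * v0 + b * (state.v + dt * rhs_v)
        else:
            rhs_u, rhs_v = _rhs_nonperiodic(state)
            if state.bc == "tank":
                uc_out = max(state.inflow, float(state.u[-1].mean()), 0.0)
                u_out = state.u[-1] - dt * uc_out * (state.u[-1] - state.u[-2]) / h
                u_out = a * u0[-1] + b * u_out
            ue = state.u.copy()
            ve = state.v.copy()
            ue[1:-1, :] += dt * rhs_u
            ve[:, 1:-1] += dt * rhs_v
            state.u = a * u0 + b * ue
            state.v = a * v0 + b * ve
            if state.bc == "tank":
                state.u[0, :] = state.inflow
                state.u[-1, :] = u_out
                state.v[:, 0] = 0.0
                state.v[:, -1] = 0.0
            else:  # cavity
                state.u[0, :] = 0.0
                state.u[-1, :] = 0.0
                state.v[:, 0] = 0.0
                state.v[:, -1] = 0.0

        if boundary is not None and len(boundary):
            rec = _apply_ib_forcing(state, boundary, dt)
            if force_acc is None:
                force_acc = rec
                force_acc.fx = w * rec.fx
                force_acc.fy = w * rec.fy
            else:
                force_acc.fx += w * rec.fx
                force_acc.fy += w * rec.fy

        if state.bc == "tank":
            # flux correction: the outflow carries exactly the inflow flux
            defect = float(state.u[0, :].sum() - state.u[-1, :].sum())
            state.u[-1, :] += defect / state.ny
        _project(state, dt, p_scale=1.0 / b)

    if force_acc is not None and boundary.tangents is not None:
        tx, ty = boundary.tangents[:, 0], boundary.tangents[:, 1]
        force_acc.tangential = force_acc.fx * tx + force_acc.fy * ty
        force_acc.normal = -force_acc.fx * ty + force_acc.fy * tx
    state.last_forces = force_acc

    state.t += dt
    d = divergence(state)
    umax = max(float(np.abs(state.u).max()), float(np.abs(state.v).max()), 1e-12)
    tol = state.div_tol * max(umax / h, 1.0)
    if not np.isfinite(d).all() or not np.isfinite(state.u).all():
        raise PoissonError("non-finite fields after projection")
    if float(np.abs(d).max()) > tol:
        raise PoissonError(
            f"post-projection divergence {np.abs(d).max():.3e} exceeds {tol:.3e}")
    return state


def surface_forces(state: FlowState, boundary: ImmersedBoundary | None) -> ForceRecord:
    """Force record of the most recent step's momentum exchange.

    An empty boundary yields a zero record with a warning.
    """
    if boundary is None or len(boundary) == 0:
        warnings.warn("empty boundary: returning zero forces")
        return ForceRecord(fx=np.zeros(0), fy=np.zeros(0),
                           tags=np.zeros(0, dtype=object), t=state.t)
    if state.last_forces is None:
        warnings.warn("no step has been taken with this boundary; zero forces")
        z = np.zeros(len(boundary))
        return ForceRecord(fx=z, fy=z.copy(), tags=boundary.tags, t=state.t)
    return state.last_forces
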