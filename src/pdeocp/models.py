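"""Full-order case-study models as semi-discrete ODE systems.

Chemotaxis (1D, Keller-Segel type): cell density z and chemoattractant c
on a closed tube [0, L],

    dz/dt = D z_xixi - mu * d/dxi [ z/(1+c)^2 c_xi ]
    dc/dt = c_xixi + z^2/(1+z^2)

with zero-flux boundaries except a Robin condition at xi = L,
c_xi(L, t) = u(t) - c(L, t), through which a reservoir concentration
u(t) in [0, 1] actuates the system.  Initial state z = 1, c = 0.

FitzHugh-Nagumo (2D excitable medium): activator v and inhibitor w on
[0, 200]^2,

    dv/dt = lap(v) + (alpha - v)(v - 1)v - w + u(xi, t)
    dw/dt = eps * (gamma w - delta - beta v)

with zero-flux edges; u is piecewise constant over six equal vertical
actuator bands.  A plane front started from the step initial condition
travels in +xi1; resetting the upper half plane mid-transit breaks the
front and spawns a rotating spiral (the arrhythmia-like state the
optimal control must suppress).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .cvp import ControlParameterization, TargetProfile
from .grids import (
    SpatialGrid1D,
    SpatialGrid2D,
    build_grid_2d,
    first_derivative_1d,
    laplacian_1d,
    laplacian_2d,
)

__all__ = [
    "ChemotaxisParams",
    "FHNParams",
    "Trajectory",
    "ChemotaxisSystem",
    "chemotaxis_rhs",
    "simulate_chemotaxis",
    "fhn_reaction",
    "fhn_front_initial_condition",
    "break_front",
    "FHNSystem",
    "simulate_fhn",
    "fhn_front_target",
]


@dataclass(frozen=True)
class ChemotaxisParams:
    """D and chemotactic sensitivity of the 1D chemotaxis model."""

    D: float = 0.33
    mu_chem: float = 80.0
    L: float = 1.0

    def __post_init__(self):
        if self.D <= 0 or self.mu_chem < 0 or self.L <= 0:
            raise ValueError("require D > 0, mu_chem >= 0, L > 0")


@dataclass(frozen=True)
class FHNParams:
    alpha: float = 0.1
    eps: float = 0.01
    beta: float = 0.5
    gamma: float = 1.0
    delta: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.eps <= 0 or min(self.beta, self.gamma, self.delta) < 0:
            raise ValueError("require eps > 0 and beta, gamma, delta >= 0")


@dataclass
class Trajectory:
    """Sampled solution of a semi-discrete model."""

    t: np.ndarray
    fields: dict  # variable tag -> (n_times, n_nodes) array
    stats: dict = field(default_factory=dict)

    def final(self, var: str) -> np.ndarray:
        return self.fields[var][-1]


# ---------------------------------------------------------------------
# chemotaxis
# ---------------------------------------------------------------------


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@_njit(cache=True)
def _chemo_rhs_kernel(t, y, Az, Ac, bc, D1, b1, mu, h, tk, uk, pc, mode):
    """Interleaved chemotaxis RHS; u(t) from knots tk / values uk.

    ``pc`` selects piecewise-constant (element lookup) versus
    piecewise-linear (interpolation) control evaluation.  ``mode``
    selects the transport-term discretization:

    0  conservative half-node flux differences, zero wall fluxes
       (discrete cell mass exactly conserved for every control);
    1  product-rule evaluation at the nodes,
       d/dxi [z q c_xi] = z_xi q c_xi - 2 z c_xi^2/(1+c)^3 + z q c_xixi
       with q = 1/(1+c)^2 (mass leaks through the truncation terms);
    2  conservative interior plus the outflow-only advective wall flux
       mu z(L) q(L) max(u - c(L), 0);
    3  conservative interior plus the signed advective wall flux
       mu z(L) q(L) (u - c(L)) implied literally by the boundary data.
    """
    n = y.shape[0] // 2
    z = np.empty(n)
    c = np.empty(n)
    for i in range(n):
        z[i] = y[2 * i]
        c[i] = y[2 * i + 1]
    # control value at t
    m = tk.shape[0]
    if t <= tk[0]:
        u = uk[0]
    elif t >= tk[m - 1]:
        u = uk[uk.shape[0] - 1]
    else:
        k = 0
        for i in range(m - 1):
            if t < tk[i + 1]:
                k = i
                break
        if pc:
            u = uk[k]
        else:
            w = (t - tk[k]) / (tk[k + 1] - tk[k])
            u = (1.0 - w) * uk[k] + w * uk[k + 1]
    r = u - c[n - 1]
    # dense banded matvecs (n is small)
    dz = np.zeros(n)
    dc = np.zeros(n)
    zx = np.zeros(n)
    cx = np.zeros(n)
    for i in range(n):
        s1 = 0.0
        s2 = 0.0
        s3 = 0.0
        s4 = 0.0
        for j in range(n):
            s1 += Az[i, j] * z[j]
            s2 += Ac[i, j] * c[j]
            if mode == 1:
                s3 += D1[i, j] * z[j]
                s4 += D1[i, j] * c[j]
        dz[i] = s1
        dc[i] = s2 + r * bc[i]
        zx[i] = s3
        cx[i] = s4 + r * b1[i]
    if mode == 1:
        # dc currently holds c_xixi (production is added at the end)
        for i in range(n):
            one_c = 1.0 + c[i]
            q = 1.0 / (one_c * one_c)
            chem = (
                zx[i] * q * cx[i]
                - 2.0 * z[i] * cx[i] * cx[i] / (one_c * one_c * one_c)
                + z[i] * q * dc[i]
            )
            dz[i] -= mu * chem
    else:
        fprev = 0.0
        for i in range(n - 1):
            zm = 0.5 * (z[i] + z[i + 1])
            cm = 0.5 * (c[i] + c[i + 1])
            f = zm / ((1.0 + cm) * (1.0 + cm)) * (c[i + 1] - c[i]) / h
            if i == 0:
                dz[0] -= mu * f / (0.5 * h)
            else:
                dz[i] -= mu * (f - fprev) / h
            fprev = f
        fwall = 0.0
        if mode == 2 and r > 0.0:
            # outflow-only advective flux through the membrane
            fwall = z[n - 1] / ((1.0 + c[n - 1]) * (1.0 + c[n - 1])) * r
        elif mode == 3:
            # literal signed boundary flux implied by the printed data
            fwall = z[n - 1] / ((1.0 + c[n - 1]) * (1.0 + c[n - 1])) * r
        dz[n - 1] -= mu * (fwall - fprev) / (0.5 * h)
    # Robin boundary injection and chemoattractant production
    out = np.empty(2 * n)
    for i in range(n):
        out[2 * i] = dz[i]
        out[2 * i + 1] = dc[i] + z[i] * z[i] / (1.0 + z[i] * z[i])
    return out


class ChemotaxisSystem:
    """Semi-discretization of the chemotaxis model on a 1D grid.

    Precomputes the diffusion operators once; the state is interleaved
    as y = [z_0, c_0, z_1, c_1, ...] so that the ODE Jacobian is banded
    (half-bandwidth 4 for the 4th-order stencil), which lets LSODA use
    banded internal linear algebra.
    """

    BANDWIDTH = 4

    def __init__(
        self,
        params: ChemotaxisParams,
        grid: SpatialGrid1D,
        order: int = 4,
        scheme: str = "literal",
    ):
        """``scheme`` picks the discretization of the transport term.

        'nodal' (default) expands d/dxi[z/(1+c)^2 c_xi] by the product
        rule and evaluates it at the nodes with the same stencils as the
        diffusion terms.  The stated boundary data (z_xi = 0 plus the
        Robin condition on c) leave the advective cell flux through the
        membrane nonzero whenever u != c(L), so this variant exchanges
        cell mass with the reservoir side — which the boundary-control
        problems exploit.  'conservative' uses half-node flux
        differences with zero wall fluxes and conserves the discrete
        cell mass exactly for every control.
        """
        if abs(params.L - grid.L) > 1e-12:
            raise ValueError("params.L and grid.L disagree")
        if scheme not in ("nodal", "conservative", "upwind", "literal"):
            raise ValueError(f"unknown scheme {scheme!r}")
        self.params = params
        self.grid = grid
        self.order = order
        self.scheme = scheme
        self.mode = {"conservative": 0, "nodal": 1, "upwind": 2, "literal": 3}[scheme]
        self.A_z = laplacian_1d(grid, order=order, bc="neumann").matrix * params.D
        op_c = laplacian_1d(grid, order=order, bc="robin-right")
        self.A_c = op_c.matrix
        self.b_c = op_c.boundary_vector
        d1z = first_derivative_1d(grid, order=order, bc="neumann")
        d1c = first_derivative_1d(grid, order=order, bc="robin-right")
        self.D1 = d1z.matrix  # same interior stencil for z and c
        self.b_1 = d1c.boundary_vector
        self._h = grid.h
        self._n = grid.n_nodes

    def kernel_args(self, control: ControlParameterization):
        """(tk, uk, pc_flag) encoding the single-channel control."""
        if control.n_channels != 1:
            raise ValueError("chemotaxis admits a single boundary control channel")
        if control.interpolation == "pc":
            return control.breakpoints(), control.coeffs[0].copy(), True
        return control.breakpoints(), control.coeffs[0].copy(), False

    def rhs(self, t: float, y: np.ndarray, u_a: float, u_b: float) -> np.ndarray:
        """Interleaved RHS with u(t) = u_a + u_b * t (affine segment form)."""
        n = self._n
        z = y[0::2]
        c = y[1::2]
        h = self._h
        u_val = u_a + u_b * t
        robin = u_val - c[-1]
        cxx = self.A_c @ c + robin * self.b_c
        if self.scheme == "nodal":
            zx = self.D1 @ z
            cx = self.D1 @ c + robin * self.b_1
            q = 1.0 / (1.0 + c) ** 2
            chem = zx * q * cx - 2.0 * z * cx**2 / (1.0 + c) ** 3 + z * q * cxx
        else:
            zm = 0.5 * (z[1:] + z[:-1])
            cm = 0.5 * (c[1:] + c[:-1])
            flux = zm / (1.0 + cm) ** 2 * (c[1:] - c[:-1]) / h
            fwall = 0.0
            if (self.scheme == "upwind" and robin > 0.0) or self.scheme == "literal":
                fwall = z[-1] / (1.0 + c[-1]) ** 2 * robin
            chem = np.empty(n)
            chem[1:-1] = (flux[1:] - flux[:-1]) / h
            chem[0] = flux[0] / (0.5 * h)
            chem[-1] = (fwall - flux[-1]) / (0.5 * h)
        dz = self.A_z @ z - self.params.mu_chem * chem
        dc = cxx + z * z / (1.0 + z * z)
        out = np.empty(2 * n)
        out[0::2] = dz
        out[1::2] = dc
        return out

    def initial_state(self) -> np.ndarray:
        y0 = np.empty(2 * self._n)
        y0[0::2] = 1.0  # z
        y0[1::2] = 0.0  # c
        return y0


def chemotaxis_rhs(
    state: tuple[np.ndarray, np.ndarray],
    u_val: float,
    params: ChemotaxisParams,
    grid: SpatialGrid1D,
    order: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dz/dt, dc/dt) for nodal fields (z, c)."""
    z, c = state
    z = np.asarray(z, dtype=float)
    c = np.asarray(c, dtype=float)
    if z.shape != grid.shape or c.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(c))):
        raise FloatingPointError("non-finite field values")
    sys = ChemotaxisSystem(params, grid, order=order)
    y = np.empty(2 * grid.n_nodes)
    y[0::2] = z
    y[1::2] = c
    dy = sys.rhs(0.0, y, float(u_val), 0.0)
    return dy[0::2], dy[1::2]


def simulate_chemotaxis(
    params: ChemotaxisParams,
    grid: SpatialGrid1D,
    control: ControlParameterization,
    t_span: tuple[float, float] = (0.0, 1.0),
    rtol: float = 1e-8,
    atol: float = 1e-8,
    order: int = 4,
    t_eval: Optional[np.ndarray] = None,
    system: Optional[ChemotaxisSystem] = None,
) -> Trajectory:
    """Integrate the stiff chemotaxis system under a parameterized control.

    The integration restarts at every control breakpoint, so the right
    hand side seen by the solver is smooth on each segment (the control
    is affine in t there).  Returns fields sampled at ``t_eval``
    (default: the two endpoints of ``t_span``).
    """
    from scipy.integrate import odeint

    sys_ = system if system is not None else ChemotaxisSystem(params, grid, order=order)
    t0, tf = t_span
    if t_eval is None:
        t_eval = np.array([t0, tf])
    t_eval = np.asarray(t_eval, dtype=float)
    tk, uk, pc = sys_.kernel_args(control)
    args = (sys_.A_z, sys_.A_c, sys_.b_c, sys_.D1, sys_.b_1,
            sys_.params.mu_chem, sys_._h, tk, uk, pc, sys_.mode)

    # a piecewise-linear control is continuous, so LSODA integrates the
    # whole horizon in one sweep; piecewise-constant controls jump at
    # element boundaries, so the integration restarts there
    stops = tk if pc else np.array([t0, tf])
    stops = np.unique(np.clip(np.concatenate([stops, t_eval, [t0, tf]]), t0, tf))

    y = sys_.initial_state()
    times = [t0]
    states = [y.copy()]
    nfev = 0
    for ta, tb in zip(stops[:-1], stops[1:]):
        pts = np.union1d(t_eval[(t_eval > ta) & (t_eval <= tb)], [ta, tb])
        sol, info = odeint(
            _chemo_rhs_kernel, y, pts, args=args, tfirst=True,
            rtol=rtol, atol=atol, ml=sys_.BANDWIDTH, mu=sys_.BANDWIDTH,
            full_output=True, mxstep=6000,
        )
        if info["message"] != "Integration successful.":
            raise RuntimeError(f"chemotaxis integration failed on [{ta}, {tb}]: {info['message']}")
        nfev += int(info["nfe"][-1])
        for tj, yj in zip(pts[1:], sol[1:]):
            times.append(float(tj))
            states.append(yj.copy())
        y = sol[-1].copy()

    times = np.asarray(times)
    keep = np.isclose(times[:, None], t_eval[None, :]).any(axis=1)
    Y = np.stack(states)[keep]
    return Trajectory(
        t=times[keep],
        fields={"z": Y[:, 0::2], "c": Y[:, 1::2]},
        stats={"nfev": nfev, "rtol": rtol, "atol": atol, "order": order},
    )


def _clip_segments(control: ControlParameterization, t0: float, tf: float):
    """Affine control segments restricted to [t0, tf]."""
    for ta, tb, a, b in control.affine_segments():
        lo, hi = max(ta, t0), min(tb, tf)
        if hi > lo:
            yield lo, hi, a, b


# ---------------------------------------------------------------------
# FitzHugh-Nagumo
# ---------------------------------------------------------------------


def fhn_reaction(v, w, params: FHNParams):
    """Pointwise kinetics of the excitable medium.

    f(v, w) = (alpha - v)(v - 1) v - w
    g(v, w) = eps (beta v - gamma w - delta)

    The inhibitor relaxes toward (beta v - delta)/gamma on the slow
    time scale eps, which provides the refractory tail behind an
    excitation front — the ingredient that turns a broken front into a
    rotating spiral instead of a re-filling excitation.
    """
    f = (params.alpha - v) * (v - 1.0) * v - w
    g = params.eps * (params.beta * v - params.gamma * w - params.delta)
    return f, g


def fhn_front_initial_condition(grid: SpatialGrid2D) -> tuple[np.ndarray, np.ndarray]:
    """Step excitation: v = 1 for xi1 <= 10, else 0; w = 0 everywhere."""
    v = np.where(grid.xi1 <= 10.0, 1.0, 0.0)
    v = np.tile(v, grid.n2)
    w = np.zeros(grid.n_nodes)
    return v, w


def break_front(
    v: np.ndarray, w: np.ndarray, grid: SpatialGrid2D, reset_w: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Reset the upper half plane (xi2 in [100, 200]) to zero.

    Mimics a conduction block: the travelling plane front is cut and the
    free end curls into a spiral.  By default both v and w are reset;
    ``reset_w=False`` resets the activator only.
    """
    mask = np.repeat(grid.xi2 >= 100.0, grid.n1)
    v2 = np.where(mask, 0.0, v)
    w2 = np.where(mask, 0.0, w) if reset_w else np.asarray(w, dtype=float).copy()
    return v2, w2


class FHNSystem:
    """Semi-discretization of the 2D FHN model with band actuation."""

    def __init__(self, params: FHNParams, grid: SpatialGrid2D, order: int = 2):
        self.params = params
        self.grid = grid
        self.lap = laplacian_2d(grid, order=order)
        self.B = grid.band_indicators()  # (n_nodes, n_bands)

    def rhs(self, t, y, u_a, u_b):
        n = self.grid.n_nodes
        v = y[:n]
        w = y[n:]
        f, g = fhn_reaction(v, w, self.params)
        u = u_a + u_b * t
        dv = self.lap @ v + f + self.B @ u
        return np.concatenate([dv, g])


def simulate_fhn(
    params: FHNParams,
    grid: SpatialGrid2D,
    control: Optional[ControlParameterization],
    initial: tuple[np.ndarray, np.ndarray],
    t_span: tuple[float, float],
    rtol: float = 1e-6,
    atol: float = 1e-6,
    t_eval: Optional[np.ndarray] = None,
    system: Optional[FHNSystem] = None,
) -> Trajectory:
    """Integrate the full-order FHN system.

    ``control`` supplies one value per actuator band (n_channels must
    equal ``grid.n_bands``); ``control=None`` means u = 0.  The domain
    Laplacian is mild on the default grids, so an explicit adaptive RK
    integrator is used.
    """
    sys_ = system if system is not None else FHNSystem(params, grid)
    t0, tf = t_span
    if t_eval is None:
        t_eval = np.array([t0, tf])
    t_eval = np.asarray(t_eval, dtype=float)
    v0, w0 = initial
    y = np.concatenate([np.asarray(v0, dtype=float).ravel(), np.asarray(w0, dtype=float).ravel()])

    if control is None:
        segments = [(t0, tf, np.zeros(grid.n_bands), np.zeros(grid.n_bands))]
    else:
        if control.n_channels != grid.n_bands:
            raise ValueError("control channel count must equal the number of actuator bands")
        segments = list(_clip_segments(control, t0, tf))

    samples = {float(t0): y.copy()} if t_eval[0] == t0 else {}
    nfev = 0
    for ta, tb, a, b in segments:
        interior = t_eval[(t_eval > ta) & (t_eval <= tb)]
        pts = np.union1d(interior, [tb])
        sol = solve_ivp(
            sys_.rhs, (ta, tb), y, method="RK45", t_eval=pts,
            rtol=rtol, atol=atol, args=(a, b),
        )
        if not sol.success:
            raise RuntimeError(f"FHN integration failed on [{ta}, {tb}]: {sol.message}")
        nfev += sol.nfev
        for tj, yj in zip(sol.t, sol.y.T):
            if tj in interior:
                samples[float(tj)] = yj.copy()
        y = sol.y[:, -1].copy()
        samples.setdefault(float(tb), y.copy())

    times = np.array(sorted(t for t in samples if np.any(np.isclose(t, t_eval))))
    Y = np.stack([samples[float(t)] for t in times])
    n = grid.n_nodes
    return Trajectory(
        t=times,
        fields={"v": Y[:, :n], "w": Y[:, n:]},
        stats={"nfev": nfev, "rtol": rtol, "atol": atol},
    )


def fhn_front_target(
    params: FHNParams, grid: SpatialGrid2D, t_target: float, rtol: float = 1e-6
) -> TargetProfile:
    """Desired plane-front v-field: the unbroken front at ``t_target``."""
    v0, w0 = fhn_front_initial_condition(grid)
    traj = simulate_fhn(params, grid, None, (v0, w0), (0.0, t_target), rtol=rtol, atol=rtol)
    return TargetProfile(values=traj.final("v"), tag="front")
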