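"""Proper orthogonal decomposition and Galerkin reduced-order models.

The POD basis diagonalises the two-point spatial correlation kernel
R(xi, xi') = (1/l) sum_j x(xi, t_j) x(xi', t_j) built from an ensemble
of l snapshots.  On a quadrature grid with weights W the eigenproblem
is solved by the method of snapshots: the l x l Gram matrix
G = X^T W X / l shares its nonzero spectrum with the kernel, and each
eigenvector a_i lifts to a spatial mode phi_i = X a_i / sqrt(l s_i)
that is orthonormal under the quadrature inner product.  Energies are
the snapshot variances s_i (the inverse of the eigenvalue as written
with lambda on the left of the integral equation), sorted descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cvp import ControlParameterization, make_control
from .grids import SpatialGrid2D, inner_product, laplacian_2d

__all__ = [
    "SnapshotEnsemble",
    "PODBasis",
    "ReducedFHNModel",
    "compute_pod_basis",
    "select_modes",
    "project_field",
    "reconstruct",
    "build_reduced_fhn",
    "simulate_reduced_fhn",
    "generate_fhn_snapshots",
]


@dataclass
class SnapshotEnsemble:
    """Matrix of field samples (n_nodes x l) with their sample times."""

    snapshots: np.ndarray
    times: np.ndarray
    grid: object
    variable: str = ""

    def __post_init__(self):
        self.snapshots = np.atleast_2d(np.asarray(self.snapshots, dtype=float))
        if self.snapshots.shape[1] < 1:
            raise ValueError("need at least one snapshot")
        if not np.all(np.isfinite(self.snapshots)):
            raise ValueError("snapshots contain non-finite values")

    @property
    def n_snapshots(self) -> int:
        return self.snapshots.shape[1]


@dataclass
class PODBasis:
    """Orthonormal spatial modes with their energy spectrum."""

    modes: np.ndarray  # (n_nodes, N)
    energies: np.ndarray  # descending snapshot variances
    grid: object
    variable: str = ""

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def truncate(self, n: int) -> "PODBasis":
        return PODBasis(
            modes=self.modes[:, :n], energies=self.energies[:n],
            grid=self.grid, variable=self.variable,
        )


def compute_pod_basis(
    snapshots: SnapshotEnsemble, n_modes: Optional[int] = None
) -> PODBasis:
    """POD modes of an ensemble via the method of snapshots.

    Modes are orthonormal under the grid's quadrature inner product;
    each mode's sign is fixed by making its largest-magnitude nodal
    entry positive.  Only directions carrying numerically nonzero
    energy are kept.
    """
    X = snapshots.snapshots
    w = snapshots.grid.quad_weights
    ell = X.shape[1]
    if np.max(np.abs(X)) == 0.0:
        raise ValueError("degenerate ensemble: all snapshots are zero")
    G = (X.T * w) @ X / ell
    G = 0.5 * (G + G.T)
    s, A = np.linalg.eigh(G)
    order = np.argsort(s)[::-1]
    s, A = s[order], A[:, order]
    keep = s > max(s[0], 0.0) * 1e-13
    s, A = s[keep], A[:, keep]
    if n_modes is not None:
        s, A = s[:n_modes], A[:, :n_modes]
    modes = X @ (A / np.sqrt(ell * s))
    # polish orthonormality in the quadrature inner product: the Gram
    # route loses ~eps*(s_0/s_i) digits on near-null directions, so a
    # weighted QR (which leaves the span untouched) restores it
    sqw = np.sqrt(w)[:, None]
    Q, R = np.linalg.qr(sqw * modes)
    Q = Q * np.sign(np.diag(R))
    modes = Q / sqw
    # deterministic sign convention
    for i in range(modes.shape[1]):
        j = int(np.argmax(np.abs(modes[:, i])))
        if modes[j, i] < 0:
            modes[:, i] = -modes[:, i]
    return PODBasis(modes=modes, energies=s, grid=snapshots.grid,
                    variable=snapshots.variable)


def select_modes(basis: PODBasis, energy_pct: float) -> int:
    """Smallest N capturing at least ``energy_pct`` percent of energy."""
    if not (0.0 < energy_pct <= 100.0):
        raise ValueError("energy_pct must lie in (0, 100]")
    cum = np.cumsum(basis.energies)
    frac = 100.0 * cum / cum[-1]
    return int(np.searchsorted(frac, energy_pct - 1e-12) + 1)


def project_field(x: np.ndarray, basis: PODBasis) -> np.ndarray:
    """Mode coefficients m_i = <phi_i, x> under the quadrature pairing."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != basis.modes.shape[0]:
        raise ValueError("field does not live on the basis grid")
    return basis.modes.T @ (basis.grid.quad_weights * x)


def reconstruct(m: np.ndarray, basis: PODBasis) -> np.ndarray:
    """Truncated series sum_i m_i phi_i(xi)."""
    m = np.asarray(m, dtype=float).ravel()
    if m.size > basis.n_modes:
        raise ValueError("more coefficients than modes")
    return basis.modes[:, : m.size] @ m


# ---------------------------------------------------------------------
# reduced-order FitzHugh-Nagumo
# ---------------------------------------------------------------------


@dataclass
class ReducedFHNModel:
    """Galerkin projection of the FHN system onto (v, w) POD bases.

    The diffusion of the activator projects to the precomputed matrix
    P_A; the band-actuation term to U_A; the nonlinear kinetics are
    evaluated by reconstructing both fields on the grid, applying the
    reaction pointwise and projecting back each step (exact on the
    span of the bases).
    """

    params: object
    grid: SpatialGrid2D
    basis_v: PODBasis
    basis_w: PODBasis
    P_A: np.ndarray = field(default=None, repr=False)
    U_A: np.ndarray = field(default=None, repr=False)

    @property
    def n_v(self) -> int:
        return self.basis_v.n_modes

    @property
    def n_w(self) -> int:
        return self.basis_w.n_modes

    @property
    def dim(self) -> int:
        return self.n_v + self.n_w

    def rhs(self, t, m, u_a, u_b):
        from .models import fhn_reaction

        mv = m[: self.n_v]
        mw = m[self.n_v :]
        v = self.basis_v.modes @ mv
        w = self.basis_w.modes @ mw
        f, g = fhn_reaction(v, w, self.params)
        wq = self.grid.quad_weights
        u = u_a + u_b * t
        dmv = self.P_A @ mv + self.basis_v.modes.T @ (wq * f) + self.U_A @ u
        dmw = self.basis_w.modes.T @ (wq * g)
        return np.concatenate([dmv, dmw])

    def project_state(self, v: np.ndarray, w: np.ndarray) -> np.ndarray:
        return np.concatenate([project_field(v, self.basis_v),
                               project_field(w, self.basis_w)])

    def reconstruct_state(self, m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return (reconstruct(m[: self.n_v], self.basis_v),
                reconstruct(m[self.n_v :], self.basis_w))


def build_reduced_fhn(params, grid: SpatialGrid2D, basis_v: PODBasis,
                      basis_w: PODBasis) -> ReducedFHNModel:
    if basis_v.modes.shape[0] != grid.n_nodes or basis_w.modes.shape[0] != grid.n_nodes:
        raise ValueError("basis does not live on the given grid")
    lap = laplacian_2d(grid)
    wq = grid.quad_weights
    Phi_v = basis_v.modes
    P_A = Phi_v.T @ (wq[:, None] * (lap @ Phi_v))
    B = grid.band_indicators()
    U_A = Phi_v.T @ (wq[:, None] * B)
    return ReducedFHNModel(params=params, grid=grid, basis_v=basis_v,
                           basis_w=basis_w, P_A=P_A, U_A=U_A)


def simulate_reduced_fhn(
    rom: ReducedFHNModel,
    control: Optional[ControlParameterization],
    m0: np.ndarray,
    t_span: tuple[float, float],
    rtol: float = 1e-6,
    atol: float = 1e-6,
    t_eval: Optional[np.ndarray] = None,
):
    """Integrate the reduced model; mirrors ``simulate_fhn``'s contract."""
    from scipy.integrate import solve_ivp

    from .models import Trajectory, _clip_segments

    t0, tf = t_span
    if t_eval is None:
        t_eval = np.array([t0, tf])
    t_eval = np.asarray(t_eval, dtype=float)
    if control is None:
        segments = [(t0, tf, np.zeros(rom.grid.n_bands), np.zeros(rom.grid.n_bands))]
    else:
        if control.n_channels != rom.grid.n_bands:
            raise ValueError("control channel count must equal the number of actuator bands")
        segments = list(_clip_segments(control, t0, tf))

    y = np.asarray(m0, dtype=float).copy()
    samples = {float(t0): y.copy()} if t_eval[0] == t0 else {}
    nfev = 0
    for ta, tb, a, b in segments:
        interior = t_eval[(t_eval > ta) & (t_eval <= tb)]
        pts = np.union1d(interior, [tb])
        sol = solve_ivp(rom.rhs, (ta, tb), y, method="RK45", t_eval=pts,
                        rtol=rtol, atol=atol, args=(a, b))
        if not sol.success:
            raise RuntimeError(f"ROM integration failed on [{ta}, {tb}]: {sol.message}")
        nfev += sol.nfev
        for tj, yj in zip(sol.t, sol.y.T):
            if tj in interior:
                samples[float(tj)] = yj.copy()
        y = sol.y[:, -1].copy()
        samples.setdefault(float(tb), y.copy())
    times = np.array(sorted(t for t in samples if np.any(np.isclose(t, t_eval))))
    M = np.stack([samples[float(t)] for t in times])
    return Trajectory(t=times, fields={"m": M}, stats={"nfev": nfev, "rtol": rtol})


# ---------------------------------------------------------------------
# snapshot protocol
# ---------------------------------------------------------------------


def generate_fhn_snapshots(
    params,
    grid: SpatialGrid2D,
    seed: int = 0,
    t_break: float = 200.0,
    t_spin: float = 200.0,
    rtol: float = 1e-6,
    n_random_experiments: int = 15,
) -> tuple[SnapshotEnsemble, SnapshotEnsemble]:
    """Snapshot ensembles of v and w covering the controlled dynamics.

    Three sets are concatenated per variable:

    (a) the plane front from the step initial condition, u = 0, sampled
        every 10 time units on [0, 200] (21 snapshots);
    (b) the spiral born of breaking the front at ``t_break``, sampled
        every 10 time units over the 200 time units after the break;
    (c) ``n_random_experiments`` runs started from the spiral state,
        with the horizon split into 10 segments of 6 time units, each
        segment driving every actuator band with an i.i.d.
        uniform[-1, 1] value; sampled at the end of every segment.

    Everything is reproducible from ``seed``.
    """
    from .models import (
        FHNSystem,
        break_front,
        fhn_front_initial_condition,
        simulate_fhn,
    )

    rng = np.random.default_rng(seed)
    system = FHNSystem(params, grid)

    # (a) front set
    t_a = np.arange(0.0, 200.0 + 1e-9, 10.0)
    v0, w0 = fhn_front_initial_condition(grid)
    front = simulate_fhn(params, grid, None, (v0, w0), (0.0, 200.0),
                         rtol=rtol, atol=rtol, t_eval=t_a, system=system)
    V = [front.fields["v"].T]
    W = [front.fields["w"].T]
    times = [t_a]

    # (b) spiral set: break the front mid-transit, sample the winding
    mid = simulate_fhn(params, grid, None, (v0, w0), (0.0, t_break),
                       rtol=rtol, atol=rtol, system=system)
    vb, wb = break_front(mid.final("v"), mid.final("w"), grid)
    t_b = np.arange(10.0, 200.0 + 1e-9, 10.0)
    spiral = simulate_fhn(params, grid, None, (vb, wb), (0.0, 200.0),
                          rtol=rtol, atol=rtol, t_eval=t_b, system=system)
    V.append(spiral.fields["v"].T)
    W.append(spiral.fields["w"].T)
    times.append(t_b + t_break)

    # spiral state used as initial condition for the random-control runs
    spun = simulate_fhn(params, grid, None, (vb, wb), (0.0, t_spin),
                        rtol=rtol, atol=rtol, system=system)
    v_sp, w_sp = spun.final("v"), spun.final("w")

    # (c) random-control experiments
    t_c = np.arange(6.0, 60.0 + 1e-9, 6.0)
    for _ in range(n_random_experiments):
        coeffs = rng.uniform(-1.0, 1.0, size=(grid.n_bands, 10))
        cp = make_control(0.0, 60.0, grid.n_bands, 10, "pc",
                          coeffs=coeffs, bounds=(-1.0, 1.0))
        run = simulate_fhn(params, grid, cp, (v_sp, w_sp), (0.0, 60.0),
                           rtol=rtol, atol=rtol, t_eval=t_c, system=system)
        V.append(run.fields["v"].T)
        W.append(run.fields["w"].T)
        times.append(t_c)

    t_all = np.concatenate(times)
    ens_v = SnapshotEnsemble(np.hstack(V), t_all, grid, "v")
    ens_w = SnapshotEnsemble(np.hstack(W), t_all, grid, "w")
    return ens_v, ens_w
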