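"""Control vector parameterization, target profiles and cost functions.

A time-varying control on a horizon [t0, tf] is parameterized by a
matrix of rho coefficients per channel, interpreted either as piecewise
constant values on rho equal elements ('pc') or as node values of a
continuous piecewise-linear interpolant through rho equally spaced times
('pl').  Packing flattens the coefficient matrix channel-major, so the
decision vector of an n_c-channel, rho-element control has length
n_c * rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .grids import SpatialGrid1D

logger = logging.getLogger(__name__)

__all__ = [
    "ControlParameterization",
    "TargetProfile",
    "OCProblem",
    "make_control",
    "eval_control",
    "pack",
    "unpack",
    "refine",
    "make_target",
    "objective_chemotaxis",
    "objective_fhn",
    "ocp_cost",
    "mean_relative_error",
    "PENALTY_COST",
]

#: cost returned when a simulation fails during optimization, so that
#: stochastic searches simply move away from the offending region
PENALTY_COST = 1.0e6


@dataclass(frozen=True)
class ControlParameterization:
    t0: float
    tf: float
    n_channels: int
    rho: int
    interpolation: str  # 'pc' | 'pl'
    coeffs: np.ndarray = field(repr=False)  # (n_channels, rho)
    u_lower: np.ndarray = field(default=None, repr=False)  # (n_channels,)
    u_upper: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.interpolation not in ("pc", "pl"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.coeffs.shape != (self.n_channels, self.rho):
            raise ValueError("coefficient matrix must be (n_channels, rho)")

    # -- evaluation ----------------------------------------------------
    def __call__(self, t: float) -> np.ndarray:
        return eval_control(self, t)

    def breakpoints(self) -> np.ndarray:
        """Times at which the control (or its slope) may jump."""
        if self.interpolation == "pc":
            return np.linspace(self.t0, self.tf, self.rho + 1)
        return np.linspace(self.t0, self.tf, self.rho)

    def affine_segments(self):
        """Yield (ta, tb, a, b) with u(t) = a + b*t on each segment."""
        bp = self.breakpoints()
        if self.interpolation == "pc":
            for i in range(self.rho):
                yield bp[i], bp[i + 1], self.coeffs[:, i].copy(), np.zeros(self.n_channels)
        else:
            for i in range(self.rho - 1):
                ta, tb = bp[i], bp[i + 1]
                ua, ub = self.coeffs[:, i], self.coeffs[:, i + 1]
                b = (ub - ua) / (tb - ta)
                yield ta, tb, ua - b * ta, b

    def with_coeffs(self, coeffs: np.ndarray) -> "ControlParameterization":
        return replace(self, coeffs=np.asarray(coeffs, dtype=float).reshape(self.n_channels, self.rho))

    @property
    def n_decisions(self) -> int:
        return self.n_channels * self.rho

    def decision_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.repeat(self.u_lower, self.rho)
        ub = np.repeat(self.u_upper, self.rho)
        return lb, ub


def make_control(
    t0: float,
    tf: float,
    n_channels: int,
    rho: int,
    interpolation: str = "pl",
    coeffs: Optional[np.ndarray] = None,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> ControlParameterization:
    if coeffs is None:
        coeffs = np.zeros((n_channels, rho))
    lo, hi = bounds
    return ControlParameterization(
        t0=float(t0), tf=float(tf), n_channels=n_channels, rho=rho,
        interpolation=interpolation, coeffs=np.asarray(coeffs, dtype=float),
        u_lower=np.full(n_channels, float(lo)), u_upper=np.full(n_channels, float(hi)),
    )


def eval_control(cp: ControlParameterization, t: float) -> np.ndarray:
    """Control value(s) at time t; raises outside the horizon."""
    eps = 1e-12 * max(1.0, abs(cp.tf))
    if t < cp.t0 - eps or t > cp.tf + eps:
        raise ValueError(f"t={t} outside control horizon [{cp.t0}, {cp.tf}]")
    t = min(max(t, cp.t0), cp.tf)
    if cp.interpolation == "pc":
        width = (cp.tf - cp.t0) / cp.rho
        i = min(int((t - cp.t0) / width), cp.rho - 1)
        return cp.coeffs[:, i].copy()
    nodes = np.linspace(cp.t0, cp.tf, cp.rho)
    out = np.empty(cp.n_channels)
    for k in range(cp.n_channels):
        out[k] = np.interp(t, nodes, cp.coeffs[k])
    return out


def pack(cp: ControlParameterization) -> np.ndarray:
    """Flatten coefficients channel-major into the decision vector."""
    return cp.coeffs.ravel().copy()


def unpack(cp: ControlParameterization, decision: np.ndarray) -> ControlParameterization:
    decision = np.asarray(decision, dtype=float)
    if decision.size != cp.n_decisions:
        raise ValueError(f"decision vector length {decision.size} != {cp.n_decisions}")
    return cp.with_coeffs(decision.reshape(cp.n_channels, cp.rho))


def refine(cp: ControlParameterization, factor: int) -> ControlParameterization:
    """Lift to a finer discretization that reproduces the control exactly.

    Piecewise-constant controls split every element, rho' = factor*rho.
    Piecewise-linear controls split every element as well, which means
    rho' = factor*(rho - 1) + 1 node values: the old nodes are a subset
    of the new ones, so the refined interpolant equals the coarse one
    everywhere (sampling at factor*rho equispaced nodes instead would
    shift the interior kinks and change the control function).
    """
    if factor < 2:
        raise ValueError("refinement factor must be >= 2")
    if cp.interpolation == "pc":
        rho_new = factor * cp.rho
        coeffs = np.repeat(cp.coeffs, factor, axis=1)
    else:
        rho_new = factor * (cp.rho - 1) + 1
        t_new = np.linspace(cp.t0, cp.tf, rho_new)
        coeffs = np.stack([eval_control(cp, t) for t in t_new], axis=1)
    return replace(cp, rho=rho_new, coeffs=coeffs)


# -- targets and objectives -------------------------------------------


@dataclass(frozen=True)
class TargetProfile:
    values: np.ndarray = field(repr=False)
    tag: str = "custom"


def make_target(tag: str, grid, field_values: Optional[np.ndarray] = None) -> TargetProfile:
    """Desired final-state profile on the case grid.

    'gaussian'  z_T(xi) = 2.2 exp(-25 (xi - 0.5)^2) + 0.1   (1D)
    'constant'  z_T = 1                                     (1D)
    'front'     a supplied v-field snapshot (2D), passed via
                ``field_values``.
    """
    if tag == "gaussian":
        xi = grid.nodes
        return TargetProfile(values=2.2 * np.exp(-25.0 * (xi - 0.5) ** 2) + 0.1, tag=tag)
    if tag == "constant":
        return TargetProfile(values=np.ones(grid.n_nodes), tag=tag)
    if tag == "front":
        if field_values is None:
            raise ValueError("'front' target requires the snapshot field")
        return TargetProfile(values=np.asarray(field_values, dtype=float).ravel(), tag=tag)
    raise ValueError(f"unknown target tag {tag!r}")


def objective_chemotaxis(z_final: np.ndarray, target: TargetProfile, grid: SpatialGrid1D) -> float:
    """J_k = L/(2 n) * sum_j (z_j(tf) - z_T,j)^2 over all grid nodes."""
    z_final = np.asarray(z_final, dtype=float)
    if z_final.shape != target.values.shape:
        raise ValueError("field/target shape mismatch")
    n = grid.n_nodes
    return float(grid.L / (2.0 * n) * np.sum((z_final - target.values) ** 2))


def objective_fhn(v_final: np.ndarray, target: TargetProfile) -> float:
    """J = (1/n) * sum_i (v_i(tf) - v_T,i)^2."""
    v_final = np.asarray(v_final, dtype=float).ravel()
    if v_final.shape != target.values.shape:
        raise ValueError("field/target shape mismatch")
    return float(np.mean((v_final - target.values) ** 2))


def mean_relative_error(z_final: np.ndarray, target: TargetProfile) -> float:
    """Node-averaged |z - z_T| / |z_T| in percent."""
    z_final = np.asarray(z_final, dtype=float)
    if z_final.shape != target.values.shape:
        raise ValueError("field/target shape mismatch")
    if np.any(target.values == 0.0):
        raise ValueError("target vanishes at a node; relative error undefined")
    return float(100.0 * np.mean(np.abs(z_final - target.values) / np.abs(target.values)))


# -- the NLP cost ------------------------------------------------------


@dataclass
class OCProblem:
    """Optimal control problem: simulator + target + control template.

    ``simulate`` maps a ControlParameterization to the final-time field
    entering the objective (cell density z for the chemotaxis cases, the
    activator v for FHN).
    """

    simulate: Callable[[ControlParameterization], np.ndarray]
    target: TargetProfile
    grid: object
    objective: str  # 'ocp1' | 'ocp2' | 'fhn'
    control_template: ControlParameterization
    penalty: float = PENALTY_COST

    def cost(self, decision: np.ndarray) -> float:
        return ocp_cost(self, decision)

    def decision_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.control_template.decision_bounds()


def ocp_cost(problem: OCProblem, decision: np.ndarray) -> float:
    """Unpack -> simulate -> objective at tf, with a penalty fallback."""
    cp = unpack(problem.control_template, decision)
    try:
        final = problem.simulate(cp)
        if not np.all(np.isfinite(final)):
            raise FloatingPointError("non-finite state at final time")
        if problem.objective in ("ocp1", "ocp2"):
            return objective_chemotaxis(final, problem.target, problem.grid)
        return objective_fhn(final, problem.target)
    except (FloatingPointError, RuntimeError, ValueError) as exc:
        logger.warning("simulation failed during optimization: %s", exc)
        return problem.penalty
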