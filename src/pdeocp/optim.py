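"""Local SQP polishing, multistart diagnostics and a scatter-search
hybrid global solver for bound-constrained NLPs.

The NLPs produced by control vector parameterization are small
(tens of decision variables) but each cost evaluation is a full PDE
simulation, and the landscapes are multimodal.  The hybrid solver
keeps a reference set of high-quality and diverse members, combines
them pairwise to generate offspring, and periodically polishes
promising members with the gradient-based local solver — the classic
scatter-search recipe.  All randomness flows from the configured seed,
so runs are bit-reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "NLPProblem",
    "OptimizerConfig",
    "OptimizationResult",
    "MultistartSummary",
    "local_solve",
    "multistart",
    "hybrid_solve",
    "refine_and_polish",
]


@dataclass
class NLPProblem:
    """Bound-constrained minimization of a black-box cost."""

    fun: Callable[[np.ndarray], float]
    lb: np.ndarray
    ub: np.ndarray
    template: object = None  # optional ControlParameterization behind the vector

    def __post_init__(self):
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.lb.shape != self.ub.shape or np.any(self.lb > self.ub):
            raise ValueError("invalid bounds")
        if not np.all(np.isfinite(self.lb)) or not np.all(np.isfinite(self.ub)):
            raise ValueError("bounds must be finite")

    @property
    def dim(self) -> int:
        return self.lb.size


@dataclass
class OptimizerConfig:
    seed: int = 0
    tol: float = 1e-5  # local-solver convergence tolerance (cost-scaled)
    max_evals: int = 5000
    ref_set_size: int = 10
    n_diverse: Optional[int] = None  # default 10 * dim
    local_trigger: int = 10  # local polish every this many refset improvements
    local_maxiter: int = 100
    local_restarts: int = 2  # SQP re-runs from the incumbent per polish
    final_restarts: int = 8  # deeper polish of the global winner
    fd_step: float = 1e-5  # central-difference step in scaled variables
    n_stall: int = 8  # stop after this many sweeps without progress
    global_fraction: float = 0.7  # share of the budget for the global phase

    def __post_init__(self):
        if self.tol <= 0 or self.max_evals < 1 or self.ref_set_size < 4:
            raise ValueError("invalid optimizer configuration")


@dataclass
class OptimizationResult:
    x: np.ndarray
    fun: float
    n_evals: int
    trace: list = field(default_factory=list)  # (n_evals, best-so-far)
    seed: Optional[int] = None
    wall_time: float = 0.0
    success: bool = True
    message: str = ""


@dataclass
class MultistartSummary:
    results: list
    bin_edges: np.ndarray
    counts: np.ndarray
    best: float
    mean: float
    worst: float


class BudgetExhausted(Exception):
    """Raised by the evaluation counter when the budget runs out."""


class _CountedCost:
    """Wraps the cost with evaluation counting and a best-so-far trace.

    Once the budget is spent every further call raises
    :class:`BudgetExhausted`, which the solvers catch to return their
    incumbent — scipy's SQP loop has no evaluation-budget hook of its
    own.
    """

    def __init__(self, fun, max_evals=None):
        self._fun = fun
        self.n_evals = 0
        self.max_evals = max_evals
        self.best = np.inf
        self.best_x = None
        self.trace = []

    @property
    def exhausted(self) -> bool:
        return self.max_evals is not None and self.n_evals >= self.max_evals

    def __call__(self, x):
        if self.exhausted:
            raise BudgetExhausted
        self.n_evals += 1
        f = float(self._fun(np.asarray(x, dtype=float)))
        if f < self.best:
            self.best = f
            self.best_x = np.array(x, dtype=float)
            self.trace.append((self.n_evals, f))
        return f


def _central_difference_jac(fun, lb, ub, eps):
    """Bound-respecting central-difference gradient of ``fun``.

    Forward differences are too noisy for the narrow curved valleys the
    simulation-backed costs produce; central differences at a step well
    above the integrator noise floor keep SQP line searches productive.
    """

    def jac(x):
        x = np.asarray(x, dtype=float)
        g = np.zeros(x.size)
        for i in range(x.size):
            xp = x.copy()
            xm = x.copy()
            xp[i] = min(x[i] + eps, ub[i])
            xm[i] = max(x[i] - eps, lb[i])
            denom = xp[i] - xm[i]
            g[i] = (fun(xp) - fun(xm)) / denom if denom > 0 else 0.0
        return g

    return jac


def local_solve(
    problem: NLPProblem,
    x0: np.ndarray,
    config: Optional[OptimizerConfig] = None,
    counter: Optional[_CountedCost] = None,
    restarts: Optional[int] = None,
) -> OptimizationResult:
    """Bounded SQP-type descent from x0 with finite-difference gradients.

    The SQP engine is restarted from its own endpoint while it keeps
    making progress (each restart rebuilds the quadratic model, which is
    what actually drives descent through the ill-conditioned valleys of
    simulation-backed costs).  The returned cost never exceeds the cost
    at x0.
    """
    config = config or OptimizerConfig()
    n_restarts = restarts if restarts is not None else config.local_restarts
    x0 = np.clip(np.asarray(x0, dtype=float), problem.lb, problem.ub)
    fun = counter if counter is not None else _CountedCost(problem.fun,
                                                           max_evals=config.max_evals)
    n0 = fun.n_evals
    t0 = time.perf_counter()
    try:
        f_inc = fun(x0)
    except BudgetExhausted:
        f_inc = fun.best if fun.best_x is not None else np.inf
        x0 = fun.best_x if fun.best_x is not None else x0
    x_inc = x0
    bounds = list(zip(problem.lb, problem.ub))
    jac = _central_difference_jac(fun, problem.lb, problem.ub, config.fd_step)
    message = ""
    for _ in range(max(1, n_restarts)):
        try:
            res = minimize(
                fun, x_inc, jac=jac, method="SLSQP", bounds=bounds,
                options={"maxiter": config.local_maxiter, "ftol": 1e-20},
            )
            message = str(res.message)
            xr, fr = np.clip(res.x, problem.lb, problem.ub), float(res.fun)
        except BudgetExhausted:
            message = "evaluation budget exhausted"
            break
        except Exception as exc:  # pragma: no cover - solver-internal failure
            message = f"local solver failed: {exc}"
            break
        f_prev = f_inc
        if fr < f_inc:
            x_inc, f_inc = xr, fr
        # keep restarting only while the decrease is material
        if not (fr < f_prev - config.tol * abs(f_prev)) or fun.exhausted:
            break
    if fun.best < f_inc and fun.best_x is not None:
        x_inc, f_inc = fun.best_x.copy(), fun.best
    return OptimizationResult(
        x=np.asarray(x_inc, dtype=float), fun=f_inc, n_evals=fun.n_evals - n0,
        trace=[(n - n0, f) for n, f in fun.trace if n > n0] or [(fun.n_evals - n0, f_inc)],
        seed=config.seed, wall_time=time.perf_counter() - t0, message=message,
    )


def multistart(
    problem: NLPProblem,
    n_starts: int,
    seed: int = 0,
    config: Optional[OptimizerConfig] = None,
) -> MultistartSummary:
    """Polish uniformly sampled starting points with the local solver.

    The summary histograms log10 of the final costs in unit-width bins,
    the standard picture for diagnosing multimodality.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    config = config or OptimizerConfig(seed=seed)
    rng = np.random.default_rng(seed)
    starts = problem.lb + rng.random((n_starts, problem.dim)) * (problem.ub - problem.lb)
    results = [local_solve(problem, x0, config) for x0 in starts]
    finals = np.array([r.fun for r in results if np.isfinite(r.fun) and r.fun > 0])
    logs = np.log10(finals)
    lo, hi = np.floor(logs.min()), np.ceil(logs.max())
    if hi <= lo:
        hi = lo + 1
    edges = np.arange(lo, hi + 1)
    counts, _ = np.histogram(logs, bins=edges)
    return MultistartSummary(
        results=results, bin_edges=edges, counts=counts,
        best=float(finals.min()), mean=float(finals.mean()), worst=float(finals.max()),
    )


def _maximin_select(pool: np.ndarray, chosen: list, k: int, scale: np.ndarray):
    """Greedy maximin-distance selection of k pool rows (scaled space)."""
    picked = []
    cand = list(range(pool.shape[0]))
    ref = [np.asarray(c) / scale for c in chosen]
    for _ in range(min(k, len(cand))):
        dists = []
        for i in cand:
            p = pool[i] / scale
            d = min(np.linalg.norm(p - r) for r in ref) if ref else np.inf
            dists.append(d)
        j = cand[int(np.argmax(dists))]
        picked.append(j)
        ref.append(pool[j] / scale)
        cand.remove(j)
    return picked


def hybrid_solve(
    problem: NLPProblem,
    config: Optional[OptimizerConfig] = None,
) -> OptimizationResult:
    """Scatter-search global phase with periodic gradient-based polishing.

    A diverse seeded population initialises a reference set of the best
    and the most mutually distant members.  Pairwise combinations
    (interpolation and extrapolation along the connecting segment, with
    a go-beyond step while an offspring keeps improving on its parent)
    refresh the set; the local solver runs on the incumbent every
    ``local_trigger`` improvements and once more before returning.
    """
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    lb, ub, d = problem.lb, problem.ub, problem.dim
    scale = np.where(ub > lb, ub - lb, 1.0)
    n_global = max(1, int(config.global_fraction * config.max_evals))
    fun = _CountedCost(problem.fun, max_evals=n_global)
    t_start = time.perf_counter()

    n_div = config.n_diverse or max(10 * d, 20)
    n_div = min(n_div, max(4, n_global // 2))  # leave room for the search
    pool = lb + rng.random((n_div, d)) * (ub - lb)
    pool_f = np.array([fun(x) for x in pool])

    b = min(config.ref_set_size, n_div)
    nb = b // 2
    order = np.argsort(pool_f)
    ref_x = [pool[i].copy() for i in order[:nb]]
    ref_f = [pool_f[i] for i in order[:nb]]
    rest = np.delete(np.arange(n_div), order[:nb])
    for i in _maximin_select(pool[rest], ref_x, b - nb, scale):
        ref_x.append(pool[rest][i].copy())
        ref_f.append(pool_f[rest][i])
    ref_x = np.array(ref_x)
    ref_f = np.array(ref_f)
    b = ref_x.shape[0]

    improvements = 0
    polished: set = set()

    def _key(x):
        return tuple(np.round(x / scale, 9))

    def polish_best():
        i = int(np.argmin(ref_f))
        if _key(ref_x[i]) in polished or fun.exhausted:
            return
        res = local_solve(problem, ref_x[i], config, counter=fun, restarts=1)
        if res.fun < ref_f[i]:
            ref_x[i] = res.x
            ref_f[i] = res.fun
        polished.add(_key(ref_x[i]))

    polish_best()

    stall = 0
    while not fun.exhausted and stall < config.n_stall:
        best_before = fun.best
        order = np.argsort(ref_f)
        for a_pos in range(b):
            if fun.exhausted:
                break
            for b_pos in range(a_pos + 1, b):
                if fun.exhausted:
                    break
                i, j = order[a_pos], order[b_pos]
                xi, xj = ref_x[i], ref_x[j]
                r = rng.uniform(-0.5, 1.5, size=d)
                child = np.clip(xi + r * (xj - xi), lb, ub)
                try:
                    fc = fun(child)
                    step = child - xi
                    while fc < ref_f[i] and not fun.exhausted:
                        nxt = np.clip(child + rng.uniform(0.5, 1.0) * step, lb, ub)
                        fn = fun(nxt)
                        if fn >= fc:
                            break
                        child, fc = nxt, fn
                        step = 2.0 * step
                except BudgetExhausted:
                    break
                w = int(np.argmax(ref_f))
                if fc < ref_f[w]:
                    # keep the set spread out: reject near-duplicates of
                    # better members (scaled distance below 1e-3)
                    dists = np.linalg.norm((ref_x - child) / scale, axis=1)
                    close = dists < 1e-3
                    if np.any(close & (ref_f <= fc)):
                        continue
                    ref_x[w] = child
                    ref_f[w] = fc
                    improvements += 1
                    if improvements % config.local_trigger == 0:
                        polish_best()
        if fun.best < best_before:
            stall = 0
        else:
            stall += 1
            # regenerate the worst half with fresh diverse members so a
            # collapsed set keeps exploring (eSS-style regeneration)
            if not fun.exhausted and stall < config.n_stall:
                worst = np.argsort(ref_f)[b - b // 2:]
                fresh = lb + rng.random((8 * len(worst), d)) * (ub - lb)
                keep = [ref_x[i] for i in np.argsort(ref_f)[: b - len(worst)]]
                for w, i in zip(worst, _maximin_select(fresh, keep, len(worst), scale)):
                    if fun.exhausted:
                        break
                    ref_x[w] = fresh[i]
                    ref_f[w] = fun(fresh[i])


    # spend the reserved share of the budget on a deep polish of the winner
    stopped_early = not fun.exhausted
    fun.max_evals = config.max_evals
    if fun.best_x is not None and not fun.exhausted:
        local_solve(problem, fun.best_x, config, counter=fun,
                    restarts=config.final_restarts)

    return OptimizationResult(
        x=fun.best_x.copy(), fun=fun.best, n_evals=fun.n_evals,
        trace=list(fun.trace), seed=config.seed,
        wall_time=time.perf_counter() - t_start,
        message="stalled" if stopped_early else "budget exhausted",
    )


def refine_and_polish(
    problem_factory: Callable[[int], NLPProblem],
    start: OptimizationResult,
    rho0: int,
    factor: int = 2,
    n_refinements: int = 1,
    config: Optional[OptimizerConfig] = None,
) -> OptimizationResult:
    """Control-refinement driver: lift the incumbent control, polish locally.

    ``problem_factory(rho)`` must return an NLPProblem whose ``template``
    is the control parameterization behind the decision vector, so the
    incumbent control can be lifted between discretization levels.
    """
    from .cvp import pack, refine, unpack

    if factor < 2 or n_refinements < 1:
        raise ValueError("factor must be >= 2 and n_refinements >= 1")
    config = config or OptimizerConfig()
    res = start
    rho = rho0
    for _ in range(n_refinements):
        coarse = problem_factory(rho)
        if coarse.template is None:
            raise ValueError("problem_factory must attach a control template")
        cp = unpack(coarse.template, res.x)
        cp_fine = refine(cp, factor)
        rho = cp_fine.rho
        fine = problem_factory(rho)
        res_fine = local_solve(fine, pack(cp_fine), config)
        res = OptimizationResult(
            x=res_fine.x, fun=res_fine.fun, n_evals=res.n_evals + res_fine.n_evals,
            trace=res.trace + [(res.n_evals + n, f) for n, f in res_fine.trace],
            seed=config.seed, wall_time=res.wall_time + res_fine.wall_time,
        )
    return res
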