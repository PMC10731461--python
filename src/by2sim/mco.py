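"""Bi-criteria design optimization: biomass yield versus process time.

The two objectives are the dimensionless active-biomass yield at its peak,
Ya* = Xa(t*)/X0 (maximize), and the peak time t* (minimize), both functions
of the inoculum dry mass X0 and the initial sucrose concentration S0 of a
batch run.  The front is built in three stages: (1) the max-yield anchor
(argmax Ya*), (2) the min-time anchor (earliest achievable peak), and (3) an
epsilon-constraint sweep over a uniform t* grid between the anchors, merged
with a weighted-sum sweep; the union is filtered to its non-dominated subset.
The weighted sum recovers the convex portion of the front; the
epsilon-constraint scalarization recovers the non-convex remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .kinetics import DEFAULT_MOLAR_MASSES, KineticParameters, MolarMassTable, ProcessState
from .process_sim import (
    ExperimentDesign,
    FeedPolicy,
    NoPeakError,
    SimulationError,
    SolverOptions,
    peak_active_yield,
    simulate,
)

__all__ = [
    "DesignSpace",
    "ParetoPoint",
    "InfeasibleDesignError",
    "objectives",
    "make_evaluator",
    "anchor_points",
    "epsilon_grid",
    "pareto_front",
    "pareto_front_from_evaluator",
    "nondominated",
]


class InfeasibleDesignError(RuntimeError):
    """No interior biomass peak within the simulation horizon."""


@dataclass(frozen=True)
class DesignSpace:
    """Optimization box over (X0 [g/L DM], S0 [mM]) with fixed co-initials."""

    x0_range: tuple[float, float] = (0.3, 1.5)
    s0_range_mM: tuple[float, float] = (17.0, 88.0)
    a0_mM: float = 21.0
    n0_mM: float = 39.0
    p0_mM: float = 2.7
    f0_mM: float = 0.0
    g0_mM: float = 0.0
    volume: float = 5.0
    horizon: float = 500.0  # h; batch window long enough to contain the peak
    variant: str = "initial"
    mm: MolarMassTable = field(default_factory=lambda: DEFAULT_MOLAR_MASSES)

    def __post_init__(self) -> None:
        for lo, hi in (self.x0_range, self.s0_range_mM):
            if not (0 < lo < hi):
                raise ValueError("design ranges must be positive and non-degenerate")

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [self.x0_range, self.s0_range_mM]

    def make_design(self, x0: float, s0_mM: float) -> ExperimentDesign:
        """Batch design at one point of the space (zero feed, dead mass 0)."""
        mm = self.mm
        initial = ProcessState(
            t=0.0, V=self.volume, Xa=x0, Xd=0.0,
            S=float(mm.to_internal(s0_mM, "S")),
            F=float(mm.to_internal(self.f0_mM, "F")),
            G=float(mm.to_internal(self.g0_mM, "G")),
            A=float(mm.to_internal(self.a0_mM, "A")),
            N=float(mm.to_internal(self.n0_mM, "N")),
            P=float(mm.to_internal(self.p0_mM, "P")),
        )
        return ExperimentDesign(label=f"design(X0={x0:.3g},S0={s0_mM:.3g}mM)",
                                variant=self.variant, initial=initial,
                                duration=self.horizon, feed=FeedPolicy())


@dataclass(frozen=True)
class ParetoPoint:
    """A design with its objective values and the scalarization that found it."""

    x0: float        # g/L DM
    s0_mM: float     # mM sucrose
    t_star: float    # h
    ya_star: float   # dimensionless
    method: str      # weighted_sum | eps_constraint | anchor

    def dominates(self, other: "ParetoPoint", tol: float = 1e-9) -> bool:
        ge = (self.ya_star >= other.ya_star - tol and
              self.t_star <= other.t_star + tol)
        strict = (self.ya_star > other.ya_star + tol or
                  self.t_star < other.t_star - tol)
        return ge and strict


def objectives(x0: float, s0_mM: float, params: KineticParameters,
               space: DesignSpace | None = None,
               solver: SolverOptions | None = None) -> tuple[float, float]:
    """(t*, Ya*) of the batch run at design (X0, S0)."""
    space = space or DesignSpace()
    design = space.make_design(x0, s0_mM)
    try:
        traj = simulate(design, params, solver)
        return peak_active_yield(traj, X0=x0)
    except (NoPeakError, SimulationError) as exc:
        raise InfeasibleDesignError(
            f"design (X0={x0}, S0={s0_mM} mM) has no usable peak: {exc}") from exc


def make_evaluator(params: KineticParameters, space: DesignSpace | None = None,
                   solver: SolverOptions | None = None,
                   ) -> Callable[[float, float], tuple[float, float]]:
    """Memoized (X0, S0) -> (t*, Ya*) map backed by batch simulation."""
    space = space or DesignSpace()
    cache: dict[tuple[float, float], tuple[float, float]] = {}

    def ev(x0: float, s0: float) -> tuple[float, float]:
        key = (round(float(x0), 10), round(float(s0), 10))
        if key not in cache:
            cache[key] = objectives(key[0], key[1], params, space, solver)
        return cache[key]

    return ev


def _multistart(fun, bounds, starts, maxiter=120):
    best = None
    for x0 in starts:
        res = minimize(fun, np.asarray(x0, dtype=float), method="Nelder-Mead",
                       bounds=bounds,
                       options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
    return best


def _center(bounds):
    (xl, xu), (sl, su) = bounds
    return (0.5 * (xl + xu), 0.5 * (sl + su))


def _corner_starts(bounds):
    (xl, xu), (sl, su) = bounds
    return [(xl, sl), (xl, su), (xu, sl), (xu, su), _center(bounds)]


def anchor_points(evaluator, space: DesignSpace | None = None,
                  maxiter: int = 120) -> tuple[ParetoPoint, ParetoPoint]:
    """The two front endpoints: max-yield anchor and min-time anchor.

    The max-yield anchor maximizes Ya* over the box (recording the t* at
    which that yield is reached); the min-time anchor finds the earliest
    achievable biomass peak, i.e. minimizes t* subject to t* being an
    interior maximum of Xa (enforced by the peak detector itself).
    """
    space = space or DesignSpace()
    bounds = space.bounds
    big = 1e9

    def neg_yield(z):
        try:
            return -evaluator(z[0], z[1])[1]
        except InfeasibleDesignError:
            return big

    def time_of_peak(z):
        try:
            return evaluator(z[0], z[1])[0]
        except InfeasibleDesignError:
            return big

    starts = _corner_starts(bounds)
    res_y = _multistart(neg_yield, bounds, starts, maxiter)
    res_t = _multistart(time_of_peak, bounds, starts, maxiter)
    if res_y is None or res_t is None or res_y.fun >= big or res_t.fun >= big:
        raise InfeasibleDesignError("anchor optimization found no feasible design")
    ty, yy = evaluator(*res_y.x)
    tt, yt = evaluator(*res_t.x)
    return (ParetoPoint(res_y.x[0], res_y.x[1], ty, yy, "anchor"),
            ParetoPoint(res_t.x[0], res_t.x[1], tt, yt, "anchor"))


def epsilon_grid(t_min: float, t_max: float, step: float = 3.0) -> np.ndarray:
    """Uniform process-time grid spanning [t_min, t_max] at the given step."""
    if t_max <= t_min:
        return np.array([t_min])
    n = int(round((t_max - t_min) / step))
    return np.linspace(t_min, t_min + n * step, n + 1)


def nondominated(points: Sequence[ParetoPoint]) -> list[ParetoPoint]:
    """Filter to the non-dominated subset, sorted by increasing t*."""
    pts = sorted(points, key=lambda p: (p.t_star, -p.ya_star))
    front: list[ParetoPoint] = []
    best_ya = -np.inf
    for p in pts:
        if p.ya_star > best_ya + 1e-9:
            front.append(p)
            best_ya = p.ya_star
    return front


def pareto_front_from_evaluator(evaluator, space: DesignSpace | None = None,
                                t_step: float = 3.0, eps_tol: float = 0.5,
                                n_weights: int = 11, maxiter: int = 100,
                                anchors: tuple[ParetoPoint, ParetoPoint] | None = None,
                                ) -> list[ParetoPoint]:
    """Three-stage front construction over an arbitrary (X0,S0) -> (t*,Ya*) map."""
    space = space or DesignSpace()
    bounds = space.bounds
    if anchors is None:
        anchors = anchor_points(evaluator, space, maxiter=maxiter)
    a_yield, a_time = anchors
    big = 1e9
    candidates: list[ParetoPoint] = [a_yield, a_time]

    # weighted-sum sweep (convex portion); each solve warm-starts from the
    # previous weight's solution, walking the front from the max-yield anchor
    t_ref = max(a_yield.t_star, 1e-9)
    y_ref = max(a_yield.ya_star, 1e-9)
    warm = [a_yield.x0, a_yield.s0_mM]
    for w in np.linspace(0.0, 1.0, n_weights):
        def scal(z, w=w):
            try:
                t, y = evaluator(z[0], z[1])
            except InfeasibleDesignError:
                return big
            return w * t / t_ref - (1.0 - w) * y / y_ref
        res = _multistart(scal, bounds, [warm, _center(bounds)], maxiter)
        if res is not None and res.fun < big:
            t, y = evaluator(*res.x)
            candidates.append(ParetoPoint(res.x[0], res.x[1], t, y, "weighted_sum"))
            warm = list(res.x)

    # epsilon-constraint sweep over the time grid (non-convex remainder):
    # maximize Ya* while pinning t* to the grid value within eps_tol
    grid = epsilon_grid(a_time.t_star, a_yield.t_star, t_step)
    rho = 100.0 / max(eps_tol, 1e-6)
    warm = [a_time.x0, a_time.s0_mM]
    for t_target in grid:
        def pen(z, t_target=t_target):
            try:
                t, y = evaluator(z[0], z[1])
            except InfeasibleDesignError:
                return big
            excess = max(abs(t - t_target) - eps_tol, 0.0)
            return -y + rho * (excess ** 2 + abs(t - t_target) * 1e-3)
        res = _multistart(pen, bounds, [warm, _center(bounds)], maxiter)
        if res is None or res.fun >= big:
            continue  # infeasible grid value: skip
        t, y = evaluator(*res.x)
        if abs(t - t_target) <= 2 * eps_tol:
            candidates.append(ParetoPoint(res.x[0], res.x[1], t, y, "eps_constraint"))
            warm = list(res.x)

    return nondominated(candidates)


def pareto_front(params: KineticParameters, space: DesignSpace | None = None,
                 t_step: float = 3.0, eps_tol: float = 0.5,
                 n_weights: int = 11, maxiter: int = 100,
                 solver: SolverOptions | None = None) -> list[ParetoPoint]:
    """Yield-versus-time Pareto front of batch designs under one model."""
    space = space or DesignSpace()
    ev = make_evaluator(params, space, solver)
    return pareto_front_from_evaluator(ev, space, t_step=t_step, eps_tol=eps_tol,
                                       n_weights=n_weights, maxiter=maxiter)
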