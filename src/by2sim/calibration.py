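"""Parameter identification, bootstrap confidence intervals, error metrics.

The calibration objective is a weighted relative least-squares sum over
experiments, sampling times and responses,

    Q(theta) = sum_h sum_t sum_r w_r * (1 - g_r(theta; t) / y_htr)^2,

minimized subject to box bounds and the linear inequalities KI_r >= K_r that
enforce saturation plateaus.  Confidence intervals come from a residual-style
non-parametric bootstrap: per-response measurement-uncertainty entries
(u0_r + u%_r * y) are resampled with replacement, given a random sign, added
to the fitted model prediction, and the model is refitted on each synthetic
dataset; the CI is the percentile interval (default 90 %).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .kinetics import KineticParameters, STATE_VARS
from .process_sim import ExperimentDesign, SimulationError, SolverOptions, simulate

__all__ = [
    "TimeSeriesDataset",
    "FitProblem",
    "FitResult",
    "ConfigurationError",
    "UndefinedMetricError",
    "predict_responses",
    "objective",
    "fit",
    "error_matrix",
    "bootstrap_ci",
    "mae",
    "nmae",
    "mae_subset",
    "grand_mean",
]

#: Objective value returned when a simulation fails at a trial point, so
#: optimizers can continue past pathological parameter regions.
SIMULATION_PENALTY = 1.0e6


class ConfigurationError(ValueError):
    """A dataset/problem is missing information the operation requires."""


class UndefinedMetricError(ValueError):
    """Requested a quality measure on an empty response."""


@dataclass
class TimeSeriesDataset:
    """Measured (or synthetic) time series of one fermentation run.

    ``times``/``values`` map each response symbol (X, S, F, G, A, N, P) to
    aligned arrays; values are in internal units (g/L).  ``noise`` carries the
    per-response uncertainty components (u0, u%) used to reconstruct the
    error matrix.
    """

    label: str
    design: ExperimentDesign | None
    times: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    noise: object | None = None  # NoiseSpec-like: has .sigma(response, value)

    def __post_init__(self) -> None:
        for r in self.times:
            t = np.asarray(self.times[r], dtype=float)
            y = np.asarray(self.values[r], dtype=float)
            if t.shape != y.shape:
                raise ValueError(f"times/values mismatch for response {r}")
            if np.any(y < 0):
                raise ValueError(f"negative measurement in response {r}")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"times must be strictly increasing ({r})")
            if self.design is not None and t.size and (
                    t[0] < 0 or t[-1] > self.design.duration + 1e-9):
                raise ValueError(f"times outside design duration ({r})")
            self.times[r], self.values[r] = t, y

    @property
    def responses(self) -> tuple[str, ...]:
        return tuple(self.times)

    def n_observations(self, responses: Sequence[str] | None = None) -> int:
        rs = responses or self.responses
        return int(sum(self.times[r].size for r in rs if r in self.times))

    def with_values(self, values: Mapping[str, np.ndarray]) -> "TimeSeriesDataset":
        return dataclasses.replace(self, values={r: np.asarray(v, dtype=float)
                                                 for r, v in values.items()})


def _default_responses(variant: str) -> tuple[str, ...]:
    return (("X", "S", "F", "G", "A", "N", "P") if variant == "improved"
            else ("X", "S", "A", "N", "P"))


@dataclass
class FitProblem:
    """A constrained weighted least-squares identification problem.

    ``free`` selects the subset of the parameter vector to fit (all names by
    default); fixed entries keep their ``base_params`` values.  ``floor``
    guards the relative residual against division by near-zero measurements:
    observations below the floor (default: the response's constant
    uncertainty u0 if positive, else 1e-6) are excluded from Q.
    """

    datasets: list[TimeSeriesDataset]
    base_params: KineticParameters
    free: tuple[str, ...] | None = None
    responses: tuple[str, ...] | None = None
    weights: Mapping[str, float] | None = None
    bounds: Mapping[str, tuple[float, float]] | None = None
    floor: Mapping[str, float] | None = None
    solver: SolverOptions | None = None

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ConfigurationError("FitProblem needs at least one dataset")
        if self.free is None:
            self.free = tuple(self.base_params.NAMES)
        else:
            self.free = tuple(self.free)
            unknown = set(self.free) - set(self.base_params.NAMES)
            if unknown:
                raise ConfigurationError(f"unknown free parameters: {sorted(unknown)}")
        if self.responses is None:
            self.responses = _default_responses(self.base_params.variant)
        else:
            self.responses = tuple(self.responses)
        if self.weights is not None:
            for r, w in self.weights.items():
                if w < 0:
                    raise ConfigurationError(f"weight for {r} must be >= 0")
        for ds in self.datasets:
            if ds.design is None:
                raise ConfigurationError(f"dataset {ds.label!r} has no design")

    def weight(self, response: str) -> float:
        return 1.0 if self.weights is None else float(self.weights.get(response, 1.0))

    def bounds_array(self) -> list[tuple[float, float]]:
        src = self.bounds or self.base_params.BOUNDS
        return [tuple(src[n]) for n in self.free]

    def floor_for(self, ds: TimeSeriesDataset, response: str) -> float:
        if self.floor is not None and response in self.floor:
            return float(self.floor[response])
        if ds.noise is not None:
            u0 = getattr(ds.noise, "u0", {}).get(response, 0.0)
            if u0 > 0:
                return float(u0)
        return 1e-6

    def assemble(self, x: np.ndarray) -> KineticParameters:
        """Full parameter object from a free-parameter vector."""
        return self.base_params.with_values(self.free, x)

    def constraint_functions(self) -> list[Callable[[np.ndarray], float]]:
        """KI - K >= 0 inequalities involving at least one free parameter."""
        funs = []
        for k, ki in self.base_params.INHIBITION_PAIRS:
            if k in self.free or ki in self.free:
                def gap(x, k=k, ki=ki):
                    p = self.assemble(x)
                    return getattr(p, ki) - getattr(p, k)
                funs.append(gap)
        return funs


@dataclass
class FitResult:
    """Outcome of a (multistart) identification run."""

    params: KineticParameters
    q: float
    problem: FitProblem
    free: tuple[str, ...]
    diagnostics: list[dict] = field(default_factory=list)
    ci: pd.DataFrame | None = None

    @property
    def constraint_active(self) -> dict[str, bool]:
        return self.params.constraint_activity()

    def residuals(self) -> dict[str, dict[str, np.ndarray]]:
        """Per-dataset, per-response raw residuals y - g at the optimum."""
        out = {}
        for ds in self.problem.datasets:
            g = predict_responses(self.params, ds.design, ds.times,
                                  self.problem.solver)
            out[ds.label] = {r: ds.values[r] - g[r] for r in g}
        return out

    def to_frame(self) -> pd.DataFrame:
        """Parameter report mirroring the published layout."""
        rows = []
        bounds = self.problem.bounds or self.params.BOUNDS
        act = self.constraint_active
        inv = {}
        for k, ki in self.params.INHIBITION_PAIRS:
            inv[ki] = f"{ki}>={k}"
        for name in self.params.NAMES:
            lo, hi = bounds[name]
            row = dict(parameter=name, optimum=getattr(self.params, name),
                       bound_min=lo, bound_max=hi,
                       ci_low=np.nan, ci_high=np.nan,
                       constraint_active=act.get(inv.get(name, ""), False))
            rows.append(row)
        frame = pd.DataFrame(rows).set_index("parameter")
        if self.ci is not None:
            for name, r in self.ci.iterrows():
                frame.loc[name, ["ci_low", "ci_high"]] = [r["ci_low"], r["ci_high"]]
        return frame.reset_index()


def predict_responses(params: KineticParameters, design: ExperimentDesign,
                      times: Mapping[str, np.ndarray],
                      solver: SolverOptions | None = None) -> dict[str, np.ndarray]:
    """Model predictions g_r at the requested times (one simulation)."""
    traj = simulate(design, params, solver)
    out = {}
    for r, t in times.items():
        states = traj.state_at(np.asarray(t, dtype=float))
        if r == "X":
            out[r] = states[:, 0] + states[:, 1]
        else:
            out[r] = states[:, STATE_VARS.index(r)]
    return out


def objective(x, problem: FitProblem) -> float:
    """Weighted relative least-squares objective Q; finite penalty on failure."""
    params = problem.assemble(np.asarray(x, dtype=float)) \
        if not isinstance(x, KineticParameters) else x
    q = 0.0
    for ds in problem.datasets:
        used = [r for r in problem.responses if r in ds.times]
        try:
            # pathological trial parameters may overflow inside the RHS; the
            # penalty return makes that a quiet, recoverable event
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                g = predict_responses(params, ds.design,
                                      {r: ds.times[r] for r in used},
                                      problem.solver)
        except (SimulationError, ValueError, FloatingPointError):
            return SIMULATION_PENALTY
        for r in used:
            y = ds.values[r]
            ok = y >= problem.floor_for(ds, r)
            if not np.any(ok):
                continue
            rel = 1.0 - g[r][ok] / y[ok]
            q += problem.weight(r) * float(np.dot(rel, rel))
    if not np.isfinite(q):
        return SIMULATION_PENALTY
    return q


def _latin_hypercube_starts(bounds, n, seed) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    return lo + sampler.random(n) * (hi - lo)


def fit(problem: FitProblem, n_starts: int = 16, seed: int = 0,
        method: str = "SLSQP", maxiter: int = 200,
        include_base_start: bool = True) -> FitResult:
    """Multistart constrained minimization of the calibration objective.

    Starts are the base parameter values plus Latin-hypercube samples inside
    the bounds (``n_starts`` total, seeded).  Each local solve respects the
    box bounds and the KI >= K inequalities; the best feasible solution wins.
    The returned Q never exceeds the best start's Q.
    """
    bounds = problem.bounds_array()
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    cons = [{"type": "ineq", "fun": f} for f in problem.constraint_functions()]

    starts = []
    if include_base_start:
        starts.append(np.clip(problem.base_params.to_array(problem.free), lo, hi))
    n_lhs = max(n_starts - len(starts), 0)
    if n_lhs:
        starts.extend(_latin_hypercube_starts(bounds, n_lhs, seed))

    fun = lambda x: objective(x, problem)
    best_x, best_q, diags = None, np.inf, []
    for x0 in starts:
        q0 = fun(x0)
        try:
            res = minimize(fun, x0, method=method, bounds=bounds,
                           constraints=cons, options={"maxiter": maxiter})
            x1, q1, ok, msg = res.x, res.fun, bool(res.success), str(res.message)
        except Exception as exc:  # keep multistart alive
            x1, q1, ok, msg = x0, q0, False, repr(exc)
        if q1 > q0:  # a failed line search must not beat its own start
            x1, q1 = x0, q0
        x1 = np.clip(x1, lo, hi)
        diags.append(dict(x0=np.asarray(x0), q0=q0, x=x1, q=q1,
                          success=ok, message=msg))
        if q1 < best_q:
            best_x, best_q = x1, q1
    if best_x is None:
        raise RuntimeError(f"all {len(starts)} starts failed: {diags}")
    return FitResult(params=problem.assemble(best_x), q=float(best_q),
                     problem=problem, free=problem.free, diagnostics=diags)


def error_matrix(datasets: Sequence[TimeSeriesDataset]) -> dict[str, dict[str, np.ndarray]]:
    """Measurement-uncertainty entries sigma = u0_r + u%_r * y per observation."""
    out = {}
    for ds in datasets:
        if ds.noise is None:
            raise ConfigurationError(
                f"dataset {ds.label!r} carries no uncertainty specification")
        out[ds.label] = {r: np.asarray(ds.noise.sigma(r, ds.values[r]), dtype=float)
                         for r in ds.responses}
    return out


def bootstrap_ci(result: FitResult, n_boot: int = 1000, level: float = 0.90,
                 seed: int = 0, refit_n_starts: int = 1,
                 refit_maxiter: int = 100,
                 max_failure_rate: float = 0.20) -> pd.DataFrame:
    """Percentile bootstrap confidence intervals for the free parameters.

    Per response, the pooled uncertainty entries (u0 + u% * y across all
    experiments and times) are resampled with replacement and attached to a
    random sign; each resampled error matrix is added to the fitted model
    prediction to form a synthetic study, which is refitted starting from the
    optimum.  Deterministic under a fixed seed.  The resulting table is also
    attached to ``result.ci``.
    """
    problem = result.problem
    rng = np.random.default_rng(seed)
    sigma = error_matrix(problem.datasets)
    pools = {}
    for ds in problem.datasets:
        for r, s in sigma[ds.label].items():
            pools.setdefault(r, []).append(s)
    pools = {r: np.concatenate(v) for r, v in pools.items()}

    preds = {ds.label: predict_responses(result.params, ds.design, ds.times,
                                         problem.solver)
             for ds in problem.datasets}

    thetas, failures = [], 0
    for b in range(n_boot):
        synth = []
        for ds in problem.datasets:
            vals = {}
            for r in ds.responses:
                g = preds[ds.label][r]
                draw = rng.choice(pools[r], size=g.size)
                sign = rng.choice([-1.0, 1.0], size=g.size)
                vals[r] = np.maximum(g + sign * draw, 0.0)
            synth.append(ds.with_values(vals))
        sub = dataclasses.replace(problem, datasets=synth,
                                  base_params=result.params)
        try:
            res_b = fit(sub, n_starts=refit_n_starts, seed=seed + b + 1,
                        maxiter=refit_maxiter)
            thetas.append(res_b.params.to_array(problem.free))
        except RuntimeError:
            failures += 1
    n_eff = len(thetas)
    if n_eff == 0:
        raise RuntimeError("every bootstrap refit failed")
    if failures / n_boot > max_failure_rate:
        warnings.warn(f"bootstrap refit failure rate {failures / n_boot:.0%} "
                      f"exceeds {max_failure_rate:.0%}; effective n = {n_eff}")
    theta = np.vstack(thetas)
    a = 100.0 * (1.0 - level) / 2.0
    lo_q = np.percentile(theta, a, axis=0)
    hi_q = np.percentile(theta, 100.0 - a, axis=0)
    table = pd.DataFrame({
        "estimate": result.params.to_array(problem.free),
        "ci_low": lo_q, "ci_high": hi_q,
    }, index=pd.Index(problem.free, name="parameter"))
    table.attrs["effective_n"] = n_eff
    table.attrs["level"] = level
    result.ci = table
    return table


# --------------------------------------------------------------------------
# quality measures
# --------------------------------------------------------------------------

def _obs(params, ds: TimeSeriesDataset, response: str,
         solver: SolverOptions | None, mask=None):
    if response not in ds.times or ds.times[response].size == 0:
        raise UndefinedMetricError(
            f"response {response!r} has no observations in {ds.label!r}")
    y = ds.values[response]
    g = predict_responses(params, ds.design, {response: ds.times[response]},
                          solver)[response]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not np.any(mask):
            raise UndefinedMetricError(
                f"mask removes every observation of {response!r} in {ds.label!r}")
        y, g = y[mask], g[mask]
    return y, g


def mae(params: KineticParameters, dataset: TimeSeriesDataset, response: str,
        solver: SolverOptions | None = None, mask=None) -> float:
    """Mean absolute error of one response on one experiment [response units]."""
    y, g = _obs(params, dataset, response, solver, mask)
    return float(np.mean(np.abs(y - g)))


def grand_mean(datasets: Sequence[TimeSeriesDataset], response: str) -> float:
    """Mean of all measured values of a response across a normalization set."""
    vals = [ds.values[response] for ds in datasets if response in ds.times]
    if not vals:
        raise UndefinedMetricError(f"no observations of {response!r}")
    return float(np.mean(np.concatenate(vals)))


def nmae(params: KineticParameters, dataset: TimeSeriesDataset, response: str,
         normalization: Sequence[TimeSeriesDataset],
         solver: SolverOptions | None = None) -> float:
    """MAE normalized by the grand mean of the response over ``normalization``."""
    return mae(params, dataset, response, solver) / grand_mean(normalization, response)


def mae_subset(params: KineticParameters, datasets: Sequence[TimeSeriesDataset],
               response: str, solver: SolverOptions | None = None,
               masks: Mapping[str, np.ndarray] | None = None) -> float:
    """Pooled MAE of one response over a subset of experiments.

    Pools all (time, value) pairs across the given datasets, i.e. the mean is
    over the union of observations, not the mean of per-experiment MAEs.
    """
    num, count = 0.0, 0
    for ds in datasets:
        if response not in ds.times:
            continue
        m = masks.get(ds.label) if masks else None
        try:
            y, g = _obs(params, ds, response, solver, m)
        except UndefinedMetricError:
            continue
        num += float(np.sum(np.abs(y - g)))
        count += y.size
    if count == 0:
        raise UndefinedMetricError(f"no observations of {response!r} in subset")
    return num / count
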