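"""Stirred-tank process simulator: batch and semi-continuous operation.

Integrates either kinetic model through a batch phase and, optionally, a
semi-continuous phase in which feeding starts once the fresh-mass density
reaches a setpoint (emulating capacitance-probe control) and broth is drained
back to the starting volume at fixed intervals.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    DEFAULT_MOLAR_MASSES,
    NUTRIENT_SYMBOLS,
    STATE_VARS,
    KineticParameters,
    KineticParametersImproved,
    MediumComposition,
    MolarMassTable,
    ProcessState,
    _growth_rate_improved,
    _growth_rate_initial,
    _rhs_improved,
    _rhs_initial,
)

__all__ = [
    "FeedPolicy",
    "ExperimentDesign",
    "Trajectory",
    "SolverOptions",
    "SimulationError",
    "NoPeakError",
    "simulate",
    "peak_active_yield",
]


class SimulationError(RuntimeError):
    """Integrator failure; carries the last valid state reached."""

    def __init__(self, message: str, last_state: ProcessState | None = None):
        super().__init__(message)
        self.last_state = last_state


class NoPeakError(RuntimeError):
    """Active dry mass is still increasing at the end of the trajectory."""


@dataclass(frozen=True)
class FeedPolicy:
    """Feeding/draining protocol of the semi-continuous process.

    The feed engages when the fresh mass (FM = dry mass * ``fm_per_dm``)
    reaches ``trigger_fm`` and thereafter holds the dry-mass density at the
    setpoint; broth is drained back to the starting volume every
    ``drain_interval`` hours.
    """

    mode: str = "batch_only"  # or "semi_continuous"
    trigger_fm: float = 100.0      # g/L fresh mass
    fm_per_dm: float = 20.0        # g FM per g DM
    drain_interval: float = 24.0   # h
    feed_medium: MediumComposition = field(default_factory=MediumComposition)
    v_max: float | None = None     # L
    v_start: float | None = None   # L; defaults to the design's initial volume

    def __post_init__(self) -> None:
        if self.mode not in ("batch_only", "semi_continuous"):
            raise ValueError(f"unknown feed mode {self.mode!r}")
        if self.trigger_fm <= 0:
            raise ValueError("trigger_fm must be positive")
        if self.mode == "semi_continuous" and not (22.0 <= self.drain_interval <= 26.0):
            raise ValueError("drain_interval must lie in [22, 26] h")
        if self.v_start is not None and self.v_max is not None and self.v_start > self.v_max:
            raise ValueError("v_start must not exceed v_max")


@dataclass
class ExperimentDesign:
    """A fully specified fermentation run: initial state, protocol, sampling."""

    label: str
    variant: str  # "initial" | "improved"
    initial: ProcessState
    duration: float  # h
    feed: FeedPolicy = field(default_factory=FeedPolicy)
    sampling_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if self.variant not in ("initial", "improved"):
            raise ValueError(f"unknown model variant {self.variant!r}")
        if self.initial.Xd != 0.0:
            raise ValueError("initial dead dry mass must be zero")
        st = np.asarray(self.sampling_times, dtype=float)
        if st.size and (np.any(np.diff(st) <= 0) or st[0] < 0 or st[-1] > self.duration):
            raise ValueError("sampling times must be sorted within [0, duration]")
        self.sampling_times = st


@dataclass(frozen=True)
class SolverOptions:
    """Integrator settings; stiff-capable defaults with event detection."""

    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10
    grid_step: float = 0.5  # h, spacing of the dense output grid


@dataclass
class Trajectory:
    """Dense simulated trajectory with an event log.

    ``states`` has one row per grid time, columns in ``STATE_VARS`` order.
    ``state_at`` interpolates through the underlying ODE solution segments,
    so sampled values are solver-accurate, not linear interpolants.
    """

    times: np.ndarray
    states: np.ndarray
    events: list[tuple[float, str]] = field(default_factory=list)
    _segments: list[tuple[float, float, object]] = field(
        default_factory=list, repr=False)

    def state_at(self, t) -> np.ndarray:
        """Interpolated state vector(s) at time(s) ``t`` (shape (..., 9))."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tq = np.atleast_1d(t)
        out = np.empty((tq.size, len(STATE_VARS)))
        starts = [s[0] for s in self._segments]
        for i, ti in enumerate(tq):
            if ti < self.times[0] - 1e-9 or ti > self.times[-1] + 1e-9:
                raise ValueError(f"time {ti} outside trajectory range")
            k = max(0, bisect.bisect_right(starts, ti) - 1)
            t0, t1, sol = self._segments[k]
            out[i] = np.maximum(sol(np.clip(ti, t0, t1)), 0.0)
        return out[0] if scalar else out

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(name)]

    @property
    def total_dm(self) -> np.ndarray:
        return self.column("Xa") + self.column("Xd")

    def to_frame(self, mm: MolarMassTable = DEFAULT_MOLAR_MASSES) -> pd.DataFrame:
        """Tidy wide table: time, volume, biomass and nutrients in g/L and mM."""
        d = {"time_h": self.times, "volume_L": self.column("V"),
             "Xa_gL": self.column("Xa"), "Xd_gL": self.column("Xd"),
             "X_gL": self.total_dm}
        for sym in NUTRIENT_SYMBOLS:
            c = self.column(sym)
            d[f"{sym}_gL"] = c
            d[f"{sym}_mM"] = mm.to_reported(c, sym)
        return pd.DataFrame(d)


def _make_rhs(params: KineticParameters, feed_rate, feed_medium: MediumComposition):
    """Build f(t, y) with a state-dependent feed-rate law."""
    improved = isinstance(params, KineticParametersImproved)
    core = _rhs_improved if improved else _rhs_initial

    def f(t, y):
        Ft = feed_rate(t, y)
        return core(y, params, Ft, feed_medium)

    return f


def simulate(design: ExperimentDesign, params: KineticParameters,
             solver: SolverOptions | None = None) -> Trajectory:
    """Integrate a design under the given kinetic parameters.

    Batch phase runs with zero feed.  Under a semi-continuous policy, feeding
    starts when FM = (Xa + Xd) * fm_per_dm crosses the trigger; the feed rate
    then holds total dry mass at the setpoint (Ft = mu*Xa*V / X_set, floored
    at zero and shut off at v_max).  Every ``drain_interval`` hours after feed
    start, well-mixed broth is removed instantaneously to restore the starting
    volume (concentrations continuous, volume drops).
    """
    solver = solver or SolverOptions()
    if isinstance(params, KineticParametersImproved) and (
            params.delta_A is None or params.delta_P is None):
        params = params.with_deltas_from(design.initial)
    # design.variant annotates which model the experiment was planned for
    # (and which responses were recorded); the dynamics follow the parameter
    # object, so either model can be run on any design, as model comparison
    # requires.

    pol = design.feed
    x_set = pol.trigger_fm / pol.fm_per_dm
    v_start = pol.v_start if pol.v_start is not None else design.initial.V
    growth = (_growth_rate_improved
              if isinstance(params, KineticParametersImproved)
              else _growth_rate_initial)

    def feed_off(t, y):
        return 0.0

    def feed_on(t, y):
        if pol.v_max is not None and y[8] >= pol.v_max:
            return 0.0
        return max(growth(y, params) * y[0] * y[8] / x_set, 0.0)

    rhs_batch = _make_rhs(params, feed_off, pol.feed_medium)
    rhs_feed = _make_rhs(params, feed_on, pol.feed_medium)

    segments: list[tuple[float, float, object]] = []
    events: list[tuple[float, str]] = []

    def integrate(f, t0, t1, y0, ev=None):
        sol = solve_ivp(f, (t0, t1), y0, method=solver.method, rtol=solver.rtol,
                        atol=solver.atol, dense_output=True, events=ev)
        if not sol.success:
            last = ProcessState.from_vector(sol.y[:, -1], t=sol.t[-1])
            raise SimulationError(f"integration failed at t={sol.t[-1]:.2f} h: "
                                  f"{sol.message}", last_state=last)
        return sol

    y0 = design.initial.as_vector()
    t_end = design.duration

    if pol.mode == "semi_continuous":
        def fm_trigger(t, y):
            return (y[0] + y[1]) * pol.fm_per_dm - pol.trigger_fm
        fm_trigger.terminal = True
        fm_trigger.direction = 1.0
        sol = integrate(rhs_batch, 0.0, t_end, y0, ev=fm_trigger)
        t_feed = sol.t[-1]
        segments.append((0.0, t_feed, sol.sol))
        y = sol.y[:, -1].copy()
        if sol.status == 1:  # trigger crossed before the end
            events.append((t_feed, "feed_start"))
            t0 = t_feed
            k = 1
            while t0 < t_end - 1e-9:
                t1 = min(t_feed + k * pol.drain_interval, t_end)
                sol = integrate(rhs_feed, t0, t1, y)
                segments.append((t0, t1, sol.sol))
                y = sol.y[:, -1].copy()
                if t1 < t_end - 1e-9 and y[8] > v_start:
                    y[8] = v_start  # instantaneous drain to the start volume
                    events.append((t1, "drain"))
                t0, k = t1, k + 1
    else:
        sol = integrate(rhs_batch, 0.0, t_end, y0)
        segments.append((0.0, t_end, sol.sol))

    grid = np.arange(0.0, t_end, solver.grid_step)
    grid = np.unique(np.concatenate([grid, [t_end], [t for t, _ in events]]))
    traj = Trajectory(times=grid, states=np.empty((grid.size, len(STATE_VARS))),
                      events=events, _segments=segments)
    traj.states[:] = traj.state_at(grid)
    return traj


def peak_active_yield(traj: Trajectory, X0: float | None = None,
                      slope_tol: float = 1e-8) -> tuple[float, float]:
    """Locate the peak of active dry mass and the dimensionless yield there.

    Returns ``(t_star, Ya_star)`` where ``t_star`` is the time of the first
    maximum of Xa (refined by a quadratic fit through the bracketing grid
    points) and ``Ya_star = Xa(t_star) / X0``; ``X0`` defaults to the initial
    total dry mass.  Raises :class:`NoPeakError` if Xa is still rising at the
    end of the trajectory.
    """
    t = traj.times
    xa = traj.column("Xa")
    if X0 is None:
        X0 = traj.total_dm[0]
    if X0 <= 0:
        raise ValueError("X0 must be positive")
    i = int(np.argmax(xa))
    if i == t.size - 1:
        # still increasing at the horizon?
        slope = (xa[-1] - xa[-2]) / (t[-1] - t[-2])
        if slope > slope_tol * max(xa[-1], 1.0):
            raise NoPeakError("active dry mass still increasing at the end of "
                              "the trajectory (extrapolation_failed)")
        return float(t[-1]), float(xa[-1] / X0)
    if i == 0:
        return float(t[0]), float(xa[0] / X0)
    # quadratic refinement on the three bracketing grid points
    t1, t2, t3 = t[i - 1], t[i], t[i + 1]
    f1, f2, f3 = xa[i - 1], xa[i], xa[i + 1]
    denom = (f1 - 2.0 * f2 + f3)
    if denom == 0.0 or not (t3 - t2 == t2 - t1):
        # non-uniform spacing near events: full 3-point parabola vertex
        A = np.array([[t1 ** 2, t1, 1.0], [t2 ** 2, t2, 1.0], [t3 ** 2, t3, 1.0]])
        a, b, _ = np.linalg.solve(A, np.array([f1, f2, f3]))
        t_star = t2 if a == 0 else -b / (2.0 * a)
    else:
        t_star = t2 - 0.5 * (t3 - t2) * (f3 - f1) / denom
    t_star = float(np.clip(t_star, t1, t3))
    xa_star = float(traj.state_at(t_star)[STATE_VARS.index("Xa")])
    return t_star, xa_star / X0
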