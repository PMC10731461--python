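"""Synthetic fermentation studies: model trajectories plus measurement noise.

The generator emulates the offline sampling of a bioreactor run: trajectories
are produced by a chosen kinetic model and parameter set, sampled roughly once
per day, and perturbed by a measurement error with a constant and a
proportional component (defaults: 3 % proportional for dry mass, 6 % for each
nutrient).  Nine packaged presets mirror the study designs used for model
setup (#1-#3), Pareto-optimal validation (#4, #5), non-optimal validation
(#6, #7), and single-hexose carbon sources (#8, #9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import TimeSeriesDataset
from .kinetics import (
    DEFAULT_MOLAR_MASSES,
    RESPONSES,
    KineticParameters,
    MolarMassTable,
    ProcessState,
)
from .process_sim import ExperimentDesign, FeedPolicy, SolverOptions, simulate

__all__ = [
    "NoiseSpec",
    "default_noise",
    "PRESETS",
    "preset_design",
    "generate",
    "make_study",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-uncertainty structure: sigma_r(y) = u0_r + u%_r * y.

    ``u0`` is the constant component in the response's unit; ``u_prop`` the
    proportional fraction.  Defaults: u0 = 0 everywhere, u% = 0.03 for dry
    mass and 0.06 for every nutrient.
    """

    u0: Mapping[str, float] = field(default_factory=dict)
    u_prop: Mapping[str, float] = field(
        default_factory=lambda: {r: (0.03 if r == "X" else 0.06) for r in RESPONSES})

    def __post_init__(self) -> None:
        for r, v in self.u0.items():
            if v < 0:
                raise ValueError(f"u0[{r}] must be non-negative")
        for r, v in self.u_prop.items():
            if not 0.0 <= v < 1.0:
                raise ValueError(f"u_prop[{r}] must lie in [0, 1)")

    def sigma(self, response: str, value) -> np.ndarray:
        """Error scale u0 + u% * value for a response."""
        return (self.u0.get(response, 0.0)
                + self.u_prop.get(response, 0.0) * np.asarray(value, dtype=float))


def default_noise() -> NoiseSpec:
    return NoiseSpec()


def zero_noise() -> NoiseSpec:
    return NoiseSpec(u_prop={})


#: The nine study designs: initial carbon/biomass loadings (mM and g/L DM).
#: All share 21 mM ammonium, 39 mM nitrate and 2.7 mM phosphate, and start
#: with zero dead mass.  #8/#9 replace sucrose by one hexose; their inoculum
#: is the standard 0.75 g/L DM (20 g/L FM at FM/DM = 20).
PRESETS: dict[int, dict] = {
    1: dict(S0_mM=88.0, F0_mM=0.0, G0_mM=0.0, X0=0.68),
    2: dict(S0_mM=88.0, F0_mM=0.0, G0_mM=0.0, X0=0.58),
    3: dict(S0_mM=88.0, F0_mM=0.0, G0_mM=0.0, X0=1.00),
    4: dict(S0_mM=67.0, F0_mM=0.0, G0_mM=0.0, X0=0.80),
    5: dict(S0_mM=67.0, F0_mM=0.0, G0_mM=0.0, X0=0.56),
    6: dict(S0_mM=47.0, F0_mM=0.0, G0_mM=0.0, X0=0.92),
    7: dict(S0_mM=87.0, F0_mM=0.0, G0_mM=0.0, X0=1.25),
    8: dict(S0_mM=0.0, F0_mM=151.0, G0_mM=0.0, X0=0.75),
    9: dict(S0_mM=0.0, F0_mM=0.0, G0_mM=151.0, X0=0.75),
}

#: Shared mineral initials [mM].
STANDARD_MINERALS_MM = dict(A=21.0, N=39.0, P=2.7)


def preset_design(preset: int, variant: str = "initial", duration: float = 144.0,
                  sampling_interval: float = 24.0, volume: float = 5.0,
                  feed: FeedPolicy | None = None,
                  mm: MolarMassTable = DEFAULT_MOLAR_MASSES) -> ExperimentDesign:
    """Build the batch design of one packaged study preset.

    Default duration is a 144-h (6-day) batch, sampled daily; the batch stage
    of the study runs ended when sucrose was depleted, within 6 days.
    """
    try:
        rec = PRESETS[preset]
    except KeyError:
        raise KeyError(f"unknown preset {preset}; valid ids are 1-9") from None
    initial = ProcessState(
        t=0.0, V=volume, Xa=rec["X0"], Xd=0.0,
        S=float(mm.to_internal(rec["S0_mM"], "S")),
        F=float(mm.to_internal(rec["F0_mM"], "F")),
        G=float(mm.to_internal(rec["G0_mM"], "G")),
        A=float(mm.to_internal(STANDARD_MINERALS_MM["A"], "A")),
        N=float(mm.to_internal(STANDARD_MINERALS_MM["N"], "N")),
        P=float(mm.to_internal(STANDARD_MINERALS_MM["P"], "P")),
    )
    times = np.arange(0.0, duration + 1e-9, sampling_interval)
    return ExperimentDesign(label=f"#{preset}", variant=variant, initial=initial,
                            duration=duration, feed=feed or FeedPolicy(),
                            sampling_times=times)


def _default_responses(variant: str) -> tuple[str, ...]:
    if variant == "improved":
        return ("X", "S", "F", "G", "A", "N", "P")
    return ("X", "S", "A", "N", "P")


def generate(design: ExperimentDesign, params: KineticParameters,
             noise: NoiseSpec | None = None,
             rng: np.random.Generator | int | None = 0,
             sampling_times: np.ndarray | None = None,
             responses: Sequence[str] | None = None,
             solver: SolverOptions | None = None) -> TimeSeriesDataset:
    """Simulate a design and sample it with the measurement-error structure.

    Each observation is ``max(0, g + eps)`` with ``eps ~ N(0, sigma_r(g))``
    (a zero-truncated Gaussian), drawn independently per entry.  With a fixed
    seed the output is byte-identical across calls.
    """
    noise = default_noise() if noise is None else noise
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    times = np.asarray(sampling_times if sampling_times is not None
                       else design.sampling_times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two sampling times")
    responses = tuple(responses) if responses else _default_responses(design.variant)

    traj = simulate(design, params, solver)
    states = traj.state_at(times)
    cols = {"X": states[:, 0] + states[:, 1]}
    from .kinetics import STATE_VARS
    for r in ("S", "F", "G", "A", "N", "P"):
        cols[r] = states[:, STATE_VARS.index(r)]

    values, tdict = {}, {}
    for r in responses:
        g = cols[r]
        eps = rng.normal(0.0, 1.0, size=g.shape) * noise.sigma(r, g)
        values[r] = np.maximum(g + eps, 0.0)
        tdict[r] = times.copy()
    return TimeSeriesDataset(label=design.label, design=design,
                             times=tdict, values=values, noise=noise)


def make_study(presets: Sequence[int], params: KineticParameters,
               noise: NoiseSpec | None = None, seed: int = 0,
               variant: str | None = None,
               solver: SolverOptions | None = None,
               **design_kwargs) -> list[TimeSeriesDataset]:
    """Generate one dataset per preset id, all from a single seeded stream."""
    variant = variant or params.variant
    rng = np.random.default_rng(seed)
    out = []
    for pid in presets:
        design = preset_design(pid, variant=variant, **design_kwargs)
        out.append(generate(design, params, noise=noise, rng=rng, solver=solver))
    return out
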