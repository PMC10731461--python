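"""Monod-type growth kinetics for BY-2 suspension cultures.

Two unstructured, segregated model variants describe biomass formation and
macronutrient uptake in a stirred-tank culture:

* the *initial* model: growth on sucrose with multiplicative Monod factors for
  sucrose, ammonium and nitrate, first-order phosphate drawdown, and a
  viable/dead split of the dry mass;
* the *improved* model: sucrose is not taken up directly but hydrolyzed by
  cell-wall invertases into fructose and glucose (the carbon sources actually
  consumed), and ammonium/phosphate enter the maximum specific growth rate as
  additive saturating terms so that their depletion does not zero out growth.

All concentrations are held internally in g L^-1; millimolar values appear only
at the I/O boundary (see :class:`MolarMassTable`).
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import ClassVar, Mapping

import numpy as np

__all__ = [
    "Nutrient",
    "NUTRIENT_SYMBOLS",
    "STATE_VARS",
    "RESPONSES",
    "MolarMassTable",
    "DEFAULT_MOLAR_MASSES",
    "ProcessState",
    "MediumComposition",
    "KineticParameters",
    "KineticParametersInitial",
    "KineticParametersImproved",
    "reference_params_initial",
    "reference_params_improved",
    "monod_factor",
    "growth_rate",
    "growth_rate_initial",
    "growth_rate_improved",
    "rhs",
    "rhs_initial",
    "rhs_improved",
    "to_internal",
    "to_reported",
    "hexose_yield_from_molar_masses",
    "SUCROSE_TO_HEXOSE_YIELD",
]


class Nutrient(str, enum.Enum):
    """Closed enumeration of the tracked medium macronutrients."""

    SUCROSE = "S"
    FRUCTOSE = "F"
    GLUCOSE = "G"
    AMMONIUM = "A"
    NITRATE = "N"
    PHOSPHATE = "P"

    @classmethod
    def coerce(cls, key: "Nutrient | str") -> "Nutrient":
        if isinstance(key, cls):
            return key
        try:
            return cls(key)
        except ValueError:
            raise KeyError(f"unknown nutrient identifier: {key!r}") from None


NUTRIENT_SYMBOLS: tuple[str, ...] = tuple(n.value for n in Nutrient)

#: Order of the integration state vector.
STATE_VARS: tuple[str, ...] = ("Xa", "Xd", "S", "F", "G", "A", "N", "P", "V")

#: Measurable responses: total dry mass plus the six nutrients.
RESPONSES: tuple[str, ...] = ("X",) + NUTRIENT_SYMBOLS


# --------------------------------------------------------------------------
# units
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MolarMassTable:
    """Molar masses [g mol^-1] bridging millimolar reporting and g/L internals.

    Defaults use the free-ion species for ammonium, nitrate and phosphate
    (assays measure the ions, not the parent salts); the table is a frozen
    value object so alternative conventions are supplied by constructing a
    new instance.
    """

    masses: Mapping[str, float] = field(
        default_factory=lambda: {
            "S": 342.30,
            "G": 180.16,
            "F": 180.16,
            "A": 18.04,
            "N": 62.00,
            "P": 94.97,
        }
    )

    def __post_init__(self) -> None:
        for sym, m in self.masses.items():
            Nutrient.coerce(sym)
            if m <= 0:
                raise ValueError(f"molar mass for {sym} must be positive, got {m}")
        # the sucrose entry must reproduce the 88 mM <-> 30 g/L equivalence
        if abs(88.0 * self.masses["S"] / 1000.0 - 30.0) > 0.5:
            raise ValueError("sucrose molar mass inconsistent with 88 mM = 30 g/L")

    def to_internal(self, c_mM: float, nutrient: Nutrient | str) -> float:
        """Convert a concentration from mM to g L^-1."""
        if np.any(np.asarray(c_mM) < 0):
            raise ValueError("concentration must be non-negative")
        return np.asarray(c_mM) * self.masses[Nutrient.coerce(nutrient).value] / 1000.0

    def to_reported(self, c_gL: float, nutrient: Nutrient | str) -> float:
        """Convert a concentration from g L^-1 to mM."""
        if np.any(np.asarray(c_gL) < 0):
            raise ValueError("concentration must be non-negative")
        return np.asarray(c_gL) * 1000.0 / self.masses[Nutrient.coerce(nutrient).value]


DEFAULT_MOLAR_MASSES = MolarMassTable()


def to_internal(c_mM, nutrient, mm: MolarMassTable = DEFAULT_MOLAR_MASSES):
    """mM -> g/L with the default molar-mass table."""
    return mm.to_internal(c_mM, nutrient)


def to_reported(c_gL, nutrient, mm: MolarMassTable = DEFAULT_MOLAR_MASSES):
    """g/L -> mM with the default molar-mass table."""
    return mm.to_reported(c_gL, nutrient)


def hexose_yield_from_molar_masses(mm: MolarMassTable = DEFAULT_MOLAR_MASSES) -> float:
    """Mass of one hexose produced per unit mass of sucrose hydrolyzed.

    One mole of sucrose yields one mole each of glucose and fructose, so the
    per-hexose mass yield is M_hexose / M_sucrose ~= 0.526.
    """
    return mm.masses["G"] / mm.masses["S"]


#: Fixed sucrose -> glucose (and -> fructose) mass conversion, never fitted.
SUCROSE_TO_HEXOSE_YIELD: float = 0.526


# --------------------------------------------------------------------------
# state and medium
# --------------------------------------------------------------------------

@dataclass
class ProcessState:
    """Instantaneous reactor state; concentrations in g L^-1, volume in L."""

    t: float = 0.0
    V: float = 1.0
    Xa: float = 0.0
    Xd: float = 0.0
    S: float = 0.0
    F: float = 0.0
    G: float = 0.0
    A: float = 0.0
    N: float = 0.0
    P: float = 0.0

    def __post_init__(self) -> None:
        if self.V <= 0:
            raise ValueError(f"volume must be positive, got {self.V}")
        for name in ("Xa", "Xd", "S", "F", "G", "A", "N", "P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def X(self) -> float:
        """Total dry mass: active plus dead."""
        return self.Xa + self.Xd

    def concentration(self, nutrient: Nutrient | str) -> float:
        return getattr(self, Nutrient.coerce(nutrient).value)

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in STATE_VARS], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float = 0.0) -> "ProcessState":
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return cls(t=t, **dict(zip(STATE_VARS, y)))


@dataclass(frozen=True)
class MediumComposition:
    """Feed-medium concentrations [g L^-1] per nutrient."""

    S: float = 0.0
    F: float = 0.0
    G: float = 0.0
    A: float = 0.0
    N: float = 0.0
    P: float = 0.0

    def __post_init__(self) -> None:
        for sym in NUTRIENT_SYMBOLS:
            if getattr(self, sym) < 0:
                raise ValueError(f"feed concentration {sym} must be non-negative")

    @classmethod
    def from_mM(cls, mm: MolarMassTable = DEFAULT_MOLAR_MASSES, **conc_mM: float) -> "MediumComposition":
        return cls(**{sym: float(mm.to_internal(c, sym)) for sym, c in conc_mM.items()})

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, sym) for sym in NUTRIENT_SYMBOLS], dtype=float)


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class KineticParameters:
    """Base class: an ordered, bounded parameter vector with KI >= K pairs."""

    #: ordered names of the fitted parameter vector (class attribute)
    NAMES: ClassVar[tuple[str, ...]] = ()
    #: per-parameter (min, max) identification bounds
    BOUNDS: ClassVar[dict[str, tuple[float, float]]] = {}
    #: (saturation, inhibition) constant pairs constrained KI >= K
    INHIBITION_PAIRS: ClassVar[tuple[tuple[str, str], ...]] = ()
    variant: ClassVar[str] = ""

    def to_array(self, names: tuple[str, ...] | list[str] | None = None) -> np.ndarray:
        names = self.NAMES if names is None else names
        return np.array([getattr(self, n) for n in names], dtype=float)

    def replace(self, **updates) -> "KineticParameters":
        return dataclasses.replace(self, **updates)

    def with_values(self, names, values) -> "KineticParameters":
        return self.replace(**dict(zip(names, np.asarray(values, dtype=float))))

    def validate(self, rtol: float = 1e-6) -> None:
        """Check non-negativity, bounds and the KI >= K constraint structure."""
        for name in self.NAMES:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
            lo, hi = self.BOUNDS[name]
            if not (lo - rtol <= v <= hi * (1 + rtol) + rtol):
                raise ValueError(f"{name}={v} outside bounds [{lo}, {hi}]")
        for k, ki in self.INHIBITION_PAIRS:
            if getattr(self, ki) < getattr(self, k) * (1 - rtol) - rtol:
                raise ValueError(f"{ki} must be >= {k}")

    def constraint_activity(self, atol: float = 1e-6, rtol: float = 5e-3) -> dict[str, bool]:
        """Whether each KI >= K inequality is active (KI ~= K) at this point."""
        out = {}
        for k, ki in self.INHIBITION_PAIRS:
            kv, kiv = getattr(self, k), getattr(self, ki)
            out[f"{ki}>={k}"] = bool(kiv - kv <= atol + rtol * max(kv, 1e-12))
        return out


@dataclass
class KineticParametersInitial(KineticParameters):
    """Parameter vector of the initial (sucrose-driven) model.

    Units: rate constants in h^-1, saturation/inhibition constants in g L^-1.
    """

    kd: float = 0.0
    mu_m: float = 0.0
    K_S: float = 1.0
    K_IS: float = 1.0
    K_A: float = 1.0
    K_IA: float = 1.0
    K_N: float = 1.0
    K_IN: float = 1.0
    mu_S: float = 0.0
    mu_A: float = 0.0
    mu_N: float = 0.0
    mu_P: float = 0.0

    NAMES: ClassVar[tuple[str, ...]] = (
        "kd", "mu_m", "K_S", "K_IS", "K_A", "K_IA", "K_N", "K_IN",
        "mu_S", "mu_A", "mu_N", "mu_P",
    )
    BOUNDS: ClassVar[dict[str, tuple[float, float]]] = {
        "kd": (0.0, 0.1),
        "mu_m": (0.0, 10.0),
        "K_S": (0.0, 100.0),
        "K_IS": (0.0, 100.0),
        "K_A": (0.0, 1.0),
        "K_IA": (0.0, 1.0),
        "K_N": (0.0, 5.0),
        "K_IN": (0.0, 5.0),
        "mu_S": (0.0, 1.0),
        "mu_A": (0.0, 1.0),
        "mu_N": (0.0, 1.0),
        "mu_P": (0.0, 1.0),
    }
    INHIBITION_PAIRS: ClassVar[tuple[tuple[str, str], ...]] = (
        ("K_S", "K_IS"), ("K_A", "K_IA"), ("K_N", "K_IN"),
    )
    variant: ClassVar[str] = "initial"


@dataclass
class KineticParametersImproved(KineticParameters):
    """Parameter vector of the improved (hydrolysis) model.

    ``delta_A``/``delta_P`` are the minimal ammonium/phosphate concentrations
    at which growth occurs; they are fixed at 10 % of the experiment's starting
    concentrations rather than fitted, and therefore live outside ``NAMES``.
    The hexose mass yields ``M_SF``/``M_SG`` are stoichiometric constants.
    """

    kd: float = 0.0
    mu_m: float = 0.0
    mu_mA: float = 0.0
    mu_mP: float = 0.0
    K_S: float = 1.0
    K_IS: float = 1.0
    K_A: float = 1.0
    K_IA: float = 1.0
    K_N: float = 1.0
    K_IN: float = 1.0
    K_F: float = 1.0
    K_IF: float = 1.0
    K_G: float = 1.0
    K_IG: float = 1.0
    alpha: float = 0.0
    mu_A: float = 0.0
    mu_N: float = 0.0
    mu_F: float = 0.0
    mu_G: float = 0.0
    mu_P: float = 0.0
    delta_A: float | None = None
    delta_P: float | None = None

    M_SF: ClassVar[float] = SUCROSE_TO_HEXOSE_YIELD
    M_SG: ClassVar[float] = SUCROSE_TO_HEXOSE_YIELD

    NAMES: ClassVar[tuple[str, ...]] = (
        "kd", "mu_m", "mu_mA", "mu_mP",
        "K_S", "K_IS", "K_A", "K_IA", "K_N", "K_IN",
        "K_F", "K_IF", "K_G", "K_IG",
        "alpha", "mu_A", "mu_N", "mu_F", "mu_G", "mu_P",
    )
    BOUNDS: ClassVar[dict[str, tuple[float, float]]] = {
        "kd": (0.0, 0.01),
        "mu_m": (0.0, 10.0),
        "mu_mA": (0.0, 10.0),
        "mu_mP": (0.0, 10.0),
        "K_S": (0.0, 100.0),
        "K_IS": (0.0, 100.0),
        "K_A": (0.0, 1.0),
        "K_IA": (0.0, 1.0),
        "K_N": (0.0, 5.0),
        "K_IN": (0.0, 5.0),
        "K_F": (0.0, 30.0),
        "K_IF": (0.0, 30.0),
        "K_G": (0.0, 30.0),
        "K_IG": (0.0, 30.0),
        "alpha": (0.0, 1.0),
        "mu_A": (0.0, 1.0),
        "mu_N": (0.0, 1.0),
        "mu_F": (0.0, 1.0),
        "mu_G": (0.0, 1.0),
        "mu_P": (0.0, 1.0),
    }
    INHIBITION_PAIRS: ClassVar[tuple[tuple[str, str], ...]] = (
        ("K_S", "K_IS"), ("K_A", "K_IA"), ("K_N", "K_IN"),
        ("K_F", "K_IF"), ("K_G", "K_IG"),
    )
    variant: ClassVar[str] = "improved"

    def with_deltas_from(self, initial: ProcessState) -> "KineticParametersImproved":
        """Fix delta_A/delta_P at 10 % of the starting A and P concentrations."""
        return self.replace(delta_A=0.1 * initial.A, delta_P=0.1 * initial.P)


def reference_params_initial() -> KineticParametersInitial:
    """Identified calibration optimum of the initial model (standard runs)."""
    return KineticParametersInitial(
        kd=6.62e-4, mu_m=9.47,
        K_S=17.64, K_IS=17.64, K_A=0.796, K_IA=0.797, K_N=0.133, K_IN=0.135,
        mu_S=2.235e-1, mu_A=4.863e-3, mu_N=3.013e-2, mu_P=2.883e-2,
    )


def reference_params_improved() -> KineticParametersImproved:
    """Identified calibration optimum of the improved (hydrolysis) model."""
    return KineticParametersImproved(
        kd=5.44e-4, mu_m=0.162, mu_mA=0.578, mu_mP=2.1e-5,
        K_S=72.53, K_IS=100.0, K_A=0.221, K_IA=0.221, K_N=0.835, K_IN=1.0,
        K_F=1.108, K_IF=1.404, K_G=18.0, K_IG=18.0,
        alpha=0.396, mu_A=6.9e-3, mu_N=1.71e-2, mu_F=8.34e-2, mu_G=0.273,
        mu_P=2.68e-2,
    )


# --------------------------------------------------------------------------
# kernels
# --------------------------------------------------------------------------

def monod_factor(c: float, K: float, KI: float) -> float:
    """Saturation-inhibition factor (c/(c+K)) * (KI/(c+KI)), in [0, 1].

    ``c`` is a substrate concentration, ``K`` the half-saturation constant and
    ``KI`` the inhibition constant (all g/L).  The product is at most 0.25
    when KI = K and approaches the plain Monod term as KI -> inf.
    """
    if c < 0 or K < 0 or KI < 0:
        raise ValueError("monod_factor arguments must be non-negative")
    if c == 0.0:
        if K == 0.0:
            raise ValueError("monod_factor undefined at c = 0, K = 0")
        return 0.0
    return (c / (c + K)) * (KI / (c + KI))


def _monod(c: float, K: float, KI: float) -> float:
    # internal kernel: clamps negative integrator excursions to zero
    if c <= 0.0:
        return 0.0
    return (c / (c + K)) * (KI / (c + KI))


def _growth_rate_initial(y: np.ndarray, p: KineticParametersInitial) -> float:
    mS = _monod(y[2], p.K_S, p.K_IS)
    mA = _monod(y[5], p.K_A, p.K_IA)
    mN = _monod(y[6], p.K_N, p.K_IN)
    return p.mu_m * mS * mA * mN


def _growth_rate_improved(y: np.ndarray, p: KineticParametersImproved) -> float:
    if p.delta_A is None or p.delta_P is None:
        raise ValueError("delta_A/delta_P unset; call with_deltas_from(initial_state)")
    A = max(y[5], 0.0)
    P = max(y[7], 0.0)
    mu_max = p.mu_m
    if p.delta_A + A > 0:
        mu_max += p.mu_mA * A / (A + p.delta_A)
    if p.delta_P + P > 0:
        mu_max += p.mu_mP * P / (P + p.delta_P)
    carbon = _monod(y[4], p.K_G, p.K_IG) + _monod(y[3], p.K_F, p.K_IF)
    return mu_max * carbon * _monod(y[6], p.K_N, p.K_IN)


def growth_rate_initial(state: ProcessState, params: KineticParametersInitial) -> float:
    """Specific growth rate [h^-1] of the initial model.

    mu = mu_m * monod(S) * monod(A) * monod(N); phosphate is deliberately
    absent from the growth law (it is depleted early, and a multiplicative
    phosphate factor would wrongly zero out growth).
    """
    return _growth_rate_initial(state.as_vector(), params)


def growth_rate_improved(state: ProcessState, params: KineticParametersImproved) -> float:
    """Specific growth rate [h^-1] of the improved model.

    mu = (mu_m + mu_mA*A/(A+delta_A) + mu_mP*P/(P+delta_P))
         * (monod(G) + monod(F)) * monod(N)
    """
    return _growth_rate_improved(state.as_vector(), params)


def growth_rate(state: ProcessState, params: KineticParameters) -> float:
    """Dispatch to the variant-appropriate growth law."""
    if isinstance(params, KineticParametersImproved):
        return growth_rate_improved(state, params)
    return growth_rate_initial(state, params)


_ZERO_FEED = MediumComposition()


def _rhs_initial(y: np.ndarray, p: KineticParametersInitial,
                 Ft: float, feed: MediumComposition) -> np.ndarray:
    Xa, Xd, S, F, G, A, N, P, V = y
    D = Ft / V
    mS = _monod(S, p.K_S, p.K_IS)
    mA = _monod(A, p.K_A, p.K_IA)
    mN = _monod(N, p.K_N, p.K_IN)
    mu = p.mu_m * mS * mA * mN
    return np.array([
        (mu - p.kd) * Xa - D * Xa,
        p.kd * Xa - D * Xd,
        D * (feed.S - S) - p.mu_S * mS * Xa,
        D * (feed.F - F),
        D * (feed.G - G),
        D * (feed.A - A) - p.mu_A * mA * Xa,
        D * (feed.N - N) - p.mu_N * mN * Xa,
        D * (feed.P - P) - p.mu_P * max(P, 0.0),
        Ft,
    ])


def _rhs_improved(y: np.ndarray, p: KineticParametersImproved,
                  Ft: float, feed: MediumComposition) -> np.ndarray:
    Xa, Xd, S, F, G, A, N, P, V = y
    D = Ft / V
    mS = _monod(S, p.K_S, p.K_IS)
    mF = _monod(F, p.K_F, p.K_IF)
    mG = _monod(G, p.K_G, p.K_IG)
    mA = _monod(A, p.K_A, p.K_IA)
    mN = _monod(N, p.K_N, p.K_IN)
    mu = _growth_rate_improved(y, p)
    hyd = p.alpha * mS * Xa  # sucrose hydrolysis flux per unit volume
    return np.array([
        (mu - p.kd) * Xa - D * Xa,
        p.kd * Xa - D * Xd,
        D * (feed.S - S) - hyd,
        D * (feed.F - F) + p.M_SF * hyd - p.mu_F * mF * Xa,
        D * (feed.G - G) + p.M_SG * hyd - p.mu_G * mG * Xa,
        D * (feed.A - A) - p.mu_A * mA * Xa,
        D * (feed.N - N) - p.mu_N * mN * Xa,
        D * (feed.P - P) - p.mu_P * max(P, 0.0),
        Ft,
    ])


def _check_rhs_inputs(state: ProcessState, Ft: float) -> None:
    if Ft < 0:
        raise ValueError("feed rate must be non-negative")
    # ProcessState validates non-negativity at construction


def rhs_initial(state: ProcessState, params: KineticParametersInitial,
                Ft: float = 0.0, feed: MediumComposition = _ZERO_FEED) -> np.ndarray:
    """Time derivative of the state vector (order ``STATE_VARS``), initial model.

    Biomass, nutrient and volume balances in concentration form; feed at rate
    ``Ft`` [L/h] dilutes every species and supplies the feed-medium
    concentrations.  Phosphate uptake is first-order in P and independent of
    the biomass.
    """
    _check_rhs_inputs(state, Ft)
    return _rhs_initial(state.as_vector(), params, Ft, feed)


def rhs_improved(state: ProcessState, params: KineticParametersImproved,
                 Ft: float = 0.0, feed: MediumComposition = _ZERO_FEED) -> np.ndarray:
    """Time derivative of the state vector, improved (hydrolysis) model.

    Sucrose leaves the medium only through invertase hydrolysis
    (alpha * monod(S) * Xa); each unit mass hydrolyzed yields ``M_SF`` mass of
    fructose and ``M_SG`` of glucose, which are consumed through their own
    Monod terms.
    """
    _check_rhs_inputs(state, Ft)
    return _rhs_improved(state.as_vector(), params, Ft, feed)


def rhs(state: ProcessState, params: KineticParameters,
        Ft: float = 0.0, feed: MediumComposition = _ZERO_FEED) -> np.ndarray:
    """Dispatch to the variant-appropriate right-hand side."""
    if isinstance(params, KineticParametersImproved):
        return rhs_improved(state, params, Ft, feed)
    return rhs_initial(state, params, Ft, feed)
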