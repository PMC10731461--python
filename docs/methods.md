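# Methods

## Models and assumptions

Both kinetic models are unstructured (no intracellular pools) and segregated
into active and dead dry mass. Active mass converts irreversibly to dead
mass at a first-order rate `kd`; dead mass takes no further part in kinetics
but is diluted by feed like every other species. The balance for dead mass,
`d(Xd·V)/dt = kd·Xa·V`, is our own closure: the published balance set fixes
only the active compartment, and conservation of the total `X = Xa + Xd`
forces this form once dead cells are assumed well mixed.

Every Monod factor pairs a saturation term with an inhibition term,
`m(c; K, KI) = (c/(c+K))·(KI/(c+KI))`, capped at 0.25 when `KI = K` and
approaching plain Monod saturation as `KI → ∞`. Calibration constrains
`KI ≥ K` per substrate so the factor has a plateau rather than a growth
optimum; at the reference optima these inequalities are active for most
substrates (`KI ≈ K`), which the fit report flags.

Model-specific choices:

* **Initial model.** Growth `mu = mu_m·m(S)·m(A)·m(N)`. Phosphate appears
  only as a tracked species with uptake `−mu_P·P·V`, deliberately
  independent of biomass: phosphate is depleted within ~90 h and a
  biomass-scaled or growth-coupled phosphate term would either destabilize
  the near-zero tail numerically or wrongly shut growth off.
* **Improved model.** Sucrose leaves the medium only through invertase
  hydrolysis at rate `alpha·m(S)·Xa·V`; each unit mass yields
  `m_SF = m_SG = 0.526` units of fructose and glucose (hexose/sucrose
  molar-mass ratio — a stoichiometric constant, never fitted). Growth runs
  on the hexoses additively, `(m(G) + m(F))`, deliberately without
  renormalization, and the mineral influence enters the maximum rate as
  additive saturating terms `mu_mA·A/(A+dA)` and `mu_mP·P/(P+dP)`. The
  offsets `dA`, `dP` are fixed at 10 % of the experiment's starting ammonium
  and phosphate concentrations (not fitted); the parameter object derives
  them from the design's initial state when unset.

Units: every concentration is g/L internally, including the saturation
constants. Millimolar values appear only at the I/O boundary through a
molar-mass table whose defaults use free-ion species for ammonium
(18.04 g/mol), nitrate (62.00) and phosphate (94.97) — assays measure the
ions, not the parent salts — while the sucrose entry is validated against
the 88 mM ↔ 30 g/L equivalence. The table is replaceable for users whose
data follow a salt convention; this choice is the single largest unresolved
unit ambiguity and shifts growth-factor magnitudes for the minerals.

## Process simulation

The simulator integrates either model with LSODA (stiff-capable; relative
tolerance 1e-8, absolute 1e-10 by default — near-zero nutrient tails are
stiff) and exposes solver-accurate interpolation through the stored dense
segments. Monod factors are evaluated at `max(c, 0)` so tiny negative
integrator excursions cannot produce spurious fluxes, and exported states
are clipped at zero.

Semi-continuous operation abstracts the capacitance-controlled feed to a
setpoint-holding law: feeding starts when fresh mass `FM = X · fm_per_dm`
(default 20 g FM per g DM) crosses the trigger (default 100 g/L FM), after
which `F_t = mu·Xa·V / X_set` holds total dry mass at the setpoint; no probe
transfer function is modeled. Drains are instantaneous, every 24 h by
default (22–26 h allowed), and restore the starting volume with
concentrations continuous across the event.

The peak of active dry mass is located on the dense grid and refined with a
three-point parabola; `Ya* = Xa(t*)/X0`. A trajectory still rising at the
horizon raises an explicit no-peak error rather than extrapolating.

## Calibration

The objective is the relative weighted least-squares sum
`Q = Σ_h Σ_t Σ_r w_r (1 − g/ỹ)²` with equal weights by default and
per-observation pooling (experiments with more samples weigh more).
Observations below a response-specific floor (the constant uncertainty `u⁰`
if positive, else 1e-6 in units) are excluded: the relative residual is
undefined at `ỹ = 0`, which late-time phosphate reaches routinely.

The problem is nonconvex, so fitting multistarts SLSQP from the base
parameter values plus Latin-hypercube samples inside the bounds (16 starts
by default, seeded); `KI ≥ K` enters as explicit inequality constraints. A
local solve that ends worse than its own start is discarded in favor of the
start, so the reported `Q` never exceeds the best start's. Simulation
failures at pathological trial points return a large finite penalty (1e6)
instead of raising, keeping the optimizer alive. Any subset of the parameter
vector can be frozen; the K/KI pairs of a multi-substrate Monod product are
weakly identified from a handful of runs (a sloppiness the tests document),
whereas the consumption rates and the overall growth scale are recoverable
to well under 1 % on noiseless synthetic studies.

Confidence intervals use a residual-style non-parametric bootstrap: the
per-response pools of uncertainty entries `u⁰_r + u%_r·ỹ` are resampled with
replacement, each resampled entry is given an independent random sign, added
to the fitted prediction `g(θ*)`, and the model is refitted (starting from
θ*) on each synthetic study; the CI is the percentile interval, 90 % by
default, deterministic under a fixed seed. Two declared choices where the
published procedure is silent: the error entries are treated as magnitudes
with Rademacher signs (adding strictly positive entries would bias every
synthetic dataset upward), and resampling pools residual entries per
response across experiments and times. Both are configurable consequences of
the implementation, not of the data. On a near-linear reduction the
percentile interval agrees with a linearized error-propagation (sandwich)
interval, and its 90 % coverage on Monte-Carlo replicates sits in the
80–98 % band.

Quality measures: `MAE` per response and experiment, `nMAE = MAE / ȳ_r` with
the grand mean taken over a declared normalization set, and a pooled-subset
variant that averages over the union of observations.

## Cross-validation

Model comparison is leave-one-experiment-out: folds are whole experiments,
never splits within a time series. Each fold refits every candidate on the
remaining runs and scores the held-out run; `aMAE` is the arithmetic mean of
fold MAEs and `anMAE` divides by the response's grand mean over all folds.
The high-density column restricts the dry-mass MAE to observations with
measured `X` above a threshold (8 g/L by default; a switch applies the
threshold to predicted `X` instead). On studies generated by the hydrolysis
model, that model's held-out `anMAE_X` beats the sucrose-only model in at
least 80 % of seeded replicates — the directional signature the comparison
is designed to detect.

## Design optimization

The bi-criteria problem maximizes `Ya*` and minimizes `t*` over inoculum
`X0 ∈ [0.3, 1.5] g/L` and initial sucrose `S0 ∈ [17, 88] mM`, with the
remaining initials fixed (21 mM ammonium, 39 mM nitrate, 2.7 mM phosphate,
no hexoses, no dead mass). Optimization-stage simulations run batch-only
with a 500 h horizon: the quantity being optimized is the batch peak, and
whether the original optimization simulated feeding is not documented — a
config switch exposes the semi-continuous alternative. The front is built in
three stages: the max-yield anchor (argmax `Ya*`), the min-time anchor
(earliest achievable interior peak), then an ε-constraint sweep over a
uniform `t*` grid between the anchors (3 h step) merged with a weighted-sum
sweep, filtered to the non-dominated set. The ε-constraint "pin `t*` to a
grid value" is enforced by penalty with a 0.5 h tolerance; inner solves are
bounded Nelder-Mead, warm-started along the front plus corner/center
multistarts. Weighted sums recover only the convex portion of a front, so
the ε-sweep is what populates non-convex arcs; the tests exercise this on an
analytic sigmoid landscape where the distinction is provable. An alternative
end-concentration objective `Xa(t*)` is pluggable but unvalidated.

With the packaged reference calibration of the initial model this
reproduces the published endpoints: `(t*, Ya*) ≈ (183 h, 30.5)` at
`(X0, S0) = (0.3 g/L, 88 mM)` against the printed `(185 h, 27.9)` (the yield
sits ~9 % high, within the printed-parameter rounding and ion-vs-salt unit
slack), and a minimum peak time of ~101.5 h at `X0 = 1.5 g/L` against the
printed 102 h. The published narrative also mentions ~96 h from the
anchor-stage estimate; both figures are surfaced rather than reconciled,
and the endpoint value is the one the implementation reports.

## Synthetic studies

The generator emulates the nine study designs (initial sucrose/hexose and
inoculum loadings; shared minerals) sampled every 24 h over a 144 h batch —
six days, the span in which sucrose is depleted in the real runs. The two
hexose-only designs carry no published inoculum; the package uses the
standard 0.75 g/L DM (20 g/L FM at FM/DM = 20). Measurement error is an
independent zero-truncated Gaussian per entry with scale `u⁰ + u%·g`
(defaults `u⁰ = 0`, `u% = 0.03` for dry mass, 0.06 per nutrient — the
summary percentages; the per-assay constant components are not public).
The Gaussian shape is a choice; only the scale structure is documented.

What the generator does *not* emulate: autocorrelated probe drift, assay
detection limits, irregular sampling, inoculum variability between runs, or
model-structure error (data are generated by the same family being fitted,
minus whichever terms a study switches off). Passing tests therefore
demonstrate correctness of the machinery and internal consistency of the
workflow, not field accuracy of either model on new cultures.

## Numerical choices and scales

* Integrator LSODA, rtol 1e-8 / atol 1e-10 defaults; the suite runs most
  simulations at rtol 1e-6 / atol 1e-8, at which peak location and yield are
  stable to well under 0.1 % against halved tolerances.
* Peak refinement: parabola through the bracketing grid points (0.5 h grid);
  monotone-decreasing trajectories peak at `t = 0`.
* Fit: SLSQP, 16 LHS starts by default; reduced-scale studies in the test
  suite use 1–2 starts and small free subsets, chosen once as the smallest
  problems that still exercise the property under test.
* Bootstrap scales: 1000 resamples for production CIs; the coverage study
  runs 50 Monte-Carlo replicates at 100 resamples on a single-rate
  reduction, and the model-comparison property runs 20 seeded replicates of
  a four-run study with two free parameters per model.
* Degenerate inputs: collapsed bounds return the collapsed point; empty
  responses raise an undefined-metric error; datasets without an uncertainty
  spec cannot build an error matrix; unsimulable trial parameters are
  penalized, not fatal.

## Known limitations

* The free-ion vs. salt unit convention for the minerals is assumed, not
  known; all mineral-linked constants inherit that assumption.
* Individual `K`/`KI` values are only weakly identified from few runs; CIs
  on them are honest but wide, and the bootstrap refits inherit the
  nonconvexity of the outer fit.
* The feed controller is an idealized setpoint law; real capacitance control
  has dynamics and noise the simulator does not represent.
* The ε-constraint solve enforces the time pin by penalty, so front points
  can sit up to ~0.5 h off their grid value.
* Hydrolysis kinetics lump invertase abundance into a single constant
  `alpha·m(S)·Xa`; high-hexose regimes (the 151 mM single-hexose designs)
  extrapolate far beyond the concentrations any packaged calibration saw.
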