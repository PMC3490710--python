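# Methods

## Model class and likelihood

`predprofile` works with state-space models

    dx/dt = f(x(t), u(t), θ),        y(t) = g(x(t), θ) + ε,   ε ~ N(0, σ²)

with known, fixed per-record noise SDs σ. The parameter vector θ comprises
kinetic parameters, free initial values and observation parameters. Under
Gaussian noise, −2 log-likelihood equals (up to a constant that cancels in
every interval construction) the weighted residual sum of squares
RSS(θ|y) = Σᵢ (yᵢ − F(tᵢ,u,θ))²/σᵢ², and maximum-likelihood estimation is
weighted least squares. Models are declared symbolically (states, parameters,
rate expressions, observation expressions, initial values); expressions are
parsed once with sympy and compiled to numpy callables, including the
analytic ODE Jacobian handed to the integrator.

σ is treated as known throughout; estimating noise parameters is out of
scope, as is any model class beyond ODEs (no delays, algebraic constraints,
events or dosing schedules). Inputs u(t) may be constant or
piecewise-constant per stimulation condition.

## Prediction and validation profiles

A prediction z = F(D_pred, θ) is any expression over states and parameters
evaluated at one time under one input condition. The prediction profile
likelihood is the constrained optimum

    −2 PPL(z) = min { RSS(θ|y) : F(D_pred, θ) = z },

and the prediction confidence interval (PCI) at level α is the sublevel set
{z : −2 PPL(z) ≤ −2 LL* + icdf(χ²₁, α)}. The validation profile likelihood
treats a hypothetical future measurement with error SD as one extra data
point,

    −2 VPL_SD(z) = min_θ [ RSS(θ|y) + (z − F(D_vali,θ))²/SD² ],

whose sublevel set (VCI) covers the outcome of a *noisy* validation
experiment and always contains the PCI.

The default PPL route is penalized: the VPL scan is run with a small penalty
SD_c (10⁻³ of the prediction scale, where prediction scale =
max(|F(D_pred, θ̂)|, data scale)), and at each scan optimum θ\* the data-only
RSS is recorded together with the fitted response z′ = F(D_vali, θ\*). At the
penalized optimum the penalty gradient is exactly the Lagrange multiplier of
the equality-constrained problem, so the data-only RSS *is* −2 PPL(z′); on
the −2 LL scale the identity reads

    −2 PPL(z′) = −2 VPL_SD(z) − (z − z′)²/SD².

Reading off the data RSS avoids accumulating the algebraic correction
numerically. A direct equality-constrained scan (SLSQP, polished from a
penalized pre-solve so branch exchanges cannot trap it in a worse basin) is
kept as an independent cross-check of this rescaling; the two routes agree on
the chain-model fixture to well under 0.01 on the −2 LL scale.

## Optimization and scanning

* **Parameter transform.** All fitting and profiling is done in natural-log
  parameter space (positivity of rates, concentrations and initial amounts);
  results are reported on the natural scale. Fitting bounds default to ±2
  orders of magnitude around the reference values.
* **Multi-start fitting.** Weighted least squares (scipy TRF) from the
  reference guess plus Latin-hypercube starts in the log-box; the number of
  starts and the seed are explicit arguments, and identical seeds reproduce
  the fit exactly.
* **Finite differences.** Jacobians use a 2-point scheme with an *absolute*
  step of 10⁻⁵ in log-space. A relative step collapses for parameters near 1
  (log value near 0) and at the scipy default of ~10⁻⁸ the difference samples
  ODE-integration error rather than gradient.
* **Adaptive scan.** Each profile marches outward from the fitted prediction;
  the step adapts so one step raises −2 PL by about one fifth of the
  threshold (clamped between 10⁻⁵ and 0.5 of the prediction scale), and each
  point is warm-started from its neighbor's optimum. A side stops when the
  profile exceeds threshold + margin (default margin 1.0), when 200 steps or
  the plausibility window (10× the prediction scale) are exhausted — which
  flags the side *unbounded* — or when the constraint becomes infeasible,
  which bounds the side at the feasibility edge without an unbounded flag.
  A step that overshoots the feasible region is retried at a quarter of the
  length, so feasibility edges are localized rather than detected by
  accident.
* **Backward refinement.** After a side completes, every point is re-solved
  warm-started from its *outer* neighbor and the lower value kept. Warm
  chains can switch likelihood branches mid-scan (the chain model's two rate
  constants are exchangeable when only C is observed, so the profile is the
  lower envelope of two branches); the sweep restores that envelope, and the
  march resumes if the threshold crossing dissolves. If the sweep finds a
  point below the fitted optimum, the improved value becomes the reference
  for thresholding.
* **Crossing localization.** Interval bounds come from a local quadratic
  through the outermost bracketing pair and the next inner point (linear
  fallback on degenerate configurations); on non-monotone sides the
  outermost crossing is taken, which errs on the conservative side.
* **Feasibility semantics.** A scan point whose penalty exceeds 50× the stop
  level cannot be reached by the model response at all. If the stalled
  parameters sit strictly inside the fitting box, or the stall is adjacent to
  zero for a concentration-like prediction, the side ends at a structural
  boundary (e.g. positivity: intervals for concentrations never extend below
  0); a stall pinned at the fitting box far from zero means the box — not
  the model — stopped the scan, and the side counts as unbounded.
  A prediction the model pins completely (e.g. an initial value fixed at 0
  for every θ) collapses to a degenerate zero-width interval.
* **Integration.** LSODA (via `scipy.integrate.odeint`) with the analytic
  Jacobian; default tolerances rtol 10⁻⁸ / atol 10⁻¹⁰, chosen so the
  objective is smooth far below the χ² threshold scale. Models may override
  them: the MAPK fixture uses rtol = atol = 10⁻⁷ since its states are of
  order 100 nM. Integration failure raises an explicit error carrying the
  failing θ; during optimization such points get a large constant residual
  so the optimizer retreats, and the failure count is tracked (a scan with
  more than 20% failed points is marked unreliable).

## Thresholds

The asymptotic threshold is the χ²₁ α-quantile (exact for models linear in
θ). The Monte-Carlo alternative is a parametric bootstrap at θ̂: simulate
replicate datasets, refit, evaluate the profile statistic
−2(PPL(z_gen) − LL\*) at the generating prediction, and take the empirical
α-quantile. At least 100 replicates are required (default 500); on the
linear fixture the bootstrap quantile agrees with χ²₁ within its own
sampling error, which is the only oracle available for it here.

## Observability, bands and coverage

A per-state confidence band strings the per-time PCIs (or VCIs) together;
bounds between profiled times are interpolated with a monotone-preserving
piecewise cubic (PCHIP) so the band cannot overshoot between knots, and
segments touching an unbounded knot are left open. *Practical observability*
of a state is a bounded band: one unbounded time point renders the state
non-observable, with the offending times and sides reported (a zero-width
interval — an initial condition fixed by the model — is bounded, hence never
offending).

Coverage studies verify frequentist calibration: per replicate, data are
simulated at θ_true with fresh noise, fitted (warm-started at θ_true with 5%
log-normal jitter, with a 5-start fallback whenever the fit lands above the
expected RSS range n + 6√(2n)), the profile is scanned and membership of the
true response (prediction mode) or of an independently drawn noisy
validation point (validation mode) is recorded. Per-replicate seeds derive
from the master seed through a counter-based `SeedSequence`, so replicates
are independent and individually reproducible. The hit frequency is reported
with an exact (Clopper–Pearson) 95% binomial interval; replicate-level fit
failures are excluded and counted, and more than 10% failures invalidates
the study.

Design ranking orders (state, time) conditions by interval width, widest
first with unbounded entries on top: wide intervals mark conditions weakly
specified by the current data, i.e. the most informative next measurements.

## Synthetic fixtures — what they emulate and what they do not

* **Chain model** A→B→C (rates 0.05, 0.1; A(0)=1 free; B(0)=C(0)=0), C
  observed at t=0,10,…,100 with σ=0.1 (≈10% signal-to-noise, typical of
  cell-biology time courses). The short design t=0,2,…,20 samples only the
  transient rise of C, leaving the concentration scale practically
  non-identifiable — the canonical non-observability setting. The closed-form
  solution serves as the integration oracle.
* **MAPK cascade**: eight states (Raf, Raf\*, Mek, Mek\*, Mek\*\*, Erk,
  Erk\*, Erk\*\*), Michaelis–Menten kinetics, negative feedback of Erk\*\* on
  Raf activation, phospho-sums observed at t=0,100,…,1000 s with σ=10 nM.
  The rate-law values follow the published parameterization of the classic
  oscillatory feedback cascade (totals 100/300/300 nM, 10% pre-activated
  initial state); the 14 free parameters are the rate-law constants with the
  consecutive phosphorylation and dephosphorylation steps of Mek and Erk
  sharing parameters, and initial concentrations fixed. Results on this
  fixture are single-noise-realization and parameterization-dependent:
  checks on it are rank-based and order-of-magnitude by design.
* **Linear regression** y = θ·t wrapped as a one-state ODE, giving fully
  analytic estimator, curvature and interval formulas — the exactness oracle
  for fitting, profiling, rescaling, thresholds and coverage.

Synthetic data are i.i.d. Gaussian perturbations of the exact model response
with known σ. Real data violate several of these assumptions —
misspecified noise models, correlated errors, systematic (structural) model
error, unknown σ — so passing tests here demonstrate the *statistical*
correctness of the constructions under the stated model, not robustness to
misspecification.

## Problem sizes used in the shipped studies

The calibration study runs 200 noise replicates of the full chain design at
α=0.9; the exact binomial 95% interval at that size spans roughly ±4
percentage points. Observability runs profile all three chain states at the
11 design times of each design. The MAPK study uses a reduced grid of 3
states × 6 times (including the feedback-activation window around t≈181 s)
with a slightly coarser scan (step ≈ threshold/3); widths there are read at
the profiled times.

## Known limitations

* Profiles are point-wise: bands over time are unions of per-time intervals,
  not simultaneous confidence regions; joint profiles for several predictions
  are not implemented.
* The Monte-Carlo threshold is the generic parametric-bootstrap quantile;
  no small-sample correction beyond it is attempted.
* Non-observability verdicts depend on the declared fitting box and
  plausibility window; both are configurable and reported with the scan
  status, but a genuinely flat profile can only ever be followed to a finite
  scan limit.
* σ must be known; weighted fits with estimated variance components are out
  of scope.
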