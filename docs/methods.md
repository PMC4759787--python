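# Methods

## The single-site model

A site of DNA damage is described by the Markov jump process on
(X, Y, Z, Q) defined in `dsbkin.model_core` (see the README for the event
table). The modelling assumptions are:

* **Telegraph damage signal.** X switches 1→0 once and, in the baseline
  model, never back; repair requires bound repair molecules (propensity
  k₁·Y·X), so a site with no recruited pATM cannot repair.
* **One effective diffusible species.** All diffusible repair factors that
  bind the site (pATM, ATR, DNA-PKcs, …) are lumped into Y; recruitment and
  activation are treated as a single step because phosphorylation is much
  faster than recruitment.
* **Positive feedback.** Y phosphorylates H2AX (k₅·Y) and is itself
  recruited by γH2AX (k₃·Z) as well as directly by the break (k₂·X, which
  stops on repair while the γH2AX-driven route continues).
* **No pool depletion.** Unphosphorylated H2AX is abundant, so Z and Y are
  unbounded non-negative counts; the per-focus totals Y_max = 300 and
  Z_max = 1000 from the fitting assumptions are *observation-layer*
  quantities (soft penalty and focus normalisation respectively), not hard
  caps on the stochastic dynamics — no capping rule is part of the process
  definition, and the fitted rates keep excursions well below them.
* **Inert antibody complex.** Anti-γH2AX-TAT binds free γH2AX reversibly
  (k₈·[TAT]₀·Z forward, k₇·Q back); bound Q is invisible to every other
  propensity, including dephosphorylation.

The post-repair (X=0, Q=0) subsystem is linear with generator
[[−k₄, k₃], [k₅, −k₆]]; it relaxes to the empty state exactly when
k₃k₅ < k₄k₆ (`stability_check` reports the margin k₄k₆ − k₃k₅). Both
shipped cell-line parameter sets satisfy it (margins 13855 and 1124 h⁻²).

## Stochastic simulation

`dsbkin.ssa` implements the direct Gillespie method with exhaustive
propensity recomputation per step (no tau-leaping: the simulator doubles
as the exactness oracle for the ODE closures). Total event rates reach
~10⁵ h⁻¹ per site at the fitted parameters, giving ~10⁶ events per
24 h trajectory for the slow-repairing cell line; the inner loops are
numba-compiled, which makes 1000-replicate ensembles a matter of seconds
to a minute. Trajectories are recorded by right-continuous step sampling
(value at t = state after the last event ≤ t). Ensembles derive one
32-bit sub-seed per replicate via `numpy.random.SeedSequence`, so results
are reproducible and independent of replicate order. Default initial
condition: (X, Y, Z, Q) = (1, 0, 0, 0) — a fresh break with no recruited
molecules; antibody runs keep the same initial state because binding
requires Z > 0, making any pre-incubation before irradiation dynamically
irrelevant.

`simulate_population` couples N sites only through Auger re-damage: new
DSBs arise at population hazard (k₉/N)·ΣQ·n_off and strike a uniformly
chosen undamaged site. This recovers the mean-field term
d⟨X⟩/dt = k₉⟨Q⟩(1−⟨X⟩) exactly in expectation and serves as the
stochastic oracle for the Auger ODE system.

`detectable_foci` estimates N_DSB·P(Z ≥ Z\*) over an ensemble; by default
antibody-bound γH2AX counts toward the threshold (`count_bound=True`),
matching the observation that antibody exposure *increases* counted foci;
both modes are exposed since the stain's sensitivity to the bound complex
is an open experimental question.

## Moment closures

Differentiating the master equation gives exact unconditional mean
equations except for the repair term −k₁⟨XY⟩. Two closures are provided
(`dsbkin.moment_odes`):

* **Independence closure**: ⟨XY⟩ ≈ ⟨X⟩⟨Y⟩.
* **Conditional-mean closure**: writing p = ⟨X⟩, u = E[Y|X=1],
  v = E[Z|X=1], w = E[Y|X=0], s = E[Z|X=0], the repair term is exactly
  −k₁pu, and neglecting all conditional (co)variances yields

      p' = −k₁pu,  u' = k₂ + k₃v − k₄u,  v' = k₅u − k₆v,
      w' = k₃s − k₄w + k₁up(u−w)/(1−p),
      s' = k₅w − k₆s + k₁up(v−s)/(1−p).

  The probability flux leaving the damaged branch carries that branch's
  current conditional means (u, v) — the closure-consistent choice — which
  cancels in the (u, v) equations and appears as the relaxation terms in
  (w, s). The derivation is validated three ways in the test suite: the
  mixture identities d(pu+(1−p)w)/dt must reproduce the exact linear
  unconditional equations (an algebraic identity test), a truncated
  master equation integrated directly at gentle rates, and Gillespie
  ensembles at the fitted rates.

**Numerical choice — removable singularity.** At p = 1 the (w, s)
equations are 0/0. The public `rhs_conditional` freezes the empty branch
(zero derivative below weight 10⁻¹²), as its means carry zero weight in
the mixture. `integrate` avoids the issue entirely by integrating the
equivalent non-singular variables (p, u, v, ⟨Y⟩, ⟨Z⟩) — the unconditional
mean equations are exact and linear once ⟨XY⟩ = pu is closed — and
recovering w, s from the mixture identities afterwards.

**Known limitation — selection bias of the closure.** The exact u
equation contains an extra term −k₁·Var(Y|X=1): sites with more bound
repair molecules repair sooner, depressing the mean Y of the surviving
damaged population. Dropping it makes the closure repair slightly too
fast. Ensembles quantify the effect: negligible for the fast-repairing
MCF7 parameters, but for MDA-MB-468 (a ~10× longer repair episode and a
small stability margin) the closure underestimates mean X by ≈0.03
absolute at late times — about 2–3 Monte-Carlo SE at 1000 replicates, so
a "within 3 SE everywhere" comparison at that ensemble size straddles the
boundary for that cell line. The discrepancy is invisible at the
resolution of a printed mean-trajectory figure.

**Extensions.** The antibody adds ⟨Q⟩' = k₈[TAT]₀⟨Z⟩ − k₇⟨Q⟩ with the
matching sink/source in the ⟨Z⟩ (or per-branch v, s) equations; with
[TAT]₀ = 0 and ⟨Q⟩(0) = 0 the extended right-hand side is identical to
the unextended closure. Under the conditional closure Q is treated as
independent of X (it is inert, so its only branch coupling is the Z
exchange), keeping the mixture identity exact. The Auger extension adds
d⟨X⟩/dt += k₉⟨Q⟩(1−⟨X⟩) with k₉ = κR and is built on the independence
closure, where the re-damage bookkeeping is well-posed (re-damaged sites
keep their site history — mean-field over sites, no resetting); the
many-site SSA guards its correctness. The conditional closure refuses
k₉ > 0 rather than silently mixing formulations.

Integration uses `scipy.integrate.solve_ivp` with LSODA (stiff-capable;
the fitted systems have eigenvalues spanning ~1 to ~10³ h⁻¹), default
rtol 10⁻⁸ / atol 10⁻¹⁰. `persistence_auc` applies trapezoidal quadrature
to ⟨X⟩ on the solution grid (default horizon 24 h, the incubation length
of the motivating experiments; endpoint interpolated when needed).

## Observation maps and fitting

χ₁ (mean DSBs/cell) is modelled as N₀·⟨X⟩ with N₀ = dose × 40 DSB/Gy
(160 at 4 Gy). χ₂ (mean foci/cell) as N₀·⟨Z⟩/Z_max — one focus is worth
Z_max = 1000 molecules; when an antibody is present and bound γH2AX is
stained, ⟨Z⟩+⟨Q⟩ replaces ⟨Z⟩. The detectable-foci thresholding analysis
(tested: Pearson r > 0.99 between N_DSB·P(Z ≥ Z\*) and ⟨Z⟩ over the repair
episode) justifies this proportionality a posteriori.

The no-H2AX reference channel χ̄₁ encodes the observation that repair
without H2AX is ~10× slower: for measured data it is the time-dilated
series χ₁(t/10) (linear interpolation, initial value held); the model fits
it with k₅ = 0, solved with the *independence* closure (the historical
scheme pairs the conditional closure for the full model with the
independence closure for the barred branch; both are configurable). The
synthetic generator instead emits a model-consistent χ̄₁ (the k₅=0
solution plus noise) so that noiseless data round-trip to an exactly zero
objective at the generating parameters.

The objective sums squared residuals of the three channels, each divided
by the square of its first observation — or of its maximum when the first
observation is zero, as for foci at the moment of irradiation (the
channels have different units and magnitudes; no weighting scheme is part
of the model, so this scale-equivariant choice is the package's own, and
joint rescaling of foci units and Z_max leaves the optimum unchanged). A
soft penalty (weight 10⁴ on the squared relative excess) discourages
trajectories whose peak ⟨Y⟩ exceeds Y_max = 300. Parameter sets violating
k₃k₅ < k₄k₆ are rejected with a large finite value without integration:
they cannot reach the repaired steady state, and attempting to integrate
their exponential blow-up is what would otherwise dominate run time.

Nelder–Mead runs in log-parameter space (positivity by construction),
with optional multi-start (log-uniform within ±2 decades of the initial
guess) and simplex re-initialisation at the endpoint (up to 4 rounds) to
counter simplex collapse in six dimensions.

**Gauge fixing.** All three observation channels are exactly invariant
under (k₁,k₂,k₃,k₅) → (ck₁, k₂/c, k₃/c, ck₅): the data constrain the
repair hazard k₁·Y and the γH2AX trajectory but not the absolute scale of
the unobserved pATM count. Fitted parameter values are therefore
well-defined only up to this one-parameter family. `fit_baseline` reports
the orbit representative nearest (in log space) to the initial guess —
a closed-form slide along the orbit, adopted when the objective there is
within 5% of the converged value (exactly flat for noiseless data). On
noiseless synthetic data this recovers the generating parameters exactly;
without it, any point of the flat valley may be returned.

**Identifiability under noise.** Beyond the exact gauge, the model is
sloppy: at the default sampling times (first sample 0.5 h) the fast
relaxation eigenvalue of the (Y, Z) subsystem (~10³ h⁻¹) is unobservable,
so k₄, k₅, k₆ are constrained only through slow-mode combinations. With
10% multiplicative noise, parameter sets far from the truth can fit the
data *better* than the truth does; per-rate point recovery within a small
factor is then not a property this model/design pair possesses, and the
recovery benchmark in the test suite documents exactly that. Uncertainty
quantification beyond point fits is out of scope.

The antibody grouping g = k₈[TAT]₀/k₇ is fitted per concentration as a
one-dimensional bounded search (only g is identifiable from foci data at
binding quasi-equilibrium; k₇ is fixed at the reference 1 h⁻¹ and k₈
implied). A linear trend of g against [TAT]₀ over a chosen concentration
subset summarises the tracer-linearity prediction.

## Synthetic experiments

`dsbkin.synthetic_data` emulates the motivating assay design: 4 Gy
(≈160 initial DSBs/cell), sampling at {0, 0.5, 1, 2, 4, 6, 24} h,
conditions given as ([TAT]₀, R) pairs with the experimental concentration
panel {0, 0.025, 0.05, 0.5} µg/ml as the antibody default. χ₁ is emitted
directly in DSB-count units; the comet assay's Olive-tail-moment
calibration layer is deliberately not simulated. Noise is multiplicative
Gaussian with CV 0.1 per channel by default (focus counts are averages
over many cells, so continuous unbiased noise is adequate; no noise model
is prescribed by the source experiments), clamped at zero, with optional
Poisson cell-counting noise. What passing recovery tests on these data do
*not* show: robustness to the OTM calibration, to per-cell heterogeneity
in initial damage, to correlated residuals, or to microscope detection
effects — none of which the generator emulates.

Defaults chosen where no measured value exists (synthetic truth only):
k₇ = 1 h⁻¹ (reference dissociation rate; only the grouping g is
identifiable), k₈ = 10 h⁻¹(µg/ml)⁻¹ (gives clearly elevated, persistent
foci at the experimental concentrations without perturbing DSB kinetics
by more than ~0.6% of the initial signal), κ = 0.002 h⁻¹(MBq/µg)⁻¹ with
[TAT]₀ = 0.05 µg/ml for Auger scans (the concentration used in the
clonogenic experiments; over R = 0…8 MBq/µg this spans mild to strong
damage persistence). The tracer-principle check is quantified as the
maximum |Δχ₁| relative to the initial signal χ₁(0), which is robust to
the vanishing late-time denominator of a pointwise relative comparison.

## Problem sizes

Ensemble comparisons use 1000 replicates on a 25-point grid over 0–24 h
(matching the reference ensemble size); the truncated-master-equation
oracle runs at gentle rates with Y ≤ 12, Z ≤ 14; the noisy recovery
benchmark uses a 50-restart multistart with 600 Nelder–Mead iterations
per start and rtol 10⁻⁵ during fitting. These sizes are the package's
defaults for its own validation suite and keep the full run on a single
CPU in the minutes range.
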