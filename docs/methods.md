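# Methods

`popsse` asks a study-design question with simulation: when building a
population pharmacokinetic (Pop PK) model of an antibiotic given by
repeated intravenous infusion, does it matter whether blood samples are
drawn after the first dose, after the fourth (near-steady-state) dose, or
after both?  The package simulates virtual cohorts from a known
two-compartment vancomycin model, refits every dataset with a nonlinear
mixed-effects estimator, and scores the estimates against the simulation
truth — the stochastic-simulation-and-estimation (SSE) paradigm.

## Structural model

Drug amounts follow the linear two-compartment mass balance with
zero-order (constant-rate) infusion input,

    dA1/dt = R(t) − (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 − k21 A2,          C = A1 / V1

with micro-rate constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2.  The
closed-form concentration during an infusion of rate R starting from a
drug-free state is

    C(t) = R [ A/α (1 − e^{−αt}) + B/β (1 − e^{−βt}) ],   0 ≤ t ≤ t_inf,

where α ≥ β are the roots of x² − (k10+k12+k21)x + k10·k21 and
A = (α − k21)/(V1(α−β)), B = (k21 − β)/(V1(α−β)).  After the infusion the
two accumulation terms decay mono-exponentially in the time elapsed since
the infusion ended; this convention makes the two branches continuous at
t_inf, and the implementation uses the single equivalent expression with
te = clip(t, 0, t_inf) and τ = max(t − t_inf, 0).  Multiple doses
superpose (the model is linear).  Units are fixed: mg, L, h, mg/L.

An independent oracle — adaptive high-order ODE integration (DOP853,
rtol 1e-10) of the mass balance, split at every dose on/off switch — backs
the closed form; the test suite checks agreement to 1e-6 relative on 200
randomized (parameters, regimen, time) triples and typically observes
~1e-12.

The degenerate one-compartment case Q = 0 is handled by an explicit
mono-exponential branch and is used only in tests; `derive_macro` guards
the (unreachable for positive distinct rate constants) repeated-root case.

## Statistical model

Subject i's parameters are log-normally distributed around the population
typical values, θ_i = θ·exp(η_i) with η_i ~ N(0, Ω), Ω diagonal.  A "30%
CV" is implemented as ω = 0.30 exactly (ω² = 0.09), the standard
pharmacometric convention for exponential between-subject variability
(BSV).  Observations carry proportional residual error,
y_ij = f_ij·(1 + σ ε_ij), ε ~ N(0,1), σ = 0.10, so y_ij | η_i is Gaussian
with SD σ·f_ij.

## Study conditions (the generator's defaults)

1000 mg infused every 12 h, four doses; infusion durations 1, 2 or 4 h;
typical values V1 = 24.2 L, V2 = 32.3 L, Q = 11.2 L/h with CL 1.5 or
4.5 L/h; cohort sizes 25/50/100/200.  Sampling offsets from the dose
start are fixed per infusion duration — {0,1,2,4,12} h (1 h infusion),
{0,2,3,5,12} h (2 h), {0,4,5,9,12} h (4 h) — applied after the first dose
(dataset PK1), the fourth dose at 36 h (PK2), or both (PK3).  The full
factorial grid has 3 × 2 × 3 × 4 = 72 scenarios.

Two edge policies: the first-dose 0 h sample has a structurally zero
prediction, which makes the proportional-error variance degenerate, so it
is written with MDV=1 (present in the file, excluded from fitting; the
36 h pre-dose trough is nonzero and is fitted).  Negative simulated
concentrations (astronomically rare at 10% CV) are truncated at zero.
At coincident times the observation row precedes the dose row (trough
convention).  Randomness derives from a seed sequence keyed by
(seed, scenario, subject), so any replicate is reproducible in isolation.

What the generator does **not** emulate: covariates, dropout, assay
quantification limits, interoccasion variability, correlated random
effects, dose-recording errors, or model misspecification.  Passing tests
therefore demonstrate estimator behavior under a correctly specified
model, not robustness to real-data pathologies.

## Estimation

The marginal likelihood integrates the random effects out of the joint
density; `popsse` implements the two classical conditional
approximations, both expanded about each subject's empirical-Bayes mode
η̂_i (the minimizer of the conditional −2 log joint density):

* **Laplace** — second-order expansion, −2LL_i = g_i(η̂) − q·log 2π +
  log|∇²(g_i/2)|, with the exact η-Hessian obtained by central finite
  differences of the analytic gradient.
* **FOCE-I** (default, the field's workhorse) — the model is linearized in
  η about η̂ with Jacobian F, giving a Gaussian marginal with covariance
  Σ = FΩFᵀ + σ² diag(f(η̂)²) and residual y − f(η̂) + Fη̂; "interaction"
  means the residual variance uses f at η̂, not at zero.

Both are validated in the tests against adaptive Gauss–Hermite quadrature
on small single-random-effect instances.  Note that FOCE-I, being a
linearization, can miss the exact marginal −2LL by more than Laplace
does; on 3-subject/2-observation toys Laplace is within ~0.05 and FOCE-I
usually within ~0.3.

Numerical choices:

* All nine parameters (four θ, four ω², σ) are optimized on the log scale
  (positivity) by L-BFGS-B with central finite-difference gradients
  (relative step 1e-4) evaluated in one batched objective call over all
  18 perturbed points, warm-starting every inner solve from the center
  point's freshly computed modes.
* The inner mode search is a damped Newton iteration using the exact
  analytic η-gradient and a Hessian that keeps every first-derivative
  term (clipped elementwise to stay positive semidefinite), with
  backtracking line search, relative Levenberg damping, and an
  active-set strategy that iterates only on unconverged subjects.
  Convergence: gradient sup-norm ≤ 1e-4 or a Newton step below 1e-9
  (machine-resolved mode).  Mode error enters the marginal objective only
  quadratically, so this contributes ≲1e-9 objective noise.
* Model Jacobians with respect to η are analytic (chain rule through
  α, β, A, B), verified against complex-step differentiation to 1e-9.
* Far from the optimum the −2LL surface has near-vertical cliffs (extreme
  log-parameters overflow the model); objective values above a reference
  level fixed at the first evaluation are log-compressed — a monotone
  transform that preserves the minimizer but keeps polynomial line-search
  interpolation meaningful.
* Initial estimates default to the simulation's true values (the common
  SSE convention); a ±30% uniform jitter is applied on the single
  automatic retry of a non-converged replicate, and non-converged
  replicates are excluded from metrics (counts always reported).
* Ω is constrained diagonal; σ is reported on the SD scale, BSV on the
  ω² scale, matching how the performance metrics are defined.

## Performance metrics

Over N converged replicates of one scenario, for each parameter with
estimate PE and simulation truth PS:

    rBias = 100 · mean((PE − PS)/PS)          (accuracy, %)
    rRMSE = 100 · sqrt(mean(((PE − PS)/PS)²)) (precision, %)

with the conventional acceptability thresholds |rBias| ≤ 15% and
rRMSE ≤ 35%.  rRMSE ≥ |rBias| always (bias–variance decomposition); the
suite asserts this as a property.

## Problem sizes used by the test suite and acceptance script

The study-scale experiment (72 scenarios × 200 replicates) is summarized
at desk scale as the package's own configuration: a favorable scenario
(PK3, 1 h infusion, CL = 4.5, n = 100) at 25 replicates, and a reduced
sub-grid (PK1/PK2/PK3 × CL {1.5, 4.5} × 1 h infusion × n {25, 200}) at 10
replicates per cell.  At these sizes the structural-parameter metrics are
stable; BSV metrics carry substantial Monte-Carlo noise (their rRMSE can
exceed 100% in sparse cells, so a 10-replicate rBias has a standard error
of tens of percent), which is part of what the sparse-design results
show.

## Known limitations

* ω²_Q (and to a lesser degree other BSV variances) is weakly identified
  under these sparse designs; its maximum-likelihood estimate is biased
  downward (≈ −25% at n = 200 for single-period sampling at CL = 4.5).
  This is a property of maximum marginal likelihood itself, not of the
  approximation: profiling the exact (adaptive Gauss–Hermite) marginal
  likelihood on such datasets places its optimum at the same low ω²_Q.
  Estimators that terminate early on this nearly flat surface — e.g. a
  3-significant-digit stopping rule started at the truth — report
  estimates closer to their initial values and hence smaller apparent
  bias; `popsse` optimizes to a tighter criterion and reports the ML
  answer.
* With first-dose-only sampling and a long half-life (CL = 1.5 L/h, β
  half-life ≈ 27 h), the 0–12 h window barely covers the elimination
  phase and CL is overestimated by ~10–15%; exact-ML profiling
  reproduces this too.  This is the study's worst structural cell.
* FOCE-I objective values are not expected to be bit-identical to any
  particular NONMEM version; agreement is validated against quadrature,
  not against NONMEM constants.
* No standard errors, covariance steps, or covariate machinery; the
  package estimates and scores, nothing more.
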