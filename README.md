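# popsse

Stochastic simulation and estimation (SSE) for population-pharmacokinetic
study design: does blood sampling after the **first** dose of an
antibiotic yield population model parameters as accurate and precise as
sampling after the **fourth** (near-steady-state) dose?

Most antibiotic Pop PK studies sample at the fourth or fifth dose because
therapeutic drug monitoring traditionally does.  That habit is costly:
every dose and time up to steady state must be recorded correctly,
patients may drop out first, and pathophysiology keeps changing on the
way there.  `popsse` evaluates the alternatives by simulation for a
two-compartment vancomycin model: it generates virtual cohorts under
first-dose (PK1), fourth-dose (PK2), or combined (PK3) sampling
schedules, refits every simulated dataset with a nonlinear mixed-effects
estimator written for this purpose (first-order conditional estimation
with interaction, FOCE-I; Laplace as an alternative), and scores the
estimates against the simulation truth.

## Model

Concentrations follow the closed-form two-compartment solution for
constant-rate infusion, with superposition across doses:

    C(t) = R_inf [ A/α (1 − e^{−αt}) + B/β (1 − e^{−βt}) ]   (during infusion)

with k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, α and β the roots of
x² − (k10+k12+k21)x + k10 k21, A = (α−k21)/(V1(α−β)),
B = (k21−β)/(V1(α−β)).  Hierarchy: θ_i = θ e^{η_i}, η ~ N(0, ω²) per
parameter (30% CV), proportional residual error y = f(1 + σε) (10% CV).
Performance per scenario over N replicate fits:

    rBias = 100 · mean((PE − PS)/PS),   rRMSE = 100 · sqrt(mean(((PE − PS)/PS)²))

against the conventional criteria |rBias| ≤ 15% and rRMSE ≤ 35%.

## Worked example

```python
import numpy as np
from popsse import ScenarioSpec, simulate_dataset, fit, run_sse

scenario = ScenarioSpec("PK3", CL_true=1.5, infusion_duration=1.0, n_subjects=25)
dataset = simulate_dataset(scenario, seed=42)     # NONMEM-dialect rows + provenance
result = fit(dataset)                             # FOCE-I, initialized at the truth
print(result.theta_hat.as_array())                # [ 1.599 24.025 31.854 10.663]
print(result.omega2_hat)                          # [0.0532 0.0412 0.1356 0.0444]
print(result.sigma_hat)                           # 0.0974

summary = run_sse(scenario, n_replicates=5, base_seed=42)
print(summary.metrics.round(2))
```

```
        rbias  rrmse
CL       2.87   5.34
V1      -0.67   1.66
V2       5.47   7.37
Q       -6.33   9.11
om2_CL  -3.24  29.89
om2_V1  -2.97  34.12
om2_V2 -33.33  37.49
om2_Q  -35.41  44.39
sigma    1.53   7.97
```

Reading this: with only 25 subjects the four structural parameters
(CL, V1, V2, Q) are recovered within single-digit percent bias and rRMSE,
while the between-subject variance estimates (`om2_*`, truth 0.09) are
noisy and shrink downward — exactly the sparse-design behavior the study
quantifies.  The proportional-error coefficient (`sigma`, truth 0.10) is
nearly unbiased.

## Command line

```bash
popsse simulate --dataset-type PK1 --cl 1.5 --tinf 1 --n 25 --replicates 3 --seed 7 --outdir sims
popsse fit --data sims/PK1_1.5_1h_n25_rep0.csv --init-theta 1.5 24.2 32.3 11.2
popsse sse --dataset-type PK3 --cl 4.5 --tinf 1 --n 50 --replicates 20 --seed 7 --outdir run
popsse report --summary run/summary.csv --outdir figures
```

Every command writes its resolved configuration next to its outputs;
rerunning with the same configuration and seed reproduces every CSV
byte-for-byte.

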