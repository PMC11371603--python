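# olzdose

Population pharmacokinetics and model-informed initial dose optimization of
olanzapine in adults with bipolar disorder.

Olanzapine is dosed by therapeutic drug monitoring (TDM) once a patient is on
treatment, but the *initial* dose has to be chosen before any concentration is
available. This package implements the full model-informed precision dosing
(MIPD) workflow for that problem: a population PK model estimated from sparse
TDM troughs, its validation (bootstrap, visual predictive check,
goodness-of-fit), and Monte Carlo simulation of virtual cohorts to find the
weight-banded starting dose that maximizes the probability of landing inside
the 20–80 ng/mL therapeutic trough window.

## The model

One-compartment disposition with first-order absorption (Ka fixed at
0.861 h⁻¹), parameterized by apparent clearance CL/F and volume V/F, with
allometric body-weight scaling and a concomitant-quetiapine effect on
clearance:

    CL/F = 18.5 · (WT/70)^0.75 · (1 − 0.848·QUE)   [L/h]
    V/F  = 106 · (WT/70)                            [L]

Quetiapine inhibits the CYP1A2/CYP2D6 routes that clear olanzapine; the fitted
coefficient −0.848 means a quetiapine co-medicated patient clears olanzapine
at 0.152 times the rate of an otherwise identical patient — a 6.6-fold
exposure increase at the same dose.

Between-subject variability is lognormal on CL (ω = 18.4%); residual error is
combined proportional (30.7%) + additive (1.764 ng/mL). Estimation maximizes
the exact marginal likelihood: with a single random effect the per-subject
marginal is a 1-D integral, evaluated by adaptive Gauss–Hermite quadrature
(31 nodes re-centered at the per-subject posterior mode) rather than the
linearization approximations of classical NLME software. Covariates enter by
forward inclusion (ΔOFV > 6.63, p < 0.01) and backward elimination
(ΔOFV ≤ 10.8, p < 0.001).

Because the original 39-patient dataset is not public, `olzdose.cohort`
generates synthetic cohorts with the published statistical structure
(truncated-normal weights 70.01 ± 8.23 kg on [45, 85] kg, Bernoulli quetiapine
flag, heterogeneous steady-state dosing, 1–3 trough samples per subject);
estimation, selection and validation are exercised end-to-end against it.

## Worked example

```
$ python analysis/01_simulate_cohort.py
$ python analysis/02_fit_model.py
stepwise covariate search (include if dOFV > 6.63, drop if <= 10.8):
  forward  QUE      dOFV=  113.00  included
  forward  NOISE1   dOFV=    4.07  rejected
  forward  NOISE1   dOFV=    2.00  rejected
  backward QUE      dOFV=  113.00  kept

final model (OFV 681.43, converged=True):
  CL/F 19.71 L/h   V/F 124.5 L   theta_QUE -0.846
  omega_CL 15.1%   sigma_prop 26.6%   sigma_add 1.87 ng/mL
  RSE%: cl_typical=20, v_typical=35, theta_que=3, omega_cl=23, sigma_prop=13, sigma_add=58
  eta-shrinkage 20%
  CL ratio with/without quetiapine: 0.154
```

On this 39-subject synthetic replica the search includes the quetiapine
covariate (ΔOFV 113, far past the 6.63 inclusion bar), rejects the planted
pure-noise covariate, and recovers the generating coefficient (−0.846 vs
−0.848, i.e. a 0.154 clearance ratio). The uncertainty profile mirrors the
sparse-trough design: CL/F is well determined (RSE 20%), V/F weakly (35%),
and η-shrinkage is ~20%.

```
$ python analysis/04_optimize_dosing.py
QD quetiapine=0:  max PTA over whole once-daily grid: 43.4% (poor everywhere)
BID quetiapine=0: best cell PTA 93.3% at 0.60 mg/kg/day, 90 kg
BID quetiapine=1: 0.05 mg/kg/day covers 40-100 kg with PTA 0.989-0.999
```

Once-daily dosing cannot reliably hit the window (the 4 h effective half-life
of this model makes 24 h troughs too low), twice-daily dosing attains ~89–94%
probability with per-kg doses stepping down from 0.8–0.9 at low weight to 0.6
mg/kg/day at high weight, and under quetiapine the lowest grid dose
(0.05 mg/kg/day) is already sufficient at every weight — the same qualitative
dosing policy as the underlying clinical analysis. Each Monte Carlo cell is
cross-checked against a semi-analytic oracle: the trough is strictly
decreasing in the clearance multiplier e^η, so the attainment probability is a
difference of normal CDFs at root-solved boundaries.

The library surface is importable directly; the scripts are thin drivers:

```python
from olzdose import default_model, simulate_pta
p, se = simulate_pta(default_model(), weight=70, dose_per_kg=0.70,
                     frequency="BID", quetiapine=0, n_virtual=1000, seed=1)
# p ≈ 0.92: a 70-kg patient on 24.5 mg q12h has a ~92% chance of a
# steady-state trough inside 20–80 ng/mL
```

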