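# Methods

## Structural and statistical model

Olanzapine disposition is one-compartment with first-order oral absorption.
Apparent parameters (CL/F, V/F) absorb bioavailability; Ka is fixed at
0.861 h⁻¹ (a literature value — sparse trough sampling carries no information
about absorption). Steady-state concentrations use the superposition closed
form

    C_ss(t) = (D·Ka)/(V·(Ka−ke)) · [ e^(−ke·t)/(1−e^(−ke·τ)) − e^(−Ka·t)/(1−e^(−Ka·τ)) ]

with ke = CL/V, t hours after a dose, τ the dosing interval; doses are mg,
concentrations ng/mL (≡ µg/L), the factor 1000 applied once inside the
concentration routines. The expression is periodic, so the pre-dose trough
equals C_ss(0) = C_ss(τ). When |Ka − ke|/ke < 10⁻⁶ the flip-flop limit
(t·ke·e^(−ke·t) form, accumulated over doses) replaces the difference
quotient. A finite-dose superposition routine exists purely as a cross-check
oracle; production code always uses the closed form (exact and fast).

Covariates on clearance: allometric weight (exponent 0.75, reference 70 kg;
volume scales linearly, exponent 1 — both exponents fixed by convention, not
estimated) and a linear categorical quetiapine term, CL multiplied by
(1 + θ_QUE·QUE). Continuous covariate candidates use the power form centered
at the dataset median. Between-subject variability is lognormal on CL only
(the sparse-trough design cannot support random effects on V or Ka).
Residual error is combined: observed = pred·(1+ε₁) + ε₂, with independent
draws per observation; simulated observations may go negative and are kept
as-is in VPC simulation (a truncation flag exists; the data generator does
truncate observed DVs at zero, as a real assay would).

## Estimation

The objective is OFV = −2 Σᵢ log Lᵢ where Lᵢ marginalizes subject i's
likelihood over its clearance random effect:

    Lᵢ = ∫ Πⱼ N(dvᵢⱼ; fᵢⱼ(η), fᵢⱼ(η)²σ₁² + σ₂²) · N(η; 0, ω²) dη.

With one random effect this 1-D integral is computed essentially exactly by
*adaptive* Gauss–Hermite quadrature: per subject, the mode of the log
integrand is located by a vectorized, backtracking (monotone-ascent)
safeguarded Newton iteration — initialized from a 25-point coarse scan over
±max(6ω, 3) on cold calls, warm-started from the previous evaluation inside
an optimization — the Laplace width σ = (−g″)^(−1/2) sets the node scaling,
and 31 Hermite nodes are accumulated with log-sum-exp. Agreement with
brute-force trapezoidal integration is at the 10⁻¹⁰ level on small fixtures
(tested to 10⁻⁴). All 2π constants are included, so absolute OFVs differ by a
constant from software that drops them; every decision in the package uses
OFV differences, which are unaffected.

Free parameters (default: CL, V, θ_QUE, ω, σ₁, σ₂; Ka, both allometric
exponents and the 70-kg reference always fixed) are searched on transformed
scales — log for positive parameters, log(1+θ) for linear categorical
coefficients (keeping the clearance ratio positive) — with adaptive
Nelder–Mead (relative OFV tolerance 10⁻⁶, up to 3 seeded restarts from
perturbed starts on failure). A soft quadratic penalty beyond ±4 natural-log
units from the start keeps the search off unidentifiable ridges: with
trough-only data a grossly mis-specified model can drift to V → ∞, where the
trough degenerates to D/(CL·τ) and V drops out of the likelihood entirely.

Standard errors come from the inverse finite-difference Hessian of OFV/2 at
the optimum on the natural scale. The step size walks a small ladder
(1–5% relative) until the Hessian is positive definite; too-small steps are
dominated by quadrature/optimizer noise, too-large ones leave the quadratic
regime. η-shrinkage is SD-based, 100·(1 − SD(EBE)/ω), with EBEs the
per-subject posterior modes.

Stepwise covariate selection: forward phase adds, one candidate at a time,
the largest OFV drop exceeding 6.63 (χ²₁, p < 0.01; ties broken by candidate
order); backward phase deletes any included covariate whose removal raises
the OFV by at most 10.8 (p < 0.001), smallest rise first, iterating to
stability. A fit failure during a step skips that candidate and is logged.
Rows with MDV = 1 never enter the likelihood.

## Synthetic cohort generator

The original 39-patient TDM dataset is not publicly deposited, so the
generator emulates its statistical structure: weights truncated-normal
70.01 ± 8.23 kg on [45, 85] kg; quetiapine a Bernoulli flag; η_CL drawn from
the generating model; steady-state dosing with 1–3 pre-dose troughs per
subject, sampled uniformly up to 1 h *before* the scheduled dose (a sample
after the dose would sit on the absorption upswing and not be a trough);
combined residual error applied, observed values truncated at zero.

Dosing is deliberately heterogeneous — per-subject daily doses uniform on
0.2–1.0 mg/kg/day (0.03–0.15 for quetiapine users, whose clearance is
6.6-fold lower and whose TDM-guided doses would be titrated down
accordingly), and each subject once- or twice-daily with equal probability.
This mirrors real TDM practice and is what makes the model identifiable from
troughs alone: a cohort with one common dose and interval observes a single
concentration level, which cannot separate the proportional from the additive
residual component, and observes no accumulation contrast, which leaves V/F
nearly unidentified. The default quetiapine prevalence is 0.3 so the
interaction coefficient is estimable at research sample sizes; a
`paper_faithful_spec()` preset keeps the observed 2/39 (two quetiapine users
cannot support recovery testing, only cosmetic realism). Optional pure-noise
binary covariates support selection type-I-error experiments.

What the generator does **not** emulate: titration phases and dose changes
within a subject, non-adherence, below-quantification censoring, covariates
beyond weight/quetiapine, and any real correlation structure between
covariates. Passing recovery tests therefore demonstrates the estimator is
correct *under the stated model*, not that the model is correct for any
particular clinic's data.

## Dose optimization

The exposure target is the steady-state pre-dose trough (the cohort data are
TDM troughs and 20–80 ng/mL is a trough reference range); average and peak
metrics are available behind a flag. For each (dose, weight, frequency,
quetiapine) cell, 1,000 virtual patients draw η_CL ~ N(0, ω²); twice-daily
regimens split the daily dose evenly q12h; the probability of target
attainment (PTA) is the fraction of troughs inside the closed interval
[20, 80]. Residual (assay) error is excluded by default — the PTA is meant to
describe true individual exposure, not a noised measurement; a flag includes
it. Each grid cell gets its own seeded stream derived from (scenario seed,
frequency, quetiapine, dose index, weight index), so results are reproducible
and independent of grid traversal order.

Because the trough is strictly decreasing in the clearance multiplier
m = e^η, the PTA has a semi-analytic form: Φ(ln m_lo/ω) − Φ(ln m_hi/ω) with
the boundary multipliers root-solved from trough(m) = 20 and 80. This serves
as the independent oracle for the Monte Carlo engine and as the smooth engine
for fine-grid recommendation. When the oracle check runs over all 308 grid
cells, the per-cell binomial tolerance is multiplicity-aware (all cells
within 4 SE, ≥99% within 3 SE, SE floored by 1/n for near-degenerate cells):
at n = 1000 per cell, roughly one chance excursion past 3 SE is expected
among 308 cells even for an exact implementation.

The recommender evaluates PTA on a 1-kg weight grid (semi-analytic engine by
default), picks per weight the dose with maximal PTA (ties to the lower
dose), and merges contiguous weights sharing a dose into bands reported with
their PTA range. Under the final parameters the exact crossovers for
twice-daily dosing without quetiapine are ≈49 kg (0.9→0.8), ≈63 kg (0.8→0.7)
and ≈83 kg (0.7→0.6), with 1.0/0.9 mg/kg/day genuinely optimal below ~49 kg.
Published analyses of this design that report three bands with boundaries
near 56 and 74 kg are consistent with per-cell Monte Carlo noise at
n = 1000 — the true PTA differences between adjacent doses at those weights
(≈0.5 pp) are below one MC standard error, so grid-point argmax and
interpolated crossovers are noise-dominated there. This package reports the
exact argmax bands.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| CL/F | typical clearance at 70 kg, no quetiapine | 18.5 L/h | final estimate |
| V/F | typical volume at 70 kg | 106 L | final estimate |
| Ka | absorption rate | 0.861 h⁻¹ | fixed, literature |
| θ_QUE | quetiapine effect on CL | −0.848 | final estimate; ratio 0.152 |
| ω_CL | BSV SD on CL (lognormal) | 0.184 | final estimate |
| σ₁ | proportional residual SD | 0.307 | final estimate |
| σ₂ | additive residual SD | 1.764 ng/mL | final estimate |
| window | therapeutic trough range | 20–80 ng/mL | consensus reference |
| n_virtual | patients per PTA cell | 1000 | design choice of the simulation |
| quadrature nodes | Hermite nodes per subject | 31 | exact to ≪ test tolerance |

## Known limitations

* Only one random effect (CL): no BSV on V or Ka, no covariance structure,
  by design of the sparse-trough data.
* The OFV is an exact marginal likelihood; software using FOCE-family
  linearizations will match ΔOFV-based decisions but not absolute OFVs.
* Weighted residuals (WRES) standardize the population residual by a
  first-order marginal SD at η = 0; they are not the covariance-based
  WRES/CWRES of NLME tradition.
* Bootstrap replicates keep the final covariate structure (no per-replicate
  re-selection), standard practice but optimistic about selection
  uncertainty.
* No Bayesian individual dose adaptation from measured levels, no
  exposure–response modeling, no adherence simulation.
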