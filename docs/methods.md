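# Methods

This note is the scientific account of what `sckmipd` computes: the
model and its assumptions, where every default number comes from, what
the synthetic data generator does and does not emulate, the numerical
methods, and the known limitations.

## 1. Structural model

### 1.1 Pharmacokinetics

Two-compartment disposition with first-order absorption from a
subcutaneous depot; linear clearance from the central compartment.
States are amounts (mg); serum concentration is C = A_c/V2 (mg/L);
time is in days.

The PK subsystem is linear, so the concentration after any bolus
history is evaluated in closed form as a superposition of
tri-exponential unit responses with macro-rates α, β (disposition
eigenvalues) and ka. This is exact, which the test suite exploits:
dose superposition holds to machine precision and the full ODE route
must agree with it.

The terminal half-life is t½ = ln2/β. Rather than quote an
intercompartmental clearance directly, Q is calibrated at import time
so that CL 0.19 L/day, V2 3.61 L, V3 2.87 L reproduce t½ = 27 days
exactly (Q ≈ 0.30327 L/day). Targets at or below the infinite-Q
(one-compartment) limit ln2·(V2+V3)/CL are rejected as infeasible.

Body weight enters allometrically: CL_i = CL·(WT/70)^0.8,
V2_i = V2·(WT/70)^1. No other PK random effects are carried — an
important simplification that makes a subject's concentration profile
a deterministic function of weight and dosing history.

### 1.2 Pharmacodynamics

PASI follows indirect-response turnover: zero-order production kin,
first-order loss kout, with the pre-treatment steady state enforced by
kin = kout·PASI_base. Drug inhibits production through an Imax model,
I(C) = Imax·C/(IC50+C). Because the estimated Imax (1.19) exceeds 1,
the production multiplier is floored at zero — at high concentrations
lesion production stops entirely and PASI decays at rate kout.

Two delay/escape mechanisms shape the time course:

- **prePASI transit chain.** Four transit compartments between
  production and the observed score introduce the clinically observed
  lag of several weeks between exposure and response. The transit rate
  is tied to the remission rate (ktr = kout): the delay and the
  washout are treated as one turnover timescale, which keeps the chain
  identifiable from sparse PASI data (a free ktr is not supported by
  a handful of observations per subject).
- **Tolerance cascade.** For tolerance-flagged subjects, three
  mediator compartments are driven linearly by concentration
  (dM1/dt = SLP·C − koutTOL·M1, then a first-order cascade at
  koutTOL). The terminal mediator attenuates the inhibition through
  g(M3) = 1/(1+M3), a saturating form that keeps the multiplier
  positive for any mediator load. With koutTOL = 0.003/day, tolerance
  develops over months — an initial response followed by secondary
  loss of response.

## 2. Parameters

| Parameter | Default | Units | Provenance |
|---|---|---|---|
| CL | 0.19 | L/day | population PK of the TDM cohort |
| V2 | 3.61 | L | population PK |
| V3 | 2.87 | L | population PK |
| Q | 0.30327 | L/day | calibrated to t½ = 27 d (see 1.1) |
| ka | 0.18 | /day | reference-model convention, not re-estimated |
| F | 0.73 | — | reference-model convention |
| kout | 0.11 | /day | population PD estimate |
| Imax | 1.19 | — | population PD estimate |
| IC50 | 9.35 | mg/L | fixed in the PD analysis |
| koutTOL | 0.003 | /day | population PD estimate |
| SLP (tolerance) | 5e-4 | L/(mg·day) | calibrated, see below |
| ω(kout) | 0.913 | log-SD | IIV estimate |
| ω(Imax) | 0.0763 | log-SD | IIV estimate |
| ω(koutTOL) | 0.3715 | log-SD | IIV estimate |
| σ(PASI) | 0.76 | log-SD | exponential residual error |
| σ(PK) | 0.20 | CV | assumed (not reported); proportional |
| allometric exponents | 0.8 / 1.0 | — | CL / V2 weight scaling |

**SLP calibration.** The tolerance-driving slope is not an estimate.
It is fixed by a qualitative constraint: a typical tolerance-developing
patient on 300 mg q4w must relapse to at least half of baseline PASI
within a 1.5-year horizon (secondary loss of response on the study
timescale). Solving that condition gives SLP* ≈ 4.0e-4; the default
rounds up to one significant figure (5e-4, relapse fraction 0.55).
It is overridable via the run configuration (`slp_tolerance`).

**Baseline (B2 method).** The individual model baseline is
PASI_base = PASI_obs,0 · exp(η_RV), where the prior SD of η_RV equals
the residual error SD σ(PASI). The time-0 PASI record anchors this
and is therefore excluded from the likelihood.

## 3. Observation model

- PASI: exponential (log-normal) residual, y = f·exp(ε), ε~N(0,σ²).
  Scores below 0.05 are recorded as 0 and treated as censored
  (log-CDF contribution below log 0.05).
- Serum concentration: proportional residual, y = f·(1+ε). The assay
  quantifies 0.2–225 mg/L; BQL records contribute a log-CDF below the
  LLOQ, above-range records a log survival term above the ULOQ.

Because PK carries no random effects beyond weight, the PK likelihood
is a constant with respect to the PD random effects and is computed
once per subject.

## 4. Individual estimation

Random effects η = (η_kout, η_Imax, η_RV[, η_koutTOL for
tolerance-flagged subjects]) have independent normal priors. The MAP
estimate uses derivative-free Nelder–Mead from three starts (prior
mode, ±0.5ω). The conditional distribution p(ψᵢ|yᵢ) is sampled by
random-walk Metropolis–Hastings on η: 1000 burn-in iterations with the
proposal scale adapted every 50 iterations toward a 20–40% acceptance
rate, then 5000 frozen-scale iterations thinned to the requested
number of clones (default 100). With zero observations the conditional
equals the prior and exact i.i.d. prior draws are returned. The test
suite verifies the sampler against the prior (moment check), a
conjugate normal–normal closed form, and a 400-point grid quadrature
of a 1-D posterior (Kolmogorov–Smirnov distance < 0.05).

## 5. The dosing decision

Candidates are 150 mg q4w/q5w/q6w and 300 mg q2w/q4w/q5w/q6w
(150 mg q2w is not on the grid). Each clone is simulated through 10
cycles of the current regimen followed by 10 cycles of the candidate,
and PASI is read at the cycle-10 and cycle-20 trough instants. A
candidate qualifies if ≥ 90% of clones have PASI ≤ 1 at cycle 20;
among qualifiers the recommendation minimises annualised dose
(dose·365/τ), with ties broken toward the longer interval (fewer
injections). The change versus the current regimen is classified
optimized / maintained / intensified, or no_target when nothing
qualifies.

Costs use the dose-count convention of scaling the 14 yearly q4w doses
by the interval ratio — q5w gives round(14·4/5) = 11 doses/year, i.e.
EUR 13 717 at EUR 1246.98/dose and a 21% saving — rather than
365/τ (which would give 10).

Pooled (cycle-20 trough, PASI) clone pairs across patients and
regimens yield an exposure–response window: the widest contiguous
trough range in which ≥ 90% of nearby clones (±2.5 mg/L) are at
target.

## 6. Synthetic data

No patient-level data ship with the package; the generator emulates
the *design* of a 22-patient TDM cohort:

- covariates: weight ~ truncated normal 74.5 ± 15 kg on [46, 97];
  baseline PASI 11.6 ± 5.8 on [2, 27.5];
- regimens: 18× 300 q4w, 2× 150 q4w, 1× 300 q5w, 1× 300 q6w;
- tolerance developers: 4 of 22 subjects, assigned at random;
- PK sampling: pre-dose plus ~2, 7, 14, 22, 30, 40 days after a
  reference dose near mid-study;
- PASI visits: baseline, weeks 5–6, weeks 16–24, then every 6 months
  (±2 weeks jitter), over 1.5 years;
- residual noise and censoring as in section 3.

Scenario presets shift the population: `non_responder` lowers typical
kout to 0.07/day **and** activates the tolerance cascade for everyone
(a lower kout alone changes only response speed, not the steady state,
so sustained non-response requires the escape mechanism — in the
emulated cohort the sustained non-responders coincided with the
tolerance-flagged subjects); `intensification_candidate` draws
individual Imax uniformly in [1.06, 1.13]; `tolerance` activates the
cascade at typical parameters. `high_responder_spec()` is a cohort of
mild-baseline (5 ± 2 on [2, 10]), tolerance-free subjects used for
decision-rule directionality: such a cohort should route mostly to
maintained or reduced dosing, whereas the full-severity default mix —
high baselines, narrow Imax variability, four tolerance developers —
legitimately spreads across all four classes.

What is **not** emulated: real dropout/non-adherence, assay batch
effects, dose-timing deviations, correlated random effects, and the
specific individuals of any real cohort — headline cohort percentages
depend on those individuals and are not reproduction targets.

## 7. Numerics

- The PK forcing is closed-form and shared: per subject, an
  *integration plan* precomputes the RK4 step grid (steps ≤ dt_max,
  aligned to dose and output times, where the forcing has derivative
  kinks) and the concentrations at step nodes and midpoints. All
  clones and all MCMC iterations reuse that plan; only the eight PD
  states are integrated, in a numba-compiled classical RK4 kernel.
  Defaults: dt_max 0.25 d for simulation and clone projection, 0.5 d
  inside the likelihood (PASI dynamics have ≥ 9-day time constants, so
  these steps are far inside the stability/accuracy region; route
  agreement is tested).
- Two independent verification routes are kept: LSODA on the PD states
  with the same closed-form forcing, and LSODA on the full 11-state
  system with bolus restarts at dose times (used for mass-balance and
  cross-route checks).
- PD states are clamped at zero after each step; the production
  multiplier is floored at zero (Imax > 1).
- Reproducibility: all randomness flows from explicit seeds;
  cohort-level runs derive per-patient seeds from a `SeedSequence`.
  The CLI refuses to run stochastic steps without a seed and writes a
  manifest (seed, config digest, version) next to every output.

## 8. Limitations

- ka and F are conventions from the reference disposition model, not
  re-estimated; only the CL/V2/V3/t½ constraint is honoured.
- The PK residual CV (20%) is assumed; PK data mainly inform the
  weight-scaled typical profile rather than individual PK.
- ktr = kout couples the response delay to the washout rate; subjects
  whose delay and washout differ are absorbed into η_kout.
- The tolerance slope is calibrated from a qualitative relapse
  criterion, not estimated; only its order of magnitude is meaningful.
- The decision horizon (10+10 cycles) reads PASI at trough instants;
  regimens with identical steady states but different within-cycle
  fluctuation are distinguished only through those instants.
- Cohort-level headline fractions depend on the (synthetic) cohort
  composition; only directional behaviour is asserted.
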