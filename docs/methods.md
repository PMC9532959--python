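# Methods

## Model

True kidney function is a continuous-time Markov chain on the ordered
living stages G1/2 < G3a < G3b < G4 < G5 plus absorbing death. The only
permitted instantaneous transitions are stage *k* → stage *k+1*
(progression) and stage *k* → death, so the 6×6 intensity matrix *Q* is
upper triangular with zero death row, and the interval transition matrix is
*P(t) = exp(tQ)*. The model is therefore parametrised by nine baseline
rates per year — four progression, five death — defined for a reference
profile (woman aged 60, no comorbidities), scaled multiplicatively by
covariates:

    q(r→s; x, age) = a_{r→s} · Π_c m_c^{x_c} · m_age^{age − 60}

with one progression multiplier and one death multiplier per covariate,
shared across transitions. Age is *annually updated*: the covariate value
is the floored age, so intensities change at integer age anniversaries.

Observed eGFR stages are misclassified versions of the true stage through a
row-stochastic emission matrix *e(r, s)* supported on a band of ±2 stages
among the living stages (configurable `band_width`, default 2: a true G1/2
may be read as G3a or G3b but not G4/G5, a true G3b as anything living).
Death is always classified correctly and is never emitted by a living
state.

### Likelihood

Each patient contributes a hidden-Markov forward recursion over the living
stages at their test times. Conventions, all explicit options on
`LikelihoodOptions`:

* **Initial state** (`initial`). Default `"first_obs_exact"`: the true
  state at the first test equals the first observed stage (a common
  panel-HMM default; no emission factor for the first test).
  Alternative `"distribution"`: the first test is misclassified like any
  other, with a prior π₀ over living stages (uniform unless supplied).
  When fitting data whose baseline test is itself noisy — including
  cohorts from this package's own generator — the `"distribution"` option
  with the cohort's baseline stage mix is the correctly specified choice;
  the strict default can even render records impossible (e.g. a baseline
  read of G5 followed by a G1/2 read). The library keeps
  `"first_obs_exact"` as its default; the pipeline defaults to
  `"distribution"` with a uniform prior for robustness.
* **Time-varying age** (`age_update`). Default `"interval_start"`: *Q* is
  frozen at the covariate values in force at the start of each observation
  interval (the standard panel-data convention). Option `"exact"`: the
  interval is split at integer age anniversaries and the kernels composed,
  which matches the generator's dynamics exactly. With ~1-year test gaps
  and a 1.08 per-year multiplier the interval-start approximation inflates
  baseline rates by roughly half an anniversary's worth (≈ 2–4%); the test
  suite quantifies the likelihood difference and the recovery experiments
  use `"exact"`.
* **Death** is treated as exactly dated: a record ending in death at time
  *t_d* after the last test at *t_K* contributes the density
  Σ_s P(t_d − t_K)[·, s] · q_{s,death}.
* **Censoring.** A survivor's record carries an administrative censoring
  time; the window between the last test and censoring contributes the
  survival factor Σ_s P(t_cens − t_K)[·, s]. Omitting this term biases
  death rates upward by a factor comparable to the dangling exposure (we
  measured ≈ +30% with 1-year gaps), because deaths are always recorded
  but survivor exposure after the last test would otherwise be discarded.
  Cohort CSVs carry the censoring time in an optional `censor_years`
  column; without it, reading assumes records end at their last event and
  no survival term is added.

Impossible observation sequences (e.g. an observed regression under an
identity emission matrix) have likelihood zero and report −∞.

### Numerics

Because *Q* is upper triangular, the living 5×5 block is upper bidiagonal
and its exponential has a closed eigendecomposition: eigenvalues are the
negative total exit rates, eigenvectors follow from two fixed
back-substitutions. The likelihood engine groups observation intervals by
(floored age, covariate pattern), decomposes each group once, and runs the
forward recursion "wave by wave" across all patients simultaneously. When
two exit rates nearly coincide the eigen form is ill-conditioned
(divided-difference cancellation); groups whose minimum relative
eigenvalue gap falls below 1e-3 are rerouted through a batched
scaling/Taylor-series/squaring exponential, and a deterministic jitter of
1e-9 separates exactly tied eigenvalues elsewhere. The public
`transition_probability_matrix` uses scipy's scaling-and-squaring `expm`;
the engine's closed form is cross-checked against it in the tests.

The score is analytic: a scaled backward recursion gives ∂ℓ/∂P per
interval and ∂ℓ/∂e per observation; interval-level gradients map to
group-level ∂ℓ/∂Q through the Daleckii–Krein identity
dexp(tQ)[dQ] = V(Φ(t) ∘ V⁻¹ dQ V)V⁻¹, except in near-degenerate groups
where the exact block-matrix adjoint (top-right block of
exp([[Aᵀ, Ḡ], [0, Aᵀ]])) is used; the chain rule then yields gradients on
the log-rate / log-multiplier / emission-logit scale. The score is
validated against finite differences.

### Fitting

`CKDProgressionModel.fit()` maximises the likelihood with L-BFGS-B on the
unconstrained parameters from a deterministic start (crude
events/person-time rates with a small deterministic spread to keep exit
rates distinct, multipliers at 1, emission off-diagonals at 0.05).
The age-multiplier coordinates are rescaled by 30 inside the optimizer —
their exponent spans ±40 years, giving them ~10³ times the curvature of
the other coordinates — and optimisation restarts with cleared
quasi-Newton memory while that improves the objective. Box bounds keep the
search in a numerically sane region (rates 1e-6–10 /year, age multiplier
0.8–1.25 per year, binary multipliers 0.05–20, emission logits −25–3); at
any clinically plausible optimum none of them bind. During fitting the
per-step forward normaliser is floored at 1e-290 so that absurd parameter
regions yield a steep finite penalty rather than a −∞ cliff; evaluation
outside fitting keeps the exact −∞ semantics. A single deterministic
start is the default; `n_starts > 1` adds jittered restarts.

Standard errors come from the observed information, computed by central
differences of the analytic score (step 1e-4·(1+|θ|)); confidence
intervals are Wald on the transformed scale and back-transformed, and are
refused (flagged, never fabricated) when the information matrix is not
positive definite. Emission-probability intervals are delta-method. Mean
sojourn times are −1/q_rr with delta-method intervals on the log scale.
The covariate-selection helper mirrors the procedure of fitting with
hypertension and diabetes and removing them when no multiplier's CI
excludes no effect; the CI-based rule is our quantification of
"unable to predict".

## Synthetic cohorts

The generator emulates an open primary-care cohort:

* **Study window** 9 years with uniform staggered entry (entrants late in
  the window get short follow-up and are often excluded by the three-test
  rule, as in real extracts); `stagger_entry=False` gives a fixed-horizon
  cohort.
* **Population mixes** per albuminuria stratum (unmeasured, normo-, micro-,
  macroalbuminuria): age-band weights, covariate prevalences and baseline
  stage distributions follow the published baseline characteristics of the
  four cohorts.
* **True paths** are simulated with piecewise-constant rates refreshed at
  each integer age anniversary.
* **Test schedules**: `"random"` — renewal with exponential (or fixed)
  gaps, mean 1 year by default, independent of disease state, with a
  baseline test at entry; `"doctors_care"` — the next gap is looked up by
  the last *observed* stage (defaults G1/2 and G3a: 12 months, G3b: 6,
  G4/G5: 3, with ±20% jitter), the intensification pattern of guideline
  care. Under both, scheduling depends on the past observation history
  only, so the observation process is ignorable for the likelihood.
* **Observations** are categorical draws from the emission row of the true
  stage; death is recorded exactly; follow-up censors at the window end.
* **Retention**: patients with fewer than three eGFR tests are dropped
  (configurable `min_obs`). Note this filter is *informative*: patients
  who die early have fewer tests, so retention correlates with survival
  and the fitted death rates are attenuated relative to the generator —
  a real feature of three-test eligibility rules, not a bug. Recovery
  experiments therefore run with `min_obs=1` (correctly specified
  sampling) and the default remains 3 for realism.

Baseline intensities of the presets are calibrated by root-finding so that
the reference profile's one-year transition probabilities equal the preset
annual targets exactly; for the unmeasured stratum these targets are the
published reference values (G1/2→G3a 1.1%, G1/2→death 0.7%, G3b→G4 1.0%,
2.9% misclassification of true G1/2 as G3a), and for every stratum the
one-year progression probabilities lie inside the published per-cohort
ranges (0.75–1.3%, 1.5–2.5%, 3.4–5.4%, 3.1–11.9%). Values not pinned by
published numbers — the remaining death-rate targets, most emission rows
(chosen with under-grading mass exceeding over-grading mass), the binary
covariate multipliers (male 1.20/1.40, heart failure 1.40/2.00, cancer
1.15/1.90 progression/death; hypertension and diabetes at 1.00) — are
stated assumptions chosen once for realism. Age multipliers are 1.08
(progression) and 1.09 (death) per year.

What the generator does **not** emulate: continuous eGFR values (the model
is stage-level), patient-initiated "self-selection" of test times
(informative observation), transfer-out, secular trends, or frailty /
non-Markov memory. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
their violation in real records.

## Decoding, monitoring and calibration

**Viterbi decoding** maximises the joint probability of a non-decreasing
hidden stage sequence and the observations (including the terminal death
density or censoring survival factor), with ties broken toward the less
severe stage. Grading compares each test with its decoded stage:
*under-graded* = observed less severe than decoded, *over-graded* = more
severe; pooled percentages get Wilson score intervals (within-patient
correlation ignored in the default presentation; a patient-level bootstrap
is available).

**Monitoring metrics**, for a baseline stage and horizon: probability of
true progression to a more severe living stage (death reported
separately, optionally folded in); true positive = probability a single
test at the horizon reads more severe than baseline, given true
progression; false positive = probability it reads *any* different stage
given no true change (the directional variant — reads more severe — is
also computed). The single-test-at-horizon reading is used throughout.
The horizon kernel freezes age at its starting value by default (horizons
≤ 3 years; the exact-splitting option is honoured when selected).

**Calibration** conditions, for each held-out test beyond a patient's
first, on the patient's prior observations (filtered forward
distribution; first-observation-only conditioning is available), propagates
to the test time, conditions on being alive (a test happening implies
survival, and scheduling is ignorable given the observed past), maps
through the emission matrix, and compares predicted with observed category
proportions in 1-year bins (empty bins are reported with zero counts).
Predicted and observed proportions each sum to one per bin by
construction.

## Problem sizes used in the checks

Parameter recovery: 20 replicates of 5,000 retained patients from the
macroalbuminuria preset (chosen because its baseline stage mix populates
the severe stages, informing all 31 parameters), `min_obs=1`, fitted with
the `"distribution"` initial convention at the generating baseline mix and
exact age splitting; pooled 95%-CI coverage of the 31 true parameters
(log/logit scale) must reach 90%. Monitoring metrics are validated against
100,000 simulated paths per stratum and stage at 6/12/36 months within 3
binomial standard errors. Calibration self-consistency fits 1,500 training
patients, simulates ≈ 4,500 test patients (≈ 20,000 scored tests) from the
fitted parameters over a fixed 6-year window, and requires mean absolute
predicted-minus-observed proportion ≤ 0.02 per bin-category. Oracle
equivalence uses 200 records of ≤ 6 tests against exhaustive hidden-path
enumeration.

## Known limitations

* Wald intervals on weakly informed parameters (e.g. comorbidity
  multipliers at realistic prevalences in small cohorts) can be extremely
  wide or the information matrix non-positive-definite; the latter is
  flagged and intervals withheld.
* The interval-start age convention is an approximation; use
  `age_update="exact"` when test gaps are long or age effects strong.
* The default initial-state convention mis-specifies cohorts whose
  baseline test is noisy (see above); choose the `"distribution"`
  convention with a sensible prior for such data.
* Misclassification probabilities are covariate-independent within a
  cohort, and covariate effects are shared across transitions; per-
  transition effects are intentionally not fitted.
* No recovery transitions, no acute-kidney-injury state, no Bayesian
  fitting, no patient-level frailty.
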