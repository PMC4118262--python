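# Methods

`pahrank` implements a complete workflow for identifying long-term-care
(LTC) facilities whose residents make high use of acute hospital care, with
potentially avoidable hospitalisations (PAH) as the endpoint. This note
records the statistical model, the conventions and numerical choices, what
the synthetic cohort generator does and does not emulate, and the known
limitations.

## The endpoint: PAH classification

A hospital discharge is classified as potentially avoidable when any of its
first three diagnosis codes (position 1 = primary) starts with a prefix from
a condition code list. Matching is case-insensitive and ignores dots, so the
prefix `J18` covers `J18.0`–`J18.9`. Diagnoses at position four or beyond
never influence the classification, and classification is invariant to
permutations within the first three positions. The position limit is
configurable (`max_diagnosis_position`, default 3).

The bundled default list (`pahrank/data/pah_codes.csv`) maps the usual
residential-care PAH conditions — COPD, bronchitis, pneumonia, congestive
heart failure, dehydration, urinary tract infection, anaemia, cellulitis,
leg ulcers, collapse/syncope, constipation, influenza, fall-related
fractures and injuries, plus gastroenteritis and pressure ulcers — to
ICD-10 prefixes chosen by the package authors. It is a documented stand-in,
not an authoritative definition: studies with their own agreed code list
should supply it as a two-column CSV. Prefix (rather than exact-code)
matching was chosen so a short list reproduces condition-level intent while
an exact enumeration can still be supplied verbatim. The bundled list
deliberately contains no V/W/X/Y/Z-chapter prefixes so that the simulator's
non-PAH filler codes (`W99*`, `X99*`, `Y99*`, `Z99*`) can never collide
with it.

Event counting uses a half-open window `[start, end)` on admission date —
the standard epidemiological convention, which prevents double counting
across consecutive windows — and by default restricts to acute admissions.

## Exposure (person-time)

Per-resident person-time runs from `max(entry, window start)` to the
earliest of death, recorded exit (move-away), and window end, floored at
zero and converted at 365.25 days per year. Facility person-years are
either the exact sum of resident person-time, or the head-count
approximation: for each care level, resident count × mean observed survival
of that care level across the cohort. Mean survival is computed censored at
the window end (no extrapolation), and when applied to head-counts is
capped at the window length, so the approximation cannot manufacture
exposure beyond the observation period. The approximation is linear in the
head-counts by construction; it exists for the common situation where a
current census is available but individual follow-up is not.

## The case-mix model

Counts y_ij for resident j in facility i follow a negative-binomial (NB2)
mixed model with a facility random intercept:

    y_ij | b_i ~ NB2(mu_ij, k),    mu_ij = exp(x_ij' beta + o_ij + b_i)
    b_i ~ Normal(0, sigma_b^2)

* NB2 parameterisation: variance mu + mu^2/k; k is the size parameter and
  k → ∞ recovers Poisson. This is the convention under which the dispersion
  estimate is directly interpretable.
* Offset o_ij = log person-time by default (`offset_mode="log_person_time"`),
  making exp(x'beta) a rate per person-year — rates are the ranking
  currency. `offset_mode="none"` is available for pure-count modelling.
* The random intercept captures within-facility correlation of resident
  outcomes ("residents within a facility are likely to be somewhat
  similar").

The model accepts either per-resident rows with a facility random intercept
(the default, used for covariate selection) or per-facility rows (where the
random term acts as extra-NB overdispersion). Facility-level prediction
applies the resident-level coefficients to facility covariate proportions,
times facility person-years, at b = 0 — the conditional prediction for a
new facility. Prediction at b = 0 rather than the marginalised mean was
chosen because ranking is monotone in either and b = 0 is simpler to state.

### Likelihood evaluation

The marginal likelihood integrates b_i out per facility by adaptive
Gauss–Hermite quadrature: the integrand's mode b̂_i is found by a damped,
step-clipped Newton iteration (the joint log-density is strictly concave in
b, so this is globally convergent), the quadrature is centred at b̂_i and
scaled by the inverse square root of the observed curvature, and 15 nodes
are used by default. One node is exactly the Laplace approximation.
sigma_b = 0 degenerates analytically to a sum of independent NB log-pmfs.
On small test instances the 15-node rule agrees with 10,001-point
brute-force trapezoid integration to ~1e-9 relative or better, and the
error decreases monotonically in the node count.

The NB log-pmf is evaluated in a cancellation-free form: for counts up to
64 the Gamma ratio log Γ(y+k) − log Γ(k) is accumulated as
Σ_{j<y} log1p(j/k), and k·log(1+mu/k) is computed with `log1p`, so the
Poisson limit (k ~ 1e8 and beyond) is reached at full double precision.
Larger counts fall back to `gammaln`.

### Optimisation and inference

(beta, log sigma_b, log k) are estimated by L-BFGS-B with 3-point
finite-difference gradients; bounds keep log sigma_b in [log 1e−6, log 50]
and log k in [log 1e−6, log 1e9]. Tolerances: `ftol` 1e−11, projected-
gradient tolerance 1e−5, at most 500 iterations. These are the tolerances
at which the finite-difference gradient noise (the log-likelihood has
magnitude ~1e4 at the cohort scales used here) still dominates honest
convergence; cross-checks with derivative-free polishing move coefficients
by < 1e−5. Either variance component can be pinned (`fix_sigma_b=0`,
`fix_k=1e8`) which is how the package reduces exactly to a Poisson/plain-NB
GLM; the Poisson limit reproduces an independent IRLS fit to < 1e−6.

Standard errors come from the inverse observed information, computed as a
central-difference Hessian of the negative log-likelihood over all free
parameters (relative step 5e−4); Wald p-values are two-sided normal. A
rank-deficient design, or a non-positive-definite information matrix, sets
the SEs to NaN with a warning instead of failing. Simulation checks show
the reported SEs match the empirical sampling spread of the estimates to
within ~10% (slightly conservative) at the 149-facility scale.

### Backward elimination

Candidates are sorted by name first (so the retained set cannot depend on
the order the user listed them), then the covariate with the largest Wald
p-value is removed and the model refitted, until every retained covariate
has p ≤ alpha (default 0.05). Ties are broken toward the smaller absolute
standardized effect, then name; a NaN p-value (singular information) is
treated as maximally removable. The intercept is never a candidate. With
alpha = 1 nothing is ever removed; if everything is removed the
intercept-only model is returned with a note in the trace.

## Ranking methods

All methods rank ascending: rank 1 = lowest PAH use, rank n = highest.

1. **Method 1** — events per resident; a per-bed variant (events per bed)
   is exposed as an option since either denominator is defensible for
   monitoring, and neither is canonical.
2. **Method 2** — events per person-year (exact or approximate exposure).
   When all residents have identical follow-up this is a constant multiple
   of Method 1, so the two rankings coincide exactly — a property the test
   suite asserts.
3. **Method 3** — model-predicted events per facility: a case-mix risk
   score. Facilities expected to have many events given their residents'
   characteristics rank high regardless of observed use.
4. **Method 4** — change in ranks, defined as Method 2 rank minus Method 3
   rank, so positive change = observed use above what case-mix predicts.
   The sign convention is this package's choice; ordering by absolute
   change is available behind a flag. On tie-free inputs the changes sum
   to zero by construction.
* **Residual** — observed minus predicted counts, raw by default, with a
  Pearson variant standardised by sqrt(pred + pred²/k). Residuals are the
  model-based alternative to Method 4 for targeting higher-than-expected
  use.

Ties are broken by a stable sort on (value, facility_id), so every computed
method yields a strict permutation of 1..n — necessary for a deterministic
league table and for the rank-change arithmetic. Facilities with a zero
denominator (no residents, no exposure) are flagged and excluded from that
method's permutation but still listed in the report, rather than silently
dropped. Selection takes the top n overall, or the top n within each
stratum (re-ranked within stratum) for designs that recruit a fixed number
per region.

## Synthetic cohort generator

No suitable public dataset links LTC census records to coded hospital
discharges, so every stage is exercised on seeded synthetic cohorts drawn
from exactly the structure the model assumes: facility intercepts
b_i ~ N(0, sigma_b²); Bernoulli resident covariates; exponential survival
with care-level-specific rates, censored at the window end (day
granularity, minimum one day); event counts NB2 with mean person_time ×
exp(beta0 + beta'x + b_i) via the gamma–Poisson construction (valid for
non-integer k); admission dates uniform over the resident's exposure days.
Each event is PAH with probability `pah_fraction_of_events`: PAH events get
a code drawn from the bundled list's prefixes placed uniformly in positions
1–3, all other codes come from the disjoint dummy space, so the PAH
fraction is exact by construction. Because independent thinning of an
NB2(mu, k) count is exactly NB2(p·mu, k), the PAH counts follow the same
model with intercept shifted by log p — `SimulationScenario.pah_beta`
exposes that shifted truth for recovery tests.

Seeding: one master `SeedSequence` spawns a facility stream and a child
stream per facility for residents and events, so outputs are byte-identical
across reruns and editing one facility's scenario does not perturb
another's draws.

### The `opal_like` preset

The default study conditions emulate the scale of a census-type urban LTC
survey linked to 22 months of discharge records: 149 facilities, mean
6271/149 ≈ 42.1 residents per facility (gamma–Poisson, dispersion 8), care
mix low/high/dementia/psychogeriatric = 0.55/0.30/0.10/0.05, exponential
mortality 0.25/0.45/0.35/0.40 per year, 71% women. The four model
predictors (urgent GP visit in the prior two weeks; ED visit in the prior
window; prior diabetes admission; prior dementia admission) have
prevalences 0.08/0.15/0.10/0.12 and log-rate effects 0.5/0.4/0.3/0.2;
sigma_b = 0.3, k = 2, PAH fraction 0.8. The intercept is calibrated in
closed form so the marginal PAH rate is 0.34 per person-year:

    beta0 = log(0.34) − log[ e^{sigma_b²/2} · p_PAH · Π_j (1 − p_j + p_j e^{beta_j}) ]

Under these conditions one draw yields ≈ 2900–3000 PAH events over
≈ 8500 person-years (pooled rate 34 per 100 person-years; the facility-level
median is a little lower, ~31, because the rate distribution is
right-skewed). The `tiny` preset (5 facilities × 10 residents, PAH fraction
1) exists for oracle tests and smoke runs.

What the generator does **not** emulate: real covariate distributions and
their correlations, facility-size/ownership effects on outcomes, seasonal
admission patterns, resident turnover (everyone is present at window
start), coding error, or missing data. Passing tests therefore demonstrate
that the estimator and rankings are correct *under the model's assumptions
at a realistic scale* — not that the model is correctly specified for any
real jurisdiction's data.

## Problem sizes used by the automated checks

The test suite uses the `tiny` preset for likelihood-oracle comparisons,
cohorts of 2,000–3,200 units for GLM-limit and elimination unit tests, and
the full `opal_like` preset (20 replicates) for parameter recovery and
covariate-selection operating characteristics. `scripts/acceptance.py` runs
one complete `opal_like` pipeline — simulation through ranking and
selection — with four noise candidates added to the elimination, and
reports the computed totals, rates, overlaps, variance components and
retained-predictor count. The whole suite runs in a few minutes on one CPU.

## Known limitations

* Wald-based elimination is greedy; it does not account for multiplicity
  or model-selection uncertainty, and near-collinear candidates can be
  order-sensitive in pathological cases (mitigated, not eliminated, by the
  canonical candidate ordering).
* The observed-information SEs are asymptotic; with few facilities the
  sigma_b interval in particular can be poorly calibrated.
* The mean-survival approximation ignores within-care-level heterogeneity;
  it is exact only when survival is homogeneous given care level.
* Quadrature is one-dimensional by design: a single random intercept.
  Crossed or nested additional random effects are out of scope.
* Rankings carry no uncertainty intervals or control limits; a facility's
  rank can be highly variable when counts are small.
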