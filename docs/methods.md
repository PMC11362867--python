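# Methods

This note records the modelling choices behind `oncnet`: what each stage
computes, the constants and their rationale, what the synthetic generator
does and does not emulate, and the numerical decisions that were genuinely
open.

## Study design being implemented

The pipeline mirrors a cross-sectional claims analysis of breast-cancer
treatment delay in fee-for-service Medicare: women 66–99 with a breast
biopsy followed by two cancer diagnoses within 12 months form the base
cohort; a patient-sharing network over their physicians yields two
exposures (surgeon linchpin status, care-team care density); outcomes are
surgical delay (biopsy → first surgery > 60 days) and adjuvant delay (last
surgery → first adjuvant chemo/radiotherapy > 60 days), with 90 days as a
sensitivity cutoff; associations are estimated by Pearson χ² bivariately
and by logistic regression with cross-classified random intercepts for the
operating surgeon (NPI) and the patient's hospital referral region (HRR).

All dates are integer day indices from an arbitrary origin. Calendar
conventions are fixed constants: "3 months" = 91 days, "12 months" = 365
days, window boundaries inclusive on both ends.

## Network assembly

The physician–patient incidence keeps one entry per (physician, patient)
pair with any encounter inside `[biopsy − 91, biopsy + 365]`. Projection
applies the ≥ 5-patient node floor *before* forming edges; pairwise
shared-patient counts are unaffected by this ordering (they are pairwise
set intersections), but a floored physician can appear isolated. The
≥ 5-patient count is taken over within-window cohort patients, since the
incidence itself is window-restricted. Edge weight = number of unique
shared patients; edges below 3 are dropped. Physicians of specialty
"other" stay in the graph; specialty-restricted measures filter at
computation time.

## Exposure measures

**Linchpin score.** A neighbor is *dependent* on the focal physician if it
has no tie to any other node of the focal specialty. A neighbor that is
itself of the focal specialty is treated as *not* dependent — it has that
capacity in itself. This predicate is isolated in one function
(`measures._is_dependent`) because the toy worked example is agnostic about
it. Zero-degree focal nodes score 0 rather than undefined so the
top-fraction threshold is computable over all surgeons.

**Linchpin flag.** The top 15% is cut by nearest rank on the upper tail:
with n scores, the threshold is the m-th largest where
m = max(1, ⌊0.15·n⌋), and all scores tied with the threshold are flagged.
With 100 distinct scores exactly 15 are flagged; under ties the flagged
share may exceed 15%. The cutoff is computed over all surgeon nodes (no
tie-count floor).

**Care density.** Only team members present in the sharing graph count
(physicians dropped by the node floor cannot contribute shared-patient
weight); absent edges contribute 0 to the numerator; the denominator is the
number of unordered pairs of the graph-restricted team. A team of one is
the sole-clinician case, kept as its own exposure level rather than a
number. Preoperative teams (surgery cohort) include every physician seen
from 91 days before biopsy through first surgery; postoperative teams
(adjuvant cohort) include only oncologists (medical, radiation, surgical)
seen from last surgery through first adjuvant therapy. Numeric densities
are tertiled within cohort; sole-clinician remains a fourth level (it can
in principle occur postoperatively too and is then kept as its own level).

## Cohort derivation

Exclusions are assigned by the *first* failing rule in a fixed cascade
(prior cancer diagnosis; age outside 66–99; enrollment gap; multiple
primaries; invalid zip; metastatic diagnosis within 90 days of biopsy —
implemented two-sided, |date − biopsy| ≤ 90; neoadjuvant chemo/radiotherapy
before first surgery; reconstruction on the day of first surgery; no
surgery within 12 months), so exclusion tallies are reproducible. The
cascade is idempotent.

Treatment anchors: first surgery must be performed by a network surgeon;
adjuvant therapy by a network physician of the expected specialty
(chemotherapy → medical oncologist, radiotherapy → radiation oncologist),
strictly after the *last* surgery. The adjuvant interval runs from last
surgery to first adjuvant event — this aligns the outcome with the
encounter-count covariate ("between a patient's last surgery and first
adjuvant therapy"); the alternative first-surgery origin is available by
passing a different anchor column. Encounter-count covariates count
`visit`-class encounters over the same windows (other claim classes are
treatment anchors, not utilization).

Physician-level continuous covariates (patient volume, oncologist supply,
within-/between-HSA degree) are tertiled by the same nearest-rank rule with
ties to the lower bin; all-equal input collapses to "low". Deprivation is
binned at 5/10/15/20 percent (lower-inclusive, upper-exclusive, last bin
closed above). Comorbidity counts bin as 0 / 1 / ≥ 2.

## Regression layer

2×2 contingency tables use the Yates continuity correction; larger tables
do not. This asymmetry reproduces published reference values to one
decimal on both table shapes and matches R's `chisq.test` convention.

The delay model is `logit Pr(delay) = x'β + u_NPI + v_HRR` with
independent Gaussian crossed random intercepts. Exact integration over
crossed effects is infeasible, so the estimation strategy is explicit and
recorded on the results object:

* `laplace` (default, own implementation): damped-Newton maximization of
  the penalized log-likelihood in (β, u, v) using sparse designs — the
  objective is monotone by construction via step halving — alternating
  with Laplace-EM variance updates σ²_k ← (‖u_k‖² + tr Cov_kk)/q_k until
  the variance components move less than 1e-3. A small ridge (precision
  1e-4, i.e. prior sd 100) on fixed effects keeps separated levels finite;
  coefficients above 10 in absolute value are flagged as probable
  separation and mark the fit non-converged. The fit is deterministic.
* `vb` / `map`: the equivalent Bayesian mixed GLM in statsmodels
  (variational or posterior-mode). Accurate but impractically slow once
  the NPI factor has many hundreds of levels.
* `plain`: ordinary logistic regression ignoring clustering — the
  reference when variance components are zero.

Wald covariance of β comes from the fixed-effect block of the inverse
penalized observed information at the fitted point, conditional on the
estimated variance components. Reported effects are exponentiated
coefficients with Wald 95% CIs and two-sided p-values; reference levels
are non-linchpin and low care density. With variance components truly
zero, `laplace` estimates agree with `plain` to within 2% relative (0.01
absolute floor, since covariates with near-zero true coefficients make a
pure relative tolerance ill-posed).

## Synthetic claims generator

The generator emulates the structure the pipeline needs, with margins
matching a Medicare breast-cancer cohort: age distribution over the five
66+ brackets; race/ethnicity at published shares; ~20% rural residence
(large rural/small rural/isolated ≈ 10.6/5.6/4.2%); deprivation with a
rural shift; comorbidity at 54/23/23% for 0/1/≥2; one operating surgeon
per ~10 patients; 52.2% receiving adjuvant therapy. Geography is a nested
zip → HSA → HRR lattice (defaults: 8 HRRs × 3 HSAs × 3 zips at n = 2000,
~80 patients per HSA; scale `n_hrrs` with `n_patients` to keep that
density).

**Structural linchpin planting.** Rural HSAs get their expected surgeon
headcount scaled by (1 − rural_scarcity) and rounded *down* (minimum one),
so most rural service areas have a single surgeon. That surgeon's peers
have no tie to another surgeon, and the network pipeline discovers a high
linchpin score without the flag ever being written into the data. The
generator records its own structural truth — "sole surgeon in the HSA" —
for validation; agreement with the measured flag is asserted as a rank
association (Spearman ρ > 0.5 in tests), not equality, because the
measured top-15% rule and the structural rule need not coincide exactly.

**Care-density planting.** Each patient draws a latent team-cohesion level
(preoperative: sole clinician 10%, else low/medium/high equally;
postoperative: low/medium/high). High-cohesion teams are drawn from the
patient's HSA roster with Zipf-like weights, so the same few physicians
recur and accumulate pairwise shared patients; low-cohesion teams are
scattered across the whole roster. Measured density therefore correlates
with, but does not equal, the latent level. The two exposures are planted
independently (their real-world joint distribution is unknown, so the
generator does not guess a correlation).

**Outcome planting.** Delay indicators are Bernoulli with
`logit p = logit(baseline) + β_linchpin·linchpin + β_cd[level] + u_NPI +
v_HRR` per phase; planted defaults are the reference odds ratios (adjuvant
1.30, 0.85, 0.77 with baseline 0.21; surgical 0.91, 0.96, 0.58, 0.35 for
sole clinician, baseline 0.18; σ_NPI = 0.25, σ_HRR = 0.15), which yield
marginal delay rates near 14% (surgical) and 19% (adjuvant). Intervals are
then drawn consistently with the indicator: 15–60 days if not delayed,
61+ (geometric tail, mean ≈ 85, capped at 200) if delayed — so the 60-day
flag is exact and the 90-day sensitivity flag is a strict subset.
`PlantedTruth.null()` gives the no-effect configuration under which delay
is i.i.d. Bernoulli(baseline).

**Planted violations.** Each exclusion rule has a configurable planted
fraction (default 1%, no-surgery 2%), assigned as *disjoint* patient
classes so the filter cascade's tallies can be compared to the planted
counts exactly. Out-of-range ages are carried in an auxiliary integer
`age` column (the 5-level `age_group` stays within its levels); multiple
primaries are a planted boolean attribute, since each patient has exactly
one biopsy by design.

**What the generator does not emulate** — and hence what passing tests do
not establish about real claims: real ICD/HCPCS/CPT coding and code-list
mapping, billing and enrollment file structure, measurement error in
specialty assignment, informative missingness, exposure–confounder
correlation (no covariate effects on delay are planted), correlation
between the two exposures, and seasonality or secular trends in dates.

## Parameter recovery (the acceptance simulation)

The reference regression estimates come from restricted data, so the
check is recovery of planted effects: 50 replicate worlds of 10 000
patients (40 HRRs, keeping ~80 patients per HSA), each refitted with the
crossed-random-intercept model on the generator's exported true exposure
assignments; the replicate mean of each recovered OR must lie within 3
Monte-Carlo standard errors of its planted value, and ~95% of replicate
Wald CIs must cover it (binomial tolerance ≥ 43/50). True exposures are
used because the planted logistic generated the outcomes from exactly
them; the measured-exposure path is validated separately (rank
association, direction of the rural–linchpin gradient). Fitting uses the
two exposures as fixed effects — the generator plants no covariate
effects, so the short model is the generative truth. One replicate takes
roughly 12 s on one CPU; problem sizes were chosen so the whole recovery
runs in minutes.

## Known limitations

* The Laplace-EM variance updates carry the usual PQL-family upward drift
  for variance components with small cluster sizes (σ̂_NPI ≈ 0.3 when 0.25
  is planted at ~12 patients per surgeon); fixed-effect recovery is the
  validated quantity.
* Mean-field VB standard errors are bypassed in favor of
  information-matrix SEs, but VB point estimates are only used if that
  backend is selected explicitly.
* The generator's team construction gives every patient at least their
  surgeon in-window; cohorts with heavy out-of-network care would need the
  missing-measure handling exercised more than the defaults do.
* Sole-clinician patients are planted with the surgeon also performing the
  biopsy and no preoperative PCP contact; that is one concrete realization
  of "only saw the surgeon preoperatively", not a claim about how such
  patients arise in practice.
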