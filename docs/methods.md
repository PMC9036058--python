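# Methods

## Scope and model

The package operationalizes the two-step GLIM scheme on a per-admission
snapshot: (1) risk screening with NRS2002 and MUST, (2) GLIM diagnosis of
malnutrition, followed by agreement statistics between each screen and the
diagnosis and by outcome models. The diagnosis is binary; GLIM severity
grading (moderate vs severe malnutrition) is deliberately not implemented —
the concordance analysis the package exists for uses only the binary status.

All three rule engines are pure functions of a validated `PatientRecord`.
Weight-loss history is stored as per-window percentages rather than raw
serial weights because the instruments consume different windows: NRS2002
reads 1/2/3-month loss, MUST reads 3–6-month unplanned loss, GLIM reads loss
within/beyond 6 months. These windows are independent fields (a converter
from serial weights exists but the engines never see raw weights); this is
also what makes the archetype fixture generator possible.

## Rule-engine conventions

Band edges that the instrument descriptions leave to the implementer are
fixed deterministically and logged per patient in `triggered_rules`:

* NRS2002 nutrition sub-rules (maximum wins): 1 = loss > 5%/3 mo or intake
  (50, 75]%; 2 = loss > 5%/2 mo, BMI 18.5–20.5 with impaired general
  condition, or intake (25, 50]%; 3 = loss > 5%/1 mo (≈ > 15%/3 mo), BMI
  < 18.5 with impaired general condition, or intake ≤ 25%. Intake bands are
  half-open with the lower edge in the worse band, so a printed edge value
  scores deterministically.
* NRS2002 disease severity is an *input* (a pre-coded 0–3 class, as a ward
  pharmacist would record it); planned major abdominal surgery promotes it to
  at least 2. No diagnosis-code ontology is attempted.
* MUST bands: BMI > 20 → 0, 18.5–20 → 1, < 18.5 → 2; weight loss < 5 → 0,
  5–10 → 1, > 10 → 2, lower edges inclusive (5.0% scores 1, 20.0 BMI scores 1).
* GLIM inequalities are strict (BMI 18.5 exactly is not low under age 70;
  5.0% loss exactly is not weight loss). Age exactly 70 uses the elderly BMI
  cutoff (< 20), consistent with the NRS2002 "70 or older" age point; the
  record is annotated when this tie-break fires.
* Absent fat-free mass makes the GLIM muscle-mass criterion *not assessable*:
  it contributes false to the phenotypic disjunction and the assessment is
  annotated, rather than imputing FFMI or refusing the record.

A note on one property of NRS2002: a patient can reach the high-risk cutoff
with zero nutrition points only through disease + age points. With severity
capped at moderate (2) — the regime of an elective tumor cohort — this
requires age ≥ 70 *and* disease ≥ 2, which is exactly the mechanism that
degrades NRS2002-vs-GLIM agreement in surgical subgroups. A severity-3
(intensive-care) admission would reach the cutoff alone; the property test is
therefore stated for severity ≤ 2.

## Concordance statistics

Sensitivity, specificity, PPV, NPV are cell ratios of the screen-vs-GLIM 2×2;
likelihood ratios are LR+ = sens/(1−spec), LR− = (1−sens)/spec. Degenerate
denominators yield an *absent* metric with a reason, never 0, and zero-cell
likelihood ratios get no continuity correction.

Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the product of marginals. The
95% CI is Wald, κ ± z·SE with SE = √[p_o(1−p_o)/(n(1−p_e)²)], clipped to
[−1, 1]. This SE variant (rather than the full Fleiss–Cohen–Everitt
expression) was chosen as the package's standard because it is the common
textbook form for 2×2 screening agreement; a property test keeps it within
±0.03 of a 10,000-resample percentile bootstrap over random non-degenerate
tables, which bounds the practical difference.

AUC uses the tie-corrected rank (Mann–Whitney) statistic on the *raw ordinal
totals* (NRS2002 0–7, MUST 0–5+), which equals the trapezoidal area over all
unique thresholds; ROC points are emitted per threshold. Note the identity
AUC = (sens + spec)/2 when the score is collapsed to the binary screen class:
an ordinal-score AUC can exceed this bound, a binarized one cannot. Reported
formatting is 1 d.p. for percentages and 2 d.p. for κ/AUC; full precision is
kept internally.

## Outcome models

Continuous variables are compared with the two-tailed Mann–Whitney U
(normal approximation with tie correction, no continuity correction, matching
common clinical-statistics software; an exact option exists for groups under
~20), categorical variables with Pearson chi-square without continuity
correction. No multiple-testing correction is applied; two-tailed p < 0.05 is
the working threshold throughout.

Length of stay (days; postoperative stay for surgical admissions) is
dichotomized at the cohort median with "≥ median" as the long-stay class.
Logistic fits are maximum likelihood via statsmodels; odds ratios are
exp(β) with Wald 95% CIs. Categorical covariates expand against fixed
reference levels (tumor site: stomach; risk stratification: high). Univariate
fits screen candidates; those with any term at p < 0.05 (configurable) enter
the multivariable model. Perfect or quasi-perfect separation (non-convergence
or |β| > 15) is flagged and the fit reports no estimates — on strongly
separated synthetic cohorts the multivariable model is *expected* to flag
itself rather than print unstable odds ratios.

## Synthetic cohorts

**Fixture (archetype) cohorts.** Published agreement tables give each
instrument's 2×2 against GLIM but not the instrument-by-instrument joint.
`joint_from_marginals` refines the two marginals into an 8-cell joint per
surgical stratum by setting the both-instruments-positive cell within each
GLIM stratum to its Fréchet upper bound min(a, b) (maximal agreement,
deterministic, always feasible when the GLIM margins match). Any joint
consistent with both marginals reproduces every marginal statistic, so the
choice is immaterial to the reported panel.

Each joint cell maps to an archetype whose decisive fields sit at safe
distances from every threshold: GLIM status is driven solely by FFMI (16.0
male / 14.0 female when malnourished vs 19.0 / 17.5; BMI fixed at 21.0, which
clears the 20.5, 20 and 18.5 cutoffs at any age); NRS2002 class by intake
(0.55–0.70 → 1 nutrition point) plus 2 disease points (planned surgery in
surgical cells, pre-coded moderate severity otherwise); MUST class by
3–6-month loss in [6, 9]% (score 1). Because the three engines read disjoint
fields for these drivers, re-scoring provably reproduces the requested counts
cell-for-cell, for arbitrary feasible specs. Seeded jitter touches only
non-decisive fields (identity, labs, tumor descriptors, outcomes) and
decisive fields within their safe bands. Consequences to keep in mind: the
fixture's GLIM diagnoses rest entirely on the muscle-mass criterion, its
weight-loss windows are mutually inconsistent by construction, and its
feature correlations are degenerate — it is a cross-tab-exact test harness,
not an epidemiologically realistic cohort.

**Stochastic cohorts.** `generate_stochastic_cohort` draws each patient's
nutrition state at the stated prevalence (default 86/269) and then features
group-conditionally: age (55.93 ± 11.34 well vs 59.23 ± 13.65 malnourished),
BMI (23.73 ± 2.40 vs 19.98 ± 2.62, truncated so well patients clear their
GLIM cutoff), sex-specific FFMI, correlated weight-loss windows, intake
reduction, severity mix, surgical fraction 189/269, and outcomes
(non-surgical stay 6.05 ± 2.50 vs 12.21 ± 3.75 days; postoperative
8.24 ± 4.24 vs 9.65; complication rates 28/189 surgical, 6/80 non-surgical).
Malnourished patients are guaranteed ≥ 1 phenotypic criterion (weight loss is
forced if the BMI/FFMI draws land clear of the cutoffs), well patients none,
so observed GLIM prevalence is binomial around the parameter. Screen
positivity is *emergent* from the feature draws — there is no closed form for
the implied screen-vs-GLIM κ, so the test suite estimates the population
value once from a single large cohort (n = 20,000) and checks that the mean κ
over 50 seeded cohorts of n = 400 lands within 0.05 of it. Rates the source
population does not determine (weight-loss probability 0.60 vs 0.25 by
nutrition group, intake reduction 0.45 vs 0.10, acute illness 0.05 vs 0.01,
severity mix 0.35/0.45/0.20) are fixed plausible defaults for a subacute
tumor-admission population; they shape the emergent agreement level, and the
stability test is calibrated against whatever level they imply rather than
against a target.

What passing tests on synthetic cohorts do **not** show: instrument validity
on real patients, realistic missingness, inter-rater variation in severity
coding, or covariate structures capable of reproducing any published
regression coefficients (outcome models are checked for *structure* and for
parameter recovery on data simulated from a known truth, not against printed
odds ratios).

## Numerical and degenerate-input choices

* Percent incidences and panel percentages keep full float precision
  internally; rendering rounds (1 d.p. / 2 d.p.) only at output.
* Empty subgroups, single-class subgroups, constant variables, all-missing
  outcomes and undefined metrics are reported absent with a reason string;
  nothing degenerates to 0 silently.
* CSV missing tokens: empty string on write; empty string and `NA` accepted
  on read. Heights may be declared in cm and are normalized to metres on
  read. Writes use a fixed column order; read→write→read is lossless
  including absences.
* All randomness flows through a single `numpy` `default_rng(seed)` per
  generation call; the seed is recorded in cohort provenance and cohorts are
  byte-identical across runs with the same seed.

## Problem sizes

The packaged fixtures are desk-scale (n = 269 and its two strata). The
heavier checks — the bootstrap comparison for the κ CI (50 tables × 10,000
resamples), logistic parameter recovery (100 fits at n = 2,000), and the
stochastic κ stability study (50 cohorts of 400 against one of 20,000) — were
sized to keep the full suite around a minute on one core while leaving
Monte-Carlo error well inside the asserted tolerances.
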