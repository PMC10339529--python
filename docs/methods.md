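# Methods

This note documents the models, conventions and design decisions behind
`strokesofa`, in the order the workflow runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Scoring conventions

**Band conventions.** Clinical score tables print graded bands with gaps
(e.g. bilirubin "6.0–11.9" then "≥ 12.0", creatinine "3.5–4.9" then
"≥ 5.0"). All bands here are half-open and closed on the severe side —
bilirubin ≥ 12.0 scores 4, creatinine ≥ 5.0 scores 4, platelets < 20 scores
4 — so every real value maps to exactly one band. Each item's thresholds are
data (`BandItem`), not code, and serialize to a human-editable key/value
file.

**Vasopressor tiers.** The printed cardiovascular bands overlap
("dopamine ≤ 5" for 2 points, "dopamine 5–15" for 3). Resolution: 2 points
iff dopamine ≤ 5 (any dose > 0) or any dobutamine; 3 points iff
5 < dopamine ≤ 15 or epinephrine/norepinephrine ≤ 0.1 µg/kg/min (any dose
> 0); 4 points iff dopamine > 15 or epinephrine/norepinephrine > 0.1. When
several drugs run, the maximum applicable tier wins; hypotension alone
(MAP < 70 mmHg) scores 1.

**Respiration substitution.** When PaO₂ is unavailable, the PaO₂/FiO₂ ratio
is replaced by SpO₂/FiO₂. The published nonlinear SpO₂/FiO₂ equivalents of
the PaO₂/FiO₂ cutoffs 400/300/200/100 — **512/357/214/89** — are the default
band mapping (`ScoringConfig.spo2_fio2_bands`); they are a configurable
choice, since substitution tables differ between sources. SpO₂ readings at
100 % (configurable cap) are treated as uninformative — pulse oximetry
saturates — and disable the substitution. Every use of the surrogate is
flagged in the `ScoreResult`. The classical requirement of mechanical
ventilation for respiration scores 3–4 is **off by default** (matching the
binary bedside setting) and available as `require_ventilation_for_high_resp`.

**Missing data.** A missing component contributes 0 points and is listed in
`missing_components`. This is deliberate score-level imputation — "missing
is assumed normal" — not a raw value of zero (a raw MAP of 0 would itself
score points). A score computed with k missing components is therefore a
lower bound on any completion, which the property suite checks.

**Daily aggregation.** `worst_of_day` takes the per-variable
severity-directed extreme (minimum for SpO₂/PaO₂/MAP/platelets/GCS, maximum
for NIHSS/creatinine/bilirubin/vasopressor doses/respiratory rate…); it is
idempotent and order-invariant.

**Positivity.** `sepsis3_positive(baseline, window, delta=2)` is true iff
the maximum total in the infection window (onset day and the following day
by default) exceeds the admission baseline by ≥ delta. The rule is monotone
in every window total and antitone in the baseline. The baseline timepoint
is configurable; admission is the default. Which NIHSS (24-h versus
onset-of-infection) feeds the CNS item is the caller's choice: the engine
scores whatever observation set it is given, and the pipeline logs the
timepoint used.

## Score derivation

Step 1 — *univariable screen*: per-predictor logistic regression of the
binary poor outcome (mRS 5–6 at 3 months by default); a predictor is carried
forward when the Wald 95 % CI of its odds ratio excludes 1 (no
multiple-testing correction — the screen is deliberately inclusive), or when
it is *forced* by configuration (cardiovascular and renal markers are forced
in the default configuration: arterial hypotension and renal failure are
hallmarks of sepsis regardless of univariable significance). Model fitting
is delegated to statsmodels' Newton MLE; complete separation is detected
(exception or scaled coefficients beyond 15 log-odds) and reported as an
infinite odds ratio rather than silently returned.

Step 2 — *dichotomization*: the Youden index J = sensitivity +
specificity − 1 is maximized over **midpoints of consecutive distinct
observed values** (so rounding is meaningful), with the severity direction
fixed by configuration, never inferred from data. Ties in J break toward the
**more inclusive** threshold. The raw cutoff is rounded to the nearest whole
number — nearest multiple of 5 for blood-pressure variables — with halves
away from zero (the tie rule is a documented repo choice). If the rounded
cutoff still lies inside the predictor's clinical normal range (platelets
150–400 ×10⁹/l, creatinine 0.5–1.2 mg/dl in the defaults), it is replaced by
the established reference-score cutoff (< 150, ≥ 1.2): a data-driven cutoff
inside the normal range would label healthy physiology as organ dysfunction.

Step 3 — *model ranking*: every admissible combination of the dichotomized
items — at most one predictor per organ system, a constraint made explicit
and configurable — is fit by multivariable logistic regression and ranked by
Nagelkerke's R²,

    R² = [1 − exp(2(ll₀ − ll)/n)] / [1 − exp(2·ll₀/n)].

Because pseudo-R² differences of a few thousandths are not meaningful,
models within a configurable tolerance (default 0.01) of the best form a
near-tie set, inside which explicit preference rules decide: fewer items
first, then more clinically preferred items (SpO₂ over respiratory rate —
respiratory-rate changes after stroke are frequently non-infectious; MAP
with its established cutoff). Every selection decision is logged at info
level. The winner becomes a binary `ScoreDefinition` with the Δ ≥ 2 rule.

## AUC inference

The empirical AUC is the Mann–Whitney statistic with ties counted ½,
computed via midranks in O(n log n). Each subject retains its structural
component (fraction of opposite-class subjects it beats); DeLong's estimator
gives

    var(AUC) = S₁₀/m + S₀₁/n,   cov(A₁, A₂) = S₁₀,₁₂/m + S₀₁,₁₂/n

from the sample (co)variances of those components over m cases and n
controls. CIs are Wald with z = 1.96 and deliberately not clipped to [0, 1].
The non-inferiority test uses z = (d + margin)/se(d) and
p = 1 − Φ(z); `non_inferior ⟺ p < 0.025 ⟺ ci_low > −margin` is enforced by
using the same normal quantile in both rules and verified by a property
test. When the two component vectors agree numerically (se < 1e−7) the
comparison is flagged `exact_agreement`; at the exact boundary
(d = −margin) p = 0.5 by convention.

## Power and sample size

The planner targets the one-sided non-inferiority hypothesis
"AUC_a − AUC_b < −margin" and evaluates the same DeLong variance structure
at design-stage assumptions. Component moments come from the exponential
ROC model (Hanley's Q₁ = A/(2−A), Q₂ = 2A²/(1+A); S₁₀ = Q₂ − A² over cases,
S₀₁ = Q₁ − A² over controls), with **expected continuous counts**
m = prevalence·n — integer rounding would make the power curve a step
function and is left to the Monte-Carlo mode, which necessarily uses
integer counts. Power is Φ((d + margin)/se(n) − z₀.₉₇₅); the solver returns
the smallest integer n reaching the target by bisection (power is monotone
in n under continuous counts).

The reference design (`reference_design()`) anchors the standard score at its
derivation-cohort AUC of 0.714, assumes the new score is better by the full
margin (AUC 0.774, difference +0.06), treats the two estimators as
independent (assumed correlation 0 — conservative for the variance of the
difference), uses a 30 % outcome prevalence, 80 % power and one-sided
α = 2.5 %. Under these assumptions the solver yields **n = 354**; the
planned accrual check (950 admissions/year × 1.5 years × 30 % infection
rate → 428) confirms such a cohort is collectable in the stated window.
The assumed-AUC levels and correlation are explicit `PowerDesign` fields,
not hard-coded: they are design assumptions, and alternative assumptions
are one configuration away. A Monte-Carlo mode simulates paired scores
(exponential ROC model matching the analytic moments, or an equal-variance
binormal model; correlation through a Gaussian copula) and runs the actual
test, cross-checking the analytic power.

## Synthetic cohorts

`generate_cohort` draws, per patient: a latent stroke severity; age;
treatment-limitation, septic-course, ICU and DNR/DNI flags assigned **by
rank** of a severity-linked latent score with logistic noise, so the
configured marginal frequencies (defaults 20.2 %, 33 %, 24.3 %, 36 %) are
matched closely at any cohort size while remaining graded in severity;
admission physiology from plausible marginal distributions; and, for septic
patients, a shared gamma-distributed dysfunction burden with organ-specific
noise that drives correlated deterioration at infection onset (MAP and SpO₂
drops, platelet fall, creatinine rise, NIHSS worsening, fever and
inflammatory-marker rises), persisting with mild variation on the following
day. Non-septic patients receive an infection response (fever, CRP,
leukocytes) plus day-to-day noise only. Vasopressors appear in septic ICU
patients. Missingness is applied per variable and care setting (e.g. PaO₂
missing in 92 % of ward patients versus 35 % of ICU patients).

The mRS at 3 months is assigned by empirical quantiles of a latent score
(severity + dysfunction burden + treatment-limitation and age effects +
logistic noise) against a cumulative mRS distribution whose default is
calibrated to a general stroke-infection cohort (poor outcome mRS 5–6 =
51.7 %, death = 36.3 %, independence mRS 0–2 = 11.5 %); changing
`poor_outcome_fraction` rescales the distribution while preserving its
shape. mRS = 6 coincides with 3-month death by construction, and a
configurable share (50.7 %) of those deaths occurs in hospital.

Two calibrations are *emergent*, not assigned: the Δ ≥ 2 SOFA rule flags
about a third of patients because the deterioration magnitudes were
calibrated once so that nearly all septic patients (≈ 93 %) and few
non-septic patients (≈ 5 %) cross the threshold; and the score–outcome
association arises because the same latent burden drives both the
observations and the outcome. What passing tests show is therefore that the
pipelines behave correctly under a cohort with this structure — not that
real stroke cohorts have it. In particular the synthetic AUCs (~0.85) are
higher than typically observed on real patients, the organ-correlation
structure is a plausible default, and no within-day physiologic dynamics
are modeled (only the three analysis timepoints).

`generate_from_score` supports parameter-recovery testing: raw variables are
drawn from marginals with usable density around each default cutoff, and the
outcome is Bernoulli with log-odds α + 1.8·(item total), α solved so the
marginal outcome rate is 40 %. An effect of 1.8 log-odds per point is
"strong" (odds ratio ≈ 6 per item) — large enough that the derivation
pipeline should find the structure at n = 2000, small enough that outcomes
remain stochastic.

## Problem sizes and tolerances in the test suite

The suite checks (all sizes are the package's own choices): exhaustive
extreme-input grids for the score ceilings (1024 SOFA / 32 S-SOFA
combinations); oracle equality of the empirical AUC against O(m·n) pair
counting on 1000 random instances and of the Youden search against
exhaustive thresholding on 200 instances; the DeLong SE of a paired
difference within 15 % of a 2000-resample stratified bootstrap at n = 80;
CI/p decision-rule agreement on 1000 instances; 95 % CI coverage for the
AUC difference within ±1.5 percentage points over 5000 replicates at
n = 300 (correlated exponential-model scores, ρ = 0.5); analytic power
equal to α at the margin and within 2 points of Monte-Carlo at n = 354;
Monte-Carlo rejection within 3 points of the 80 % target at the solved n;
and score recovery in ≥ 90 % of 50 seeded replicates at n = 2000 with the
screen's null carry rate inside a 3σ binomial band around 5 %. Recovery
failures, when they occur, are near-misses of the platelet or SpO₂ cutoff
by 2–3 units — the expected behavior of cutpoint estimation at this sample
size; the rate varies by a few points across seed blocks, which is why the
acceptance script estimates it over 80 replicates.

## Known limitations

* The planner's reference assumptions (anchor AUCs, independence) are
  reconstructed design-stage choices; other assumptions change n and are
  deliberately exposed as parameters.
* The generator matches marginal frequencies by rank assignment; tail
  dependence between flags is therefore approximate, and calibration of
  *rates* does not validate the realism of joint physiology.
* Logistic fits flag separation but do not apply penalized alternatives
  (none are part of the derivation procedure being implemented).
* qSOFA, infection adjudication criteria (pneumonia/UTI definitions),
  comorbidity indices and ROC smoothing are out of scope.
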