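# Methods

`coagcomp` implements a three-stage biostatistical pipeline for systemic
lupus erythematosus (SLE): composite pathway scoring of an ELISA analyte
panel, an effect-modification (interaction) analysis of those scores on
log-transformed disease activity, and a quartile-coded two-marker logistic
model for diagnosing active disease, together with synthetic cohort
generators that make every stage testable without patient data.

## Pathway scores

The panel comprises 21 analytes: eight complement proteins (activators
C3a, C4a, C5a, MASP2, C7; inhibitors/de-activators C1q, factor I, C4),
ten coagulation proteins (activators VWF, F7, TAT, FIB, F9, D-dimer;
inhibitors PROS, F12, F13, ATIII) and three inflammatory cytokines
(TNF-RII, IL-6, IL-8, all activators). Each analyte column is divided by
its maximum over the analysis cohort, so the largest normalized value per
analyte is exactly 1 and assay units cancel. The summary score of a
pathway is

    score = sum(normalized activators) − sum(normalized inhibitors),

a dimensionless signed sum bounded by the activator/inhibitor counts:
cytokine in [0, 3], complement in [−3, 5], coagulation in [−4, 6].
Normalization is computed over the analysis cohort only; pooling with
external reference samples is deliberately not supported, because the
score is a within-cohort contrast, not a calibrated quantity. Missing
analyte values are a hard error by default; an opt-in `allow_missing`
policy drops the analyte from the affected score without rescaling, which
biases that patient's score toward zero and is therefore flagged rather
than silent.

## Interaction analysis

Disease activity is the SLEDAI index; the analysis outcome is its natural
logarithm (ltSLEDAI). Natural log is the right base here: observed group
means of ltSLEDAI near 1.6–2.9 correspond to SLEDAI 5–18, whereas base-10
would imply implausible scores. SLEDAI = 0 (possible in clinical
registries) is handled by an optional +1 offset; the panel-cohort default
requires SLEDAI ≥ 1.

The sequence is: (i) OLS of ltSLEDAI on the coagulation and complement
scores jointly, with 95% t-based confidence intervals; (ii) the formal
interaction test — a two-sided t test of the product term added to that
model (the p-value is invariant to affine rescaling of either predictor);
(iii) median dichotomization of each score (ties assigned low, so the
split is deterministic), yielding a 2×2 table of cell means ± SD with
pairwise comparisons; (iv) the same pipeline repeated inside the low- and
high-cytokine halves (cytokine score split at its median), with
dichotomization thresholds recomputed within each half.

Pairwise cell comparisons use Fisher's LSD (pairwise t on the pooled
ANOVA mean square, df = N − 4) when Levene's test (mean-centred) across
the four cells has p ≥ 0.05, and Tamhane's T2 (pairwise Welch t with
Sidak adjustment over the 6 comparisons) otherwise. The selector
threshold 0.05 is a convention; `stratified_means(route=...)` can force
either branch. No multiplicity adjustment is applied across the
row/column comparisons of the stratified tables — they are descriptive
companions to the single pre-specified product-term test. Degenerate
input (all observations identical) short-circuits to p = 1 for every
pair.

## Synthetic panel cohort

The generator draws three independent standard-normal latent activations
per patient (coagulation, complement, cytokine). Analyte concentrations
are lognormal: log-concentration has marginal SD `log_sd` (default 0.5)
and correlation `loading` (default 0.7) with the signed latent — positive
for activators, negative for inhibitors — so the activator/inhibitor sign
structure of the scores is true by construction. The continuous outcome
is

    ltSLEDAI = β0 + βcoag·Acoag + βcomp·Acomp + βint·Acoag·Acomp + ε,

with βint switching at the cytokine latent's median: 0.8 in the
high-cytokine half, 0.0 in the low half (defaults βcoag = 0.7,
βcomp = 0.6, β0 = 2.0, noise SD 0.5, n = 112). These magnitudes mirror
the effect sizes reported for lupus panel cohorts on the log-SLEDAI
scale. The hard switch at the median mirrors the median-split subgroup
analysis the pipeline performs. The integer index is exp(ltSLEDAI)
rounded, floored at 1 and capped at 105 (the index's theoretical
maximum); the untruncated continuous outcome is kept in the output
(`ltsledai_true`) together with the latents, because they are the
generating model's ground truth.

Two consequences of this design matter for interpreting test results.
First, the round-and-floor step makes the observed log outcome
heteroscedastic; the type-I calibration of the interaction test is
therefore checked on the continuous outcome (measured rejection rate
0.047 at n = 112 over 1000 replicates, versus 0.080 on the rounded
outcome). Second, the cytokine *score* is a noisy proxy of the cytokine
latent (r ≈ 0.82 with the default loading), so a median split on the
score misclassifies roughly 15% of patients and leaks interaction signal
into the nominally interaction-free half at large n; the
moderation-pattern check (interaction significant only in the
high-cytokine half) is therefore performed on the latents, where it holds
in ~97% of seeds at n = 1000. Passing these tests shows the inferential
machinery is calibrated and localizes a true moderated interaction; it
does not show that a median split on a noisy proxy has the same power in
real data.

## Synthetic clinical cohort

Quartile codes for plasma D-dimer and serum C4 are drawn marginally
uniform on {1..4} (independent by default; a Gaussian-copula
`code_correlation` option exists because the two markers are plausibly
correlated in practice). Continuous concentrations are drawn uniformly
within the code's interval, using the fixed cut points 0.56/1.20/2.80
ug/mL (D-dimer, top quartile = risk) and 0.05/0.12/0.20 mg/mL (C4, bottom
quartile = risk); the open top intervals are capped at 8.0 ug/mL and
0.40 mg/mL, conventional choices since only the interval membership is
analytically relevant. Activity labels are Bernoulli with probability
given by the built-in logistic equation (below), and SLEDAI is drawn
consistently with the label (8–24 active, 0–7 inactive). Auxiliary
comparison markers (C3, anti-dsDNA, leukopenia, thrombocytopenia, ESR,
CRP, FIB) get moderate activity-dependent shifts (~0.5 SD), chosen so
their marginal frequencies are near those reported for large lupus
registries and so that no single marker out-discriminates the two-marker
combination — the qualitative ordering this cohort emulates. Absolute
concentration scales throughout the generators are conventional; the
analyses only consume ranks, quartile memberships, and within-cohort
normalized values.

## Quartile-coded diagnostic model

Both markers are coded ordinally 1–4, 4 = highest risk; intervals are
left-open/right-closed on the concentration axis, so boundary values
belong to the lower concentration interval. The model is

    z = β0 + β1·code_d + β2·code_c + β3·code_d·code_c,
    P(active) = 1 / (1 + exp(−z)),

with built-in reference coefficients (−1.612, 0.361, 0.325, 0.093). At
the top-risk corner (4,4), z = 2.620 and P = 0.932; at (1,1), P = 0.303.
Fitting uses maximum-likelihood logistic regression (Wald CIs; complete
separation and single-class labels are errors). The 16-cell odds-ratio
grid refits the model on 15 cell indicators against the (1,1) reference
cell; empty cells are reported as undefined rather than dropped.

The cut-off performance table evaluates *rectangle rules*: a patient is
test-positive under rule (d\*, c\*) iff code_d ≥ d\* and code_c ≥ c\*.
The rule, not a threshold on P, defines positivity — a pure probability
threshold forces sensitivity to be monotone in the cut-off, which the
rectangle-rule table structure does not (and nested rectangles do satisfy
their own monotonicity: stricter rules lose sensitivity and gain
specificity, which is property-tested). Each row carries the rule's model
probability P(d\*, c\*) as its cut-off label. The Youden column is
reported as sensitivity + specificity, matching the tabulated convention
(the standard J = that value − 1 is also emitted). PPV/NPV with a zero
denominator are reported as 0 with a degeneracy flag: the all-inclusive
rule (1,1) has sensitivity 1, specificity 0, PPV = prevalence, NPV = 0.

## ROC comparison

AUROC uses the tie-corrected Mann–Whitney formulation (ties count ½);
the curve sweeps all distinct thresholds, so its trapezoidal area equals
the U-statistic value identically (property-tested against an independent
implementation). Markers where lower values signal activity (C4, C3) are
negated before ranking; binary markers are scored {0, 1}, giving the
two-point curve with AUROC = (sensitivity + specificity)/2 of the single
rule. The two-marker combination is scored by the model's predicted
probability (equivalently z, by monotone invariance); the C3 +
anti-dsDNA combination is treated identically via a refit two-predictor
logistic with interaction. Paired AUROC differences use DeLong's
covariance-based z test; comparing a marker with itself returns
difference 0, p = 1.

## Problem sizes and numerical choices

Default analysis sizes are n = 112 (panel cohort) and n = 2025 (clinical
cohort). Parameter-recovery checks use n = 20 000 and 100 seeds (both
generators recover every generating coefficient within 3 estimated SE in
≥ 95% of seeds); the type-I calibration uses 1000 replicates at n = 112;
the moderation pattern 100 seeds at n = 1000. All randomness flows
through `numpy.random.default_rng` seeds carried in the configuration
objects, and identical configurations are byte-identical on rerun.

## Limitations

The generators encode the *assumed* data-generating structure — latent
pathway activations with lognormal analytes, a hard median switch for
cytokine moderation, uniform independent quartile codes — none of which
is observable in real cohorts. Passing parameter-recovery tests validates
the estimators and the pipeline plumbing, not the clinical claims; the
observational coefficients and correlations reported for real cohorts
depend on undeposited patient data and are treated as qualitative anchors
only. Treatment exposure, longitudinal structure and assay calibration
are out of scope.
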