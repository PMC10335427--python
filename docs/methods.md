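# Methods

## Scope and model form

`riskvalid` validates a *fixed* logistic risk model in a new cohort; it
never re-estimates individual predictor weights (doing so would be model
redevelopment, a different exercise).  A model is an ordered list of named
items — binary indicators and continuous age — with log-odds coefficients
and a constant:

    η = α + Σⱼ βⱼ (xⱼ − cⱼ),    p = 1 / (1 + e^(−η)).

Continuous items may declare a centring constant c (the default model
centres age at 25 years, so α is interpretable at the cohort mean age) and
a plausible range.  When items are unknown at assessment time the scorer
reports a lower/upper risk band instead of a point estimate, formed by
giving each unknown item its minimum/maximum achievable contribution
(binary: {0, β}; continuous: β·(range endpoint − c)).  This mirrors how
web calculators for such tools behave with partly completed forms.

The shipped default configuration (`data/oxmiv_like.yaml`) is a
**synthetic** 16-item model: its coefficient signs follow the risk
directions seen in first-episode-psychosis cohorts (male sex, younger age,
personal and family antisocial history, substance misuse, low income raise
risk; current inpatient status and antidepressant treatment lower it), and
its magnitudes (|β| between 0.1 and 1.2) were chosen once so that the model
on the default cohort discriminates at AUC ≈ 0.75 — the level typical of
violence-risk tools in external validation.  The constant (−3.61) was
solved once, at large n, so the mean predicted risk over the default cohort
equals the 11% target prevalence.  The published weights of any real tool
can be dropped in as a YAML file without touching code.

## Synthetic cohort generator

The generator emulates the statistical shape of a two-service
early-intervention-in-psychosis validation cohort (n = 1145 by default):

* **Binary predictors** come from a latent Gaussian copula: draw
  z ~ N(0, R), set xⱼ = 1 iff zⱼ > Φ⁻¹(1 − πⱼ).  Marginal prevalences πⱼ
  are exact in expectation regardless of R.  Defaults: male 60%, previous
  violent crime 9%, drug misuse 21%, alcohol misuse 7%, self-harm 43%,
  lower-secondary education 30% (a three-level education item collapsed to
  the single binary indicator the model uses), parental substance misuse
  12%, parent violent crime 3%, sibling violent crime 2%, current inpatient
  19%, antipsychotic 50%, antidepressant 33%, dependence treatment 1%, low
  income 17%, benefit recipient 14%.
* **Dependence**: only marginals are published for such cohorts, so the
  latent correlation is a free, documented parameter.  Default: 0.2 within
  the antisocial/adversity block (personal and family offending and
  substance variables), 0 elsewhere — a one-factor structure that is
  guaranteed positive semi-definite.
* **Age** is truncated-normal on the 14–65 service band.  The *realised*
  moments are the targets (mean 25, SD 10): naive truncation of N(25, 10²)
  would inflate the mean to ≈27.5, so the parent location/scale are solved
  numerically from the target moments.  The solution is a far-tail parent
  whose density decreases across the band — a right-skewed age profile,
  which is what early-psychosis services actually see.  Age shares the
  copula, so it can be correlated with items if R says so.
* **Outcomes** are drawn as yᵢ ~ Bernoulli(expit(ηᵢ)) from a *truth* model:
  the configured model with its intercept re-solved by monotone
  root-finding (Brent, tolerance 1e−10) so the mean predicted risk equals
  the target prevalence (default 11%).
* **Clinician judgement** is generated from the outcome alone at fixed
  sensitivity 0.40 and specificity 0.89 — only its marginal accuracy is
  known, so conditioning on predictors would be invention.
* **Missingness** is missing-at-random by construction: each variable's
  masking probability is logistic in fully observed drivers (male, 0.3;
  standardised age, −0.2; outcome, 0.4) with the intercept solved per
  variable to hit its target rate (defaults follow the reference cohort:
  up to 43–46% for parental/sibling offending history, 12–14% for
  education and parental misuse, ≤5% elsewhere).  The outcome and the
  judgement flag are never masked.

Determinism: a master seed spawns named per-stage `SeedSequence` children
(predictors / outcome / judgement / missingness), so identical specs give
byte-identical cohort CSVs and stages can be rerun in isolation.

What the generator does **not** emulate: referral and triage flow,
follow-up allocation, informative (MNAR) missingness, measurement error in
predictors, or temporal drift.  Tests passing on synthetic cohorts
therefore demonstrate the correctness of the *statistical machinery*, not
the real-world performance of any tool.

## Multiple imputation

Chained equations, written here because the per-variable behaviour is part
of the contract (statsmodels supplies the underlying GLM/OLS fits):

* m = 20 imputations, 10 cycles each by default; visit order is increasing
  missingness; initialisation draws from each variable's observed margin.
* Binary variables: logistic conditional model on all other variables
  *including the outcome and judgement flag*, coefficients perturbed by an
  approximate posterior draw β* ~ N(β̂, cov(β̂)), then Bernoulli draws.
  On separation or unstable fits the model falls back to a ridge-penalised
  fit with a small fixed perturbation, and logs a warning.
* Continuous variables: type-1 predictive mean matching — σ²* from a
  scaled inverse-χ², β* ~ N(β̂, σ²*(XᵀX)⁻¹), missing rows matched to the
  k = 5 observed rows with nearest (unperturbed) predictions and given the
  observed value of a randomly chosen donor.  Imputed values are therefore
  always members of the observed set.
* Observed cells are never modified; a table with no missing cells
  short-circuits to m identical copies.

Cycle count, donor count and the perturbation scheme are standard-practice
defaults, all configurable; nothing about them is claimed to reproduce any
particular study's (unstated) settings.

## Performance measures

* **AUC**: midrank concordance (ties 0.5) — identical to exhaustive
  case–control pair counting, which the tests verify — with DeLong
  structural-component variance.
* **Brier**: mean (p̂ − y)².
* **Calibration**: E = Σ expit(ηᵢ), O = Σ yᵢ, E/O (values < 1 mean
  underprediction); CITL as the intercept of a binomial GLM of y with η as
  a fixed offset; slope as the coefficient of η in a free logistic refit;
  variances from the fits' information matrices.  Separation triggers a
  penalised fallback with a warning.
* **Grouped calibration plot**: 10 equal-size (±1) groups by sorted
  predicted risk (stable sort; a tie warning when distinct values are
  scarce), observed proportions with Wilson 95% CIs
  (z = Φ⁻¹(0.975) ≈ 1.959964, via statsmodels).  Pipeline reports plot the
  first imputed dataset, matching the single-dataset presentation usual in
  validation papers.

## Pooling

Rubin's rules on a declared scale per metric: AUC and the four
classification metrics on the logit scale (delta-method variances),
CITL/slope/δ/γ on the identity scale, Brier and E/O as simple means
without a CI.  T = W + (1 + 1/m)B; the CI uses Rubin's large-sample t
degrees of freedom, shrunk by the Barnard–Rubin adjustment when
complete-data degrees of freedom are supplied (the pipeline passes
n − p − 1).  B = 0 degenerates cleanly to a normal interval with T = W.

## Recalibration

Intercept-only: δ is the MLE intercept of logit P(y=1) = δ + offset(η).
Its score equation is Σ expit(ηᵢ + δ) = Σ yᵢ, so on the fitting data the
updated model has E/O = 1.00 and CITL = 0.00 identically (to solver
tolerance) — the acceptance script demonstrates exactly this identity —
while the AUC is untouched (monotone transform).  Slope-and-intercept:
(δ, γ) by free logistic refit; the updated model multiplies every
coefficient by γ and sets the constant to γα + δ, so its linear predictor
is exactly δ + γη.  Selection keeps intercept-only unless the slope model
improves Brier by more than 0.005 (absolute, configurable) — "no
substantial improvement" made explicit.  In the pipeline both updates are
estimated per imputed dataset, parameters pooled by Rubin's rules, and one
final updated model is built from the pooled parameters (a per-dataset
alternative is a one-line change at the library level).

## Classification and net benefit

Thresholding is boundary-inclusive (p̂ ≥ t flags high risk).  The default
sweep grid is 0.025 steps over [0.025, 0.50], containing the clinically
discussed 10% and 12.5% cut-offs.  A 2×2 table can also be reconstructed
from published margins (n, events, flagged, sensitivity) with TP rounded
to the nearest integer — the only reconstruction consistent with
whole-percent published accuracy summaries.

Net benefit: NB(p_t) = TP/n − (FP/n)·p_t/(1 − p_t); treat-all and
treat-none in closed form (treat-all crosses zero exactly at the
prevalence); a binary comparator keeps fixed TP/FP with only the weight
varying; standardised NB divides by prevalence.  Default preference grid
0.05–0.35 in 0.01 steps.  Across imputations NB is pooled as a simple
mean; confidence bands for NB are out of scope.

## Numerical and degenerate-input choices

* Intercept solving brackets [−50, 50] and reports the bracket on failure.
* Probability clipping only where quantile transforms require u ∈ (0, 1).
* Zero-denominator classification metrics are reported as undefined
  (None), never as 0.
* Wilson bounds are clamped to [0, 1] and to contain the point estimate
  (guarding float noise at k = 0 / k = n).
* All report floats are serialised at 4 decimals with sorted keys, which
  is what makes whole-run byte-determinism testable.
* Effective-sample-size check: pass iff events ≥ 100 and non-events ≥ 100
  (boundary inclusive).

## Problem sizes in the test suite

The suite exercises marginal recovery at n = 10⁴–10⁵, calibration
parameter recovery at n = 2×10⁴–5×10⁴, MICE prevalence recovery at
n = 5000 with m = 20 and 5 cycles, and full-pipeline determinism at
n = 400 with m = 3 — sizes at which Monte-Carlo tolerances (stated in each
test) are comfortably wider than 2–3 standard errors while the whole suite
stays fast.

## Known limitations

* The judgement comparator is conditionally independent of predictors
  given the outcome; real clinician judgement correlates with observable
  risk factors, so judgement-vs-model contrasts on synthetic data are
  structurally cleaner than reality.
* The latent correlation matrix is a stipulation, not an estimate;
  downstream metrics can be studied for sensitivity to it but not matched
  to any real cohort.
* MICE here offers logistic and PMM conditionals only — no multilevel,
  time-aware or MNAR-sensitivity machinery.
* Headline real-cohort values of any published validation (its AUC, E/O,
  sensitivity at a cut-off) depend on the undeposited patient data and are
  deliberately not reproduction targets; the package's claims are the
  analytic identities and parameter-recovery properties its tests compute.
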