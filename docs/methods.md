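# Methods

This note records the statistical model behind `ckdmr`, the design
choices made where more than one defensible option existed, and the
limits of what the synthetic-data tests demonstrate.

## The prediction model and its preprocessing

The model is a multinomial logistic model over nine categories: the
eight ordered KRT/CVD/death outcome sequences and "no event", the
reference category. Each sequence k has one linear predictor per horizon
(2 and 4 years); probabilities come from the multinomial-logit link,
computed with max-subtraction so linear predictors of any magnitude
(|LP| up to ~700) yield probabilities that sum to one within 1e-12.
Consolidated absolute risks are sums of sequence probabilities: a
sequence contributes to an outcome iff the outcome appears anywhere in
it, so risk(KRT) and risk(CVD) each sum five sequences and risk(death)
four. Under the uniform distribution (all LPs zero) the consolidated
risks are therefore 5/9, 5/9 and 4/9.

Covariate preprocessing matches the model's published convention: age,
eGFR and systolic blood pressure are center-scaled with constants stored
*in the coefficient file* (they are model parameters, not cohort
statistics); uACR enters as ln(uacr)/ln(10). Two conventions the
coefficient file format fixes, because the original publication leaves
them implicit:

- **Link convention** — coefficient files must parameterize
  ln(p_k/p_no-event); any other reference category would silently
  produce wrong risks.
- **uACR floor** — uACR below 1 mg/g is floored at 1 mg/g before the log
  (configurable via `uacr_floor`), avoiding −∞ for values recorded as 0.

eGFR supplied in the cohort file takes precedence; otherwise it is
computed from serum creatinine with the CKD-EPI 2009 equation (κ = 0.7
female / 0.9 male, α = −0.329 / −0.411, continuous at Scr = κ). Smoking
is a single boolean; whether it encodes "ever" or "current" smoking is
metadata only.

## Nonparametric observed risk

Observed risks use the Aalen–Johansen cumulative incidence function with
death as the competing event for KRT and CVD, and the Kaplan–Meier
complement for death. Both are implemented as exact step functions
(overall product-limit survival combined with cause-specific hazard
increments; events precede censorings at ties; both event types share
the risk set at a tied time), so the mass balance
CIF₁(t) + CIF₂(t) + S(t) = 1 holds to 1e-12 at every event time and
bootstrap resamples — which always contain tied times — are handled
deterministically. Step functions are evaluated left-continuously at a
horizon (value at the largest event time ≤ t). lifelines serves as an
independent cross-check in the test suite, not as the implementation,
because its competing-risks fitter breaks ties by random jitter.

## Discrimination

The competing-risk C-index follows the convention of retaining
competing-event patients as controls: a pair (i, j) with i a cause event
at tᵢ (≤ the horizon, when one is given) is usable when tⱼ > tᵢ or j had
the competing event at any time; tied event times make a pair unusable;
tied risks score 0.5. Concordance is truncated at the prediction horizon
to match the horizon-specific risks (`horizon=None` uses full
follow-up). The implementation is a chunked vectorized pair count; the
test suite checks it against an exhaustive O(n²) loop on 100 random
cohorts. No IPCW censoring adjustment is applied, matching the simple
pairwise definition.

## Calibration and intercept recalibration

O/E ratios compare the nonparametric observed risk to the mean predicted
risk. Calibration plots split patients into quintiles of predicted risk
(near-equal bins by rank; heavy ties collapse bins and are flagged in
the output), with per-bin observed risk and percentile-bootstrap CI.

Intercept recalibration shifts each sequence's intercept by
α = ln[(f/(1−f))/(m/(1−m))]. Because this correction is exact only
marginally per state (shifting one intercept changes every state's
normalization), one-step application — the usual published procedure and
the default — leaves small residual gaps; `mode="iterated"` repeats the
correction to a fixed point (|mean predicted − observed| < 1e-8 per
state, ≤ 100 iterations), after which in-sample per-state O/E is exactly
one. Recalibration never touches non-intercept coefficients.

The observed frequency f under censoring can be computed two ways:

- `determinate` (library default, the simple rule): crude frequency
  among patients followed past the horizon or with an observed event
  before it. **Caveat measured during development**: this subset is
  selection-biased under heavy censoring, because patients with events
  are included regardless of censoring while event-free patients need
  full follow-up (at ~50% censoring by 4 years it overstated a 20%
  sequence frequency as 32%).
- `aj`: Aalen–Johansen multistate occupation probabilities over the
  9-state sequence process (product-integral of empirical transition
  hazards), which uses censored patients' partial information and is
  unbiased under independent censoring. The pipeline defaults to this
  method for that reason. With no censoring the two coincide exactly.

An optional continuity correction ((x+0.5)/(n+1) for zero- or all-count
states) keeps the log-odds defined for rare sequences; the pipeline
enables it by default because sequences such as "death after KRT and
CVD within 2 years" routinely have zero events in cohorts of ~1,000.
Recalibration is applied per 8-state sequence (the contrasts are
per-sequence), not per consolidated outcome. Slope recalibration and
coefficient re-estimation are out of scope.

## Decision analysis

Decision rules flag patients for KRT preparation: 2-year predicted KRT
risk strictly above 20/30/40/50%, eGFR strictly below 30/20/15, and the
guideline OR-combination (risk > 50% and/or eGFR < 15). The reference
"model as continuous rule" flags risk ≥ pt. Flags are compared with KRT
initiation within one year (365.25 days): flagged-and-initiated is a
true positive, flagged-without-initiation (including death before one
year) a false positive. Patients censored before one year without KRT
have unknowable status and are excluded from the classification
(complete-case), with the count reported. Net benefit is
TP/n − (FP/n)·pt/(1−pt) over a default grid pt = 0.01…0.50 (step 0.01),
with treat-all and treat-none references. Classification is assessed at
baseline only, not re-assessed at later visits. No utility weighting
beyond the net-benefit formula is attempted.

## Augmentation

Relative importance is a partial-likelihood explained-variation measure:
R² = 1 − exp(−LR/n) from the likelihood-ratio statistic of a
cause-specific Cox model (competing events censored at their time), and
a predictor's importance is the drop in R² when it is removed from the
full model. Published importance screens may use a different R²
estimator; this one is the package's documented stand-in. Fits use a
ridge penalizer of 1e-6 in the importance screen so exactly collinear
predictors remain estimable (duplicated predictors then share ~zero
drop-based importance, symmetrically).

The six augmented models (3 outcomes × 2 horizons) are cause-specific
Cox fits of the base model's time-aligned consolidated risk plus the
seven labs; their linear predictor is the risk score. Discrimination is
the cumulative/dynamic time-dependent AUC at the horizon with
Kaplan–Meier inverse-probability-of-censoring weights (via
scikit-survival); with no censoring it equals the plain binary AUC. AUC
differences get a percentile bootstrap CI with the augmented model refit
on every resample. The augmentation module expects a cohort already
restricted to the intended analysis set (e.g. baseline eGFR < 30 with
complete labs); it applies no filtering itself.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:

- **Covariates.** Age normal (median 54, IQR 43–64, clipped to 18–90);
  eGFR truncated-normal on (1, 30) with location solved so the truncated
  median is exactly 22.3 (IQR 17.3–26.3); uACR log-normal with exact
  median 549.4 (IQR 158.7–1,248.3); SBP normal 135 ± 18 mmHg; binaries
  Bernoulli (male 52.4%, black 0%, CVD history 13.1%, diabetes 26.4%,
  smoking 30% — the last not reported by the emulated cohort, set to a
  typical value for Chinese CKD populations). eGFR and uACR share a
  Gaussian copula with rank correlation −0.3 (the paper-style tables
  give only marginals; some negative dependence is needed for a
  realistic risk spread). All other covariates are independent — real
  cohorts are not. Serum creatinine is derived by analytic inversion of
  CKD-EPI so creatinine, age, sex and eGFR are mutually consistent. Labs
  are independent normals at typical advanced-CKD values and carry *no*
  outcome signal — augmented-model gains on synthetic cohorts are
  expected to be null, which is exactly what the no-information tests
  use.
- **Outcomes.** Each patient's 4-year category is drawn from their own
  predicted multinomial probabilities; event times within a sequence are
  uniform order statistics on (0, 4] (the model predicts horizon
  probabilities, not hazards, so any placement consistent with the
  category is admissible — this one is the simplest exchangeable
  choice); for the three-event sequence the KRT/CVD order is randomized.
  The 2-year label is derived from the same latent times (nested), never
  re-drawn. A consequence of drawing at the 4-year horizon is that
  "no event by 4 years" patients have no events ever.
- **Censoring.** Independent uniform administrative censoring on
  (censoring_min_years, censoring_admin_years), default (0, 6),
  mirroring a ~6-year enrollment-to-closeout window. Tests that isolate
  estimator properties set the minimum above the horizon to remove
  censoring noise.
- **Reference coefficients** are a synthetic stand-in (the published
  model's coefficients live in another paper's supplement and are
  user-supplied input): clinically plausible slopes (lower eGFR and
  higher uACR raise KRT risk; age, CVD history, smoking raise CVD/death
  risk) with seeded jitter. Intercepts are moment-matched on a
  deterministic probe cohort so 4-year mean state probabilities hit the
  targets (consolidated ≈ 26% KRT / 8% CVD / 5% death at 4 years, the
  realistic outcome mix), and the 2-year block — sharing the slopes — is
  matched to the *exact* thinned 2-year distribution implied by the
  uniform order-statistic placement (each latent event lands in (0, 2]
  independently with probability 1/2). The two horizon blocks are
  therefore mutually consistent in the large for cohorts drawn from the
  default covariate spec. A `BALANCED_STATE_TARGETS` variant gives every
  sequence ~8.5% mass; recalibration self-consistency tests use it
  because with the realistic mix the rarest sequences (~0.6–0.8%) have
  crude-frequency logits whose Monte-Carlo SE at n = 10,000 (~0.12)
  would swamp the recalibration signal being tested.

Passing tests on these cohorts show that the estimators recover the
generating model's quantities under independent censoring and correct
model specification. They do not show robustness to covariate
measurement error, informative censoring, inter-center heterogeneity,
missing data (the pipeline refuses incomplete rows; imputation is an
upstream concern), or model misspecification — all present in real
cohorts.

## Numerical and scale choices

- Bootstrap: percentile intervals (not BCa), patient-level resampling,
  deterministic per seed; failing resamples are logged and redrawn
  (bounded retries). Default 1,000 replications in the pipeline; the
  test suite and the acceptance script use 15–200 replications, with
  cohorts of 300–10,000 patients chosen per check so the suite runs in
  minutes on one CPU.
- The acceptance script validates at n = 1,333 — the scale of the
  emulated validation cohort — with 200 bootstrap replications.
- Pipeline determinism: per-stage RNG streams are spawned from
  stage-named children of the master seed, so toggling one stage off
  does not shift another stage's randomness; the report JSON is
  byte-identical across reruns (the config hash excludes the output
  directory).
- Quantile bins use rank splitting (sizes differ by ≤ 1); adjacent bins
  whose predicted range collapses to a single tied value are merged and
  flagged.
- C-index memory is bounded by chunking cases (~2M pair entries per
  chunk).

## Known limitations

- The multistate AJ frequency estimator treats the sequence process as
  Markov when estimating transition hazards; the generator's latent
  times are exchangeable rather than Markov, but occupation
  probabilities remain consistently estimated under independent
  censoring.
- The R² importance measure is one of several in use; rankings, not
  absolute values, are the meaningful output.
- One-step recalibration on a severely miscalibrated model can leave
  visible residual gaps (use `mode="iterated"`).
- The decision analysis assumes the 1-year KRT outcome is assessable at
  baseline; time-varying re-assessment is not modeled.
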