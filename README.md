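# ckdmr

External-validation toolkit for a multinomial competing-risks prediction
model in advanced chronic kidney disease (CKD, eGFR < 30 mL/min/1.73 m²).

Patients with advanced CKD face three interdependent outcomes: kidney
replacement therapy (KRT — dialysis or transplantation), cardiovascular
disease (CVD), and death. A joint multinomial model predicts, at the
2- and 4-year horizons, the probability of each of the eight ordered
outcome *sequences* — KRT only, KRT after CVD, CVD only, CVD after KRT,
death only, death after KRT, death after CVD, death after KRT and CVD —
against a "no event" reference. `ckdmr` provides everything needed to
validate, update and extend such a model on a new cohort, plus a
synthetic-cohort generator so the entire workflow is testable without
patient data.

## The model

For patient covariates x (age, sex, race, CVD history, smoking, systolic
BP, diabetes, eGFR, uACR; age/eGFR/SBP center-scaled, uACR as log₁₀),
each sequence k has a linear predictor LPₖ = β₀ₖ + βₖᵀx, and

```
p_k = exp(LP_k) / (1 + Σ_j exp(LP_j)),   p_0 = 1 / (1 + Σ_j exp(LP_j))
```

Sequence probabilities are consolidated into absolute risks:
risk(KRT) = Σ p_k over the five sequences containing KRT, and likewise
for CVD (five sequences) and death (four). eGFR is computed from serum
creatinine by the CKD-EPI 2009 equation when not supplied directly.

Validation follows standard prediction-model methodology:

- **Discrimination** — a competing-risk concordance index (patients with
  the competing event are retained as controls), with percentile
  bootstrap CIs.
- **Calibration** — observed/expected (O/E) ratios and quintile
  calibration bins, with observed risk from the Aalen–Johansen
  cumulative incidence function (death as competing event) and the
  Kaplan–Meier complement for death.
- **Updating** — intercept recalibration: each sequence's intercept is
  shifted by α = ln[(f/(1−f)) / (m/(1−m))] where f is the observed
  sequence frequency and m the mean predicted probability; an iterated
  mode drives mean predicted equal to observed per state.
- **Clinical utility** — decision curve analysis of KRT-preparation
  rules (2-year risk thresholds, eGFR thresholds, their combination):
  net benefit NB(pt) = TP/n − (FP/n)·pt/(1−pt) against treat-all /
  treat-none, plus sensitivity/specificity/PPV/NPV against KRT
  initiation within one year.
- **Extension** — R²-based relative importance of seven routine
  laboratory analytes (albumin, total cholesterol, HDL, hemoglobin,
  calcium, phosphorus, bicarbonate) and six augmented Cox models
  (base predicted risk + labs) compared by time-dependent AUC.

## Worked example

Generate a synthetic cohort of 1,333 patients (covariate marginals match
a contemporary advanced-CKD cohort: median age 54, 52.4% male, median
eGFR 22.3, median uACR 549 mg/g) with known reference coefficients, and
validate the model on it:

```
$ ckdmr simulate --n 1333 --seed 1 --out synthetic
wrote 1333 patients to synthetic/cohort.csv

$ ckdmr run --cohort synthetic/cohort.csv --coefs synthetic/coefficients.json \
            --seed 1 --reps 200 --out validation
report written to validation/report.json
2y krt: C-index 0.733 (0.696-0.769), O/E 0.98
2y cvd: C-index 0.577 (0.487-0.649), O/E 0.95
2y death: C-index 0.663 (0.540-0.807), O/E 0.84
4y krt: C-index 0.731 (0.694-0.763), O/E 0.84
4y cvd: C-index 0.623 (0.567-0.681), O/E 1.06
4y death: C-index 0.621 (0.526-0.726), O/E 0.80
```

Each line is one outcome at one horizon: the C-index is the probability
that, of a comparable patient pair, the one predicted at higher risk
experiences the outcome first (0.5 = chance); O/E is observed incidence
over mean predicted risk (1.0 = perfect calibration-in-the-large; the
deviations here are sampling noise at n = 1,333 — the cohort is
simulated from the model itself). `validation/` also contains the
recalibrated coefficient file, calibration bins and plots, the decision
curve table, the clinical-impact (confusion-metric) table, predictor
importance, and the base-vs-augmented AUC comparison — every figure has
a CSV of its underlying numbers.

The same steps are available in Python:

```python
import ckdmr as m

spec = m.CohortSpec(n_patients=1333, seed=1)
coefs = m.make_reference_coefficients(1)
cohort = m.generate_cohort(spec, coefs)
risks = m.predict_cohort(cohort, coefs)          # p_<seq>_<h>y, risk_<outcome>_<h>y
recal, result = m.recalibrate(coefs, cohort, horizon=2, mode="iterated")
```

Real cohorts are supplied as a CSV (one baseline row per patient; see
`ckdmr.pipeline.REQUIRED_COLUMNS`) and the model's coefficients as a
JSON `CoefficientSet` (intercept + named coefficients for the eight
sequences per horizon, with centering/scaling constants; multinomial
logit with "no event" as reference).

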