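"""Predictor-importance and model-augmentation study.

Quantifies how much seven routine laboratory variables (serum albumin,
total cholesterol, HDL cholesterol, hemoglobin, calcium, phosphorus,
bicarbonate) add to the multinomial model's predicted risks: a
partial-likelihood R2 relative-importance screen over cause-specific Cox
fits, six augmented Cox models (base predicted risk + the seven labs,
one per outcome x horizon), and cumulative/dynamic time-dependent AUC
comparison with inverse-probability-of-censoring weights.

The R2 measure is ``1 - exp(-LR / n)`` from the partial-likelihood ratio
(a Cox-Snell-type explained variation); a predictor's importance is the
drop in R2 when it is removed from the full model. Published importance
plots may use a different estimator; this one is the package's documented
stand-in. Outcome coding is cause-specific throughout (death competing
with KRT/CVD is censored at its time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .risk import CoefficientSet, predict_cohort
from .survival import bootstrap_ci
from .synthetic import LAB_COLUMNS

__all__ = [
    "AugmentedModelSpec",
    "DEFAULT_MODEL_SPECS",
    "cox_r2",
    "relative_importance",
    "fit_augmented",
    "time_dependent_auc",
    "compare_models",
]

OUTCOMES = ("krt", "cvd", "death")


@dataclass(frozen=True)
class AugmentedModelSpec:
    """One of the six augmented proportional-hazards models."""

    outcome: str
    horizon: int

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.horizon not in (2, 4):
            raise ValueError("horizon must be 2 or 4 years")


DEFAULT_MODEL_SPECS: tuple[AugmentedModelSpec, ...] = tuple(
    AugmentedModelSpec(outcome, horizon) for outcome in OUTCOMES for horizon in (2, 4)
)


def _cause_specific(cohort: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Duration/event columns with competing events censored at their time."""
    out = pd.DataFrame(index=cohort.index)
    out["duration"] = cohort[f"time_{outcome}"].to_numpy(dtype=float)
    out["event"] = (cohort[f"event_{outcome}"].to_numpy(dtype=int) == 1).astype(int)
    return out


def _fit_cox(df: pd.DataFrame, penalizer: float) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox model failed to converge on {int(df['event'].sum())} events, "
            f"{df.shape[1] - 2} predictors: {exc}"
        ) from exc
    return cph


def cox_r2(cph: CoxPHFitter) -> float:
    """Partial-likelihood explained variation ``1 - exp(-LR/n)``."""
    lr = cph.log_likelihood_ratio_test().test_statistic
    return float(1.0 - np.exp(-max(lr, 0.0) / cph._n_examples))


def relative_importance(
    cohort: pd.DataFrame,
    predictors: list[str],
    outcome: str,
    penalizer: float = 1e-6,
) -> pd.DataFrame:
    """Per-predictor R2 contribution to a cause-specific Cox model.

    Importance of predictor ``p`` is ``R2(full) - R2(full minus p)``;
    the small default ridge penalizer keeps exactly collinear predictor
    sets estimable. Constant predictors get importance 0 with a warning.
    Returns a DataFrame sorted descending with a dense rank column.
    """
    base = _cause_specific(cohort, outcome)
    usable, constant = [], []
    for p in predictors:
        if cohort[p].nunique() <= 1:
            constant.append(p)
        else:
            usable.append(p)
    if constant:
        warnings.warn(f"constant predictor(s) {constant} have importance 0", stacklevel=2)
    if not usable:
        raise ValueError("no non-constant predictors supplied")

    full = _fit_cox(pd.concat([base, cohort[usable]], axis=1), penalizer)
    r2_full = cox_r2(full)
    rows = []
    for p in usable:
        rest = [q for q in usable if q != p]
        if rest:
            reduced = _fit_cox(pd.concat([base, cohort[rest]], axis=1), penalizer)
            drop = r2_full - cox_r2(reduced)
        else:
            drop = r2_full
        rows.append({"predictor": p, "outcome": outcome, "r2_contribution": max(drop, 0.0)})
    rows.extend(
        {"predictor": p, "outcome": outcome, "r2_contribution": 0.0} for p in constant
    )
    out = pd.DataFrame(rows).sort_values(
        "r2_contribution", ascending=False, kind="stable", ignore_index=True
    )
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["r2_full"] = r2_full
    return out


def fit_augmented(
    cohort: pd.DataFrame,
    spec: AugmentedModelSpec,
    base_risk,
    labs: tuple[str, ...] = LAB_COLUMNS,
    penalizer: float = 0.0,
) -> tuple[CoxPHFitter, np.ndarray]:
    """Fit one augmented Cox model: base predicted risk + laboratory labs.

    ``base_risk`` is the multinomial model's consolidated predicted risk
    for ``spec.outcome`` at ``spec.horizon`` (time-aligned). Returns the
    fitted model and its linear predictor per patient, the risk score
    used for ROC comparison.
    """
    df = _cause_specific(cohort, spec.outcome)
    df["base_risk"] = np.asarray(base_risk, dtype=float)
    for lab in labs:
        df[lab] = cohort[lab].to_numpy(dtype=float)
    cph = _fit_cox(df, penalizer)
    score = cph.predict_log_partial_hazard(df.drop(columns=["duration", "event"]))
    return cph, score.to_numpy(dtype=float)


def time_dependent_auc(score, time, event, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with KM-based IPCW.

    Cases are patients with the cause event by the horizon; controls are
    those still event-free after it; censoring is reweighted by the
    Kaplan-Meier estimate of the censoring distribution. With no
    censoring this reduces exactly to the plain binary AUC on
    event-by-horizon labels.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cause = event == 1
    if not (cause & (time <= horizon)).any():
        raise ValueError(f"no cause events by t={horizon}: AUC undefined")
    if horizon >= time.max():
        raise ValueError(
            f"horizon {horizon} is not within follow-up (max time {time.max():g})"
        )
    surv = Surv.from_arrays(event=cause, time=time)
    auc, _ = cumulative_dynamic_auc(surv, surv, score, [horizon])
    return float(auc[0])


def compare_models(
    cohort: pd.DataFrame,
    coefs: CoefficientSet,
    specs: tuple[AugmentedModelSpec, ...] = DEFAULT_MODEL_SPECS,
    labs: tuple[str, ...] = LAB_COLUMNS,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
    uacr_floor: float = 1.0,
) -> pd.DataFrame:
    """Time-dependent AUC of base vs augmented models per outcome/horizon.

    The base score is the multinomial model's consolidated risk; the
    augmented score is the Cox linear predictor of base risk + labs (the
    model is refit on every bootstrap resample). Reports the paired AUCs
    and a percentile-bootstrap CI of the AUC difference.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    horizons = sorted({s.horizon for s in specs})
    risks = predict_cohort(cohort, coefs, horizons=horizons, uacr_floor=uacr_floor)
    rows = []
    for spec in specs:
        col = f"risk_{spec.outcome}_{spec.horizon}y"
        data = cohort.copy()
        data["_base_risk"] = risks[col].to_numpy()

        def auc_diff(df, _spec=spec):
            base = df["_base_risk"].to_numpy()
            _, aug_score = fit_augmented(df, _spec, base, labs=labs)
            t = df[f"time_{_spec.outcome}"]
            e = df[f"event_{_spec.outcome}"]
            auc_base = time_dependent_auc(base, t, e, _spec.horizon)
            auc_aug = time_dependent_auc(aug_score, t, e, _spec.horizon)
            return auc_aug - auc_base

        _, aug_score = fit_augmented(data, spec, data["_base_risk"].to_numpy(), labs=labs)
        t = data[f"time_{spec.outcome}"]
        e = data[f"event_{spec.outcome}"]
        auc_base = time_dependent_auc(data["_base_risk"].to_numpy(), t, e, spec.horizon)
        auc_aug = time_dependent_auc(aug_score, t, e, spec.horizon)
        ci = bootstrap_ci(auc_diff, data, n_reps=n_boot, seed=rng)
        rows.append(
            {
                "outcome": spec.outcome,
                "horizon": spec.horizon,
                "auc_base": auc_base,
                "auc_augmented": auc_aug,
                "auc_diff": auc_aug - auc_base,
                "auc_diff_lo": ci.lo,
                "auc_diff_hi": ci.hi,
            }
        )
    return pd.DataFrame(rows)
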