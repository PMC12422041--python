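"""Calibration assessment and intercept recalibration.

Calibration-in-the-large is summarized by the observed/expected (O/E)
ratio, with observed risk from the Aalen-Johansen CIF (death competing)
or the Kaplan-Meier complement for death; calibration plots use quintile
bins ranked by predicted risk. Miscalibration is corrected by intercept
recalibration of the eight sequence linear predictors: each contrast's
intercept is shifted by

    alpha_k = ln[ (f_k / (1 - f_k)) / (m_k / (1 - m_k)) ]

where ``f_k`` is the observed frequency of sequence ``k`` and ``m_k``
the mean predicted probability. One-step application mirrors the usual
published updating rule; because the correction is exact only marginally
per state, an iterated mode repeats it to a fixed point where mean
predicted equals observed for every state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .risk import (
    ALL_CATEGORIES,
    NO_EVENT,
    STATES,
    CoefficientSet,
    predict_cohort,
)
from .survival import aalen_johansen_cif, bootstrap_ci, km_survival
from .synthetic import sequence_labels

__all__ = [
    "oe_ratio",
    "observed_risk",
    "oe_table",
    "calibration_bins",
    "intercept_correction",
    "observed_state_frequencies",
    "determinate_mask",
    "recalibrate",
    "RecalibrationResult",
]

OUTCOMES = ("krt", "cvd", "death")


def oe_ratio(observed: float, mean_predicted: float) -> float:
    """Observed-to-expected ratio; 1.0 is perfect calibration-in-the-large."""
    if mean_predicted <= 0:
        raise ValueError("mean predicted risk must be strictly positive")
    return float(observed) / float(mean_predicted)


def observed_risk(cohort: pd.DataFrame, outcome: str, horizon: float) -> float:
    """Nonparametric observed risk of an outcome at the horizon.

    KRT and CVD use the Aalen-Johansen CIF with death as the competing
    event; death uses the Kaplan-Meier complement.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    if outcome == "death":
        return 1.0 - km_survival(
            cohort["time_death"], cohort["event_death"], horizon=horizon
        )
    return aalen_johansen_cif(
        cohort[f"time_{outcome}"], cohort[f"event_{outcome}"], horizon=horizon
    )


def oe_table(
    cohort: pd.DataFrame,
    risks: pd.DataFrame,
    horizon: int,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-outcome O/E ratio with percentile-bootstrap CI.

    ``risks`` must carry the consolidated ``risk_<outcome>_<h>y`` columns
    aligned with ``cohort``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for outcome in OUTCOMES:
        col = f"risk_{outcome}_{horizon}y"
        data = cohort.copy()
        data["_pred"] = risks[col].to_numpy()

        def stat(df, _outcome=outcome):
            return oe_ratio(
                observed_risk(df, _outcome, horizon), float(df["_pred"].mean())
            )

        res = bootstrap_ci(stat, data, n_reps=n_boot, seed=rng)
        rows.append(
            {
                "outcome": outcome,
                "horizon": horizon,
                "observed": observed_risk(cohort, outcome, horizon),
                "expected": float(risks[col].mean()),
                "oe_ratio": res.point,
                "oe_lo": res.lo,
                "oe_hi": res.hi,
            }
        )
    return pd.DataFrame(rows)


def calibration_bins(
    predicted,
    cohort: pd.DataFrame,
    outcome: str,
    horizon: float,
    n_bins: int = 5,
    n_boot: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Quantile calibration bins (quintiles by default).

    Patients are ranked by predicted risk and split into ``n_bins``
    near-equal groups; each bin reports its mean predicted risk and the
    nonparametric observed risk with a percentile-bootstrap CI. When
    predictions tie so heavily that fewer distinct bins exist, the output
    carries ``df.attrs["degenerate"] = True`` and the effective bin count.
    """
    predicted = np.asarray(predicted, dtype=float)
    n = len(cohort)
    if predicted.shape[0] != n:
        raise ValueError("one prediction per patient required")
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} patients for {n_bins} bins")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_unique = np.unique(predicted).size
    if n_unique == 1:
        groups = [np.arange(n)]
    else:
        order = np.argsort(predicted, kind="stable")
        groups = np.array_split(order, n_bins)
        # merge adjacent bins whose predicted ranges collapse to one tie
        merged: list[np.ndarray] = []
        for g in groups:
            if merged and predicted[merged[-1]].max() == predicted[g].min() == predicted[g].max():
                merged[-1] = np.concatenate([merged[-1], g])
            else:
                merged.append(g)
        groups = merged

    rows = []
    for b, idx in enumerate(groups, start=1):
        sub = cohort.iloc[idx]
        obs = observed_risk(sub, outcome, horizon)
        res = bootstrap_ci(
            lambda df: observed_risk(df, outcome, horizon), sub, n_reps=n_boot, seed=rng
        )
        rows.append(
            {
                "bin": b,
                "n": len(idx),
                "mean_predicted": float(predicted[idx].mean()),
                "observed": obs,
                "observed_lo": res.lo,
                "observed_hi": res.hi,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_effective_bins"] = len(groups)
    out.attrs["degenerate"] = len(groups) < n_bins
    return out


def intercept_correction(observed_freq: float, mean_predicted: float) -> float:
    """Log-odds-ratio correction factor for one sequence's intercept."""
    for name, v in (("observed frequency", observed_freq), ("mean predicted", mean_predicted)):
        if not 0.0 < v < 1.0:
            raise ValueError(
                f"{name} must lie strictly inside (0, 1), got {v}; "
                "for zero-event states enable the continuity correction"
            )
    return math.log(
        (observed_freq / (1.0 - observed_freq))
        / (mean_predicted / (1.0 - mean_predicted))
    )


# ---------------------------------------------------------------------------
# Observed sequence-state frequencies under censoring
# ---------------------------------------------------------------------------


def determinate_mask(cohort: pd.DataFrame, horizon: float) -> np.ndarray:
    """Patients whose sequence label at the horizon is determinable:
    follow-up reaches the horizon, or at least one event is observed
    before it."""
    fup = cohort["follow_up_years"].to_numpy(dtype=float)
    any_event = np.zeros(len(cohort), dtype=bool)
    for name in OUTCOMES:
        any_event |= (cohort[f"event_{name}"].to_numpy() == 1) & (
            cohort[f"time_{name}"].to_numpy(dtype=float) <= horizon
        )
    return (fup >= horizon) | any_event


# multistate transition structure of the sequence process
_TRANSITIONS: dict[str, dict[str, str]] = {
    NO_EVENT: {"krt": "krt_only", "cvd": "cvd_only", "death": "death_only"},
    "krt_only": {"cvd": "cvd_after_krt", "death": "death_after_krt"},
    "cvd_only": {"krt": "krt_after_cvd", "death": "death_after_cvd"},
    "cvd_after_krt": {"death": "death_after_krt_cvd"},
    "krt_after_cvd": {"death": "death_after_krt_cvd"},
}
_STATE_INDEX = {s: i for i, s in enumerate(ALL_CATEGORIES)}


def _aj_state_occupation(cohort: pd.DataFrame, horizon: float) -> dict[str, float]:
    """Aalen-Johansen multistate occupation probabilities at ``horizon``.

    Product-integral over the empirical transition hazards of the
    no-event -> single-event -> ... -> death sequence process, with
    administrative censoring removing patients from every risk set.
    """
    n = len(cohort)
    fup = cohort["follow_up_years"].to_numpy(dtype=float)
    transitions: list[tuple[float, int, str, str]] = []
    for i in range(n):
        events = []
        for name in OUTCOMES:
            if cohort[f"event_{name}"].iloc[i] == 1:
                events.append((float(cohort[f"time_{name}"].iloc[i]), name))
        events.sort()
        state = NO_EVENT
        for t, ev in events:
            if t > horizon:
                break
            nxt = _TRANSITIONS[state][ev]
            transitions.append((t, i, state, nxt))
            state = nxt

    n_states = len(ALL_CATEGORIES)
    pi = np.zeros(n_states)
    pi[_STATE_INDEX[NO_EVENT]] = 1.0
    current = np.full(n, _STATE_INDEX[NO_EVENT])

    transitions.sort(key=lambda x: x[0])
    k = 0
    while k < len(transitions):
        t = transitions[k][0]
        batch = []
        while k < len(transitions) and transitions[k][0] == t:
            batch.append(transitions[k])
            k += 1
        active = fup >= t
        at_risk = np.bincount(current[active], minlength=n_states).astype(float)
        d = np.zeros((n_states, n_states))
        for _, i, a, b in batch:
            d[_STATE_INDEX[a], _STATE_INDEX[b]] += 1.0
        mat = np.eye(n_states)
        for a in range(n_states):
            if at_risk[a] > 0 and d[a].any():
                mat[a] += d[a] / at_risk[a]
                mat[a, a] -= d[a].sum() / at_risk[a]
        pi = pi @ mat
        for _, i, a, b in batch:
            current[i] = _STATE_INDEX[b]
    return {s: float(pi[_STATE_INDEX[s]]) for s in ALL_CATEGORIES}


def observed_state_frequencies(
    cohort: pd.DataFrame,
    horizon: float,
    method: str = "determinate",
    continuity_correction: bool = False,
) -> tuple[dict[str, float], int]:
    """Observed frequency of each of the 9 sequence categories at ``horizon``.

    ``method="determinate"`` (default): crude frequency among patients
    with follow-up past the horizon or an observed event before it.
    ``method="aj"``: Aalen-Johansen multistate occupation probabilities,
    which use censored patients' partial information.

    Returns ``(frequencies, n_used)``.
    """
    if method == "determinate":
        mask = determinate_mask(cohort, horizon)
        sub = cohort.loc[mask]
        if len(sub) == 0:
            raise ValueError("no patient has a determinable label at this horizon")
        labels = sequence_labels(sub, horizon)
        counts = labels.value_counts()
        n_used = len(sub)
        freqs = {}
        for cat in ALL_CATEGORIES:
            x = int(counts.get(cat, 0))
            if continuity_correction and (x == 0 or x == n_used):
                freqs[cat] = (x + 0.5) / (n_used + 1.0)
            else:
                freqs[cat] = x / n_used
        return freqs, n_used
    if method == "aj":
        freqs = _aj_state_occupation(cohort, horizon)
        if continuity_correction:
            n = len(cohort)
            freqs = {
                c: ((0.5 / (n + 1.0)) if f == 0.0 else f) for c, f in freqs.items()
            }
        return freqs, len(cohort)
    raise ValueError("method must be 'determinate' or 'aj'")


# ---------------------------------------------------------------------------
# Recalibration
# ---------------------------------------------------------------------------


@dataclass
class RecalibrationResult:
    alphas: dict[str, float]
    observed: dict[str, float]
    mean_predicted_before: dict[str, float]
    mean_predicted_after: dict[str, float]
    horizon: int
    mode: str
    n_used: int
    n_iterations: int
    converged: bool


def _mean_state_probs(
    cohort: pd.DataFrame, coefs: CoefficientSet, horizon: int, uacr_floor: float
) -> dict[str, float]:
    probs = predict_cohort(cohort, coefs, horizons=[horizon], uacr_floor=uacr_floor)
    return {s: float(probs[f"p_{s}_{horizon}y"].mean()) for s in STATES}


def recalibrate(
    coefs: CoefficientSet,
    cohort: pd.DataFrame,
    horizon: int,
    mode: str = "one-step",
    freq_method: str = "determinate",
    continuity_correction: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
    uacr_floor: float = 1.0,
) -> tuple[CoefficientSet, RecalibrationResult]:
    """Shift the 8 intercepts of ``horizon``'s block to match observed
    sequence frequencies.

    One-step mode applies the correction once; iterated mode repeats it
    until every state's mean predicted probability matches its observed
    frequency within ``tol`` (the fixed-point completion, since the
    correction is exact only marginally per state). All non-intercept
    coefficients are carried over unchanged.
    """
    if mode not in ("one-step", "iterated"):
        raise ValueError("mode must be 'one-step' or 'iterated'")
    coefs.require_horizon(horizon)
    freqs, n_used = observed_state_frequencies(
        cohort, horizon, method=freq_method, continuity_correction=continuity_correction
    )
    for state in STATES:
        if freqs[state] <= 0.0:
            raise ValueError(
                f"state {state!r} has zero observed events at {horizon}y; "
                "enable continuity_correction to proceed"
            )
    mask = (
        determinate_mask(cohort, horizon)
        if freq_method == "determinate"
        else np.ones(len(cohort), dtype=bool)
    )
    sub = cohort.loc[mask]

    before = _mean_state_probs(sub, coefs, horizon, uacr_floor)
    total_alpha = {s: 0.0 for s in STATES}
    current = coefs
    n_iter = 0
    converged = False
    max_steps = 1 if mode == "one-step" else max_iter
    for n_iter in range(1, max_steps + 1):
        mean_pred = _mean_state_probs(sub, current, horizon, uacr_floor)
        gap = max(abs(mean_pred[s] - freqs[s]) for s in STATES)
        if mode == "iterated" and gap < tol:
            converged = True
            n_iter -= 1
            break
        step = {
            s: intercept_correction(freqs[s], mean_pred[s]) for s in STATES
        }
        total_alpha = {s: total_alpha[s] + step[s] for s in STATES}
        current = current.shifted(step, horizon)
    after = _mean_state_probs(sub, current, horizon, uacr_floor)
    if mode == "iterated" and not converged:
        converged = max(abs(after[s] - freqs[s]) for s in STATES) < tol
    result = RecalibrationResult(
        alphas=total_alpha,
        observed={s: freqs[s] for s in STATES},
        mean_predicted_before=before,
        mean_predicted_after=after,
        horizon=int(horizon),
        mode=mode,
        n_used=n_used,
        n_iterations=n_iter,
        converged=converged if mode == "iterated" else True,
    )
    return current, result
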