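"""Nonparametric observed-risk estimation and discrimination.

Aalen-Johansen cumulative incidence with death as a competing event,
Kaplan-Meier survival, a competing-risk concordance index (Wolbers-style:
patients with the competing event stay in the comparison set as controls),
and a percentile bootstrap for confidence intervals.

Event coding throughout: ``0`` censored, ``1`` cause of interest,
``2`` competing event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "CifCurve",
    "aalen_johansen_cif",
    "km_survival",
    "km_curve",
    "competing_risk_cindex",
    "bootstrap_ci",
    "BootstrapResult",
]

logger = logging.getLogger(__name__)


@dataclass
class CifCurve:
    """A right-continuous step function estimated at event times.

    ``values[i]`` is the function value on ``[times[i], times[i+1])``;
    before ``times[0]`` the value is ``baseline``.
    """

    times: np.ndarray
    values: np.ndarray
    baseline: float = 0.0

    def at(self, t: float) -> float:
        """Value at time ``t`` (value at the largest jump time <= t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.values[idx]) if idx >= 0 else self.baseline


def _check_records(time, event, allowed_events) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("need at least one record")
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("times must be finite and strictly positive")
    if not np.isin(event, allowed_events).all():
        raise ValueError(f"event codes must be in {sorted(allowed_events)}")
    return time, event


def aalen_johansen_cif(
    time, event, horizon: float | None = None, cause: int = 1
) -> CifCurve | float:
    """Aalen-Johansen cumulative incidence of ``cause``.

    Combines the overall (all-event) product-limit survival with the
    cause-specific hazard increments:
    ``CIF(t) = sum_{t_i <= t} S(t_i-) * d_cause(t_i) / n(t_i)``.
    Ties between cause, competing and censoring times are handled by the
    standard convention (events at ``t`` precede censorings at ``t``;
    both event types share the risk set at ``t``).

    Returns the :class:`CifCurve`, or ``CIF(horizon)`` when ``horizon``
    is given.
    """
    time, event = _check_records(time, event, (0, 1, 2))
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    uniq, start = np.unique(time, return_index=True)
    # counts per distinct time
    n = time.size
    n_at_risk = n - start
    d_cause = np.add.reduceat((event == cause).astype(float), start)
    d_any = np.add.reduceat((event != 0).astype(float), start)

    frac_any = d_any / n_at_risk
    surv_before = np.concatenate([[1.0], np.cumprod(1.0 - frac_any)[:-1]])
    increments = surv_before * d_cause / n_at_risk
    curve = CifCurve(times=uniq, values=np.cumsum(increments), baseline=0.0)
    return curve.at(horizon) if horizon is not None else curve


def km_curve(time, event) -> CifCurve:
    """Kaplan-Meier survival step function (event coded 1, censored 0)."""
    time, event = _check_records(time, event, (0, 1))
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq, start = np.unique(time, return_index=True)
    n_at_risk = time.size - start
    d = np.add.reduceat((event == 1).astype(float), start)
    surv = np.cumprod(1.0 - d / n_at_risk)
    return CifCurve(times=uniq, values=surv, baseline=1.0)


def km_survival(time, event, horizon: float | None = None) -> CifCurve | float:
    """Kaplan-Meier survival, optionally evaluated at ``horizon``."""
    curve = km_curve(time, event)
    return curve.at(horizon) if horizon is not None else curve


def competing_risk_cindex(risk, time, event, horizon: float | None = None) -> float:
    """Concordance index adapted to competing risks.

    A pair ``(i, j)`` with ``i`` a case (cause event at ``t_i``, and
    ``t_i <= horizon`` when a horizon is given) is usable when ``j`` is
    known to be event-free for the cause at ``t_i``: either ``t_j > t_i``,
    or ``j`` experienced the competing event (competing-event patients
    are retained as controls for the cause of interest at all times).
    Pairs with tied event times (both cases at the same time) are
    unusable; tied risks score 0.5.

    Raises when no usable pair exists rather than returning NaN.
    """
    risk = np.asarray(risk, dtype=float)
    time, event = _check_records(time, event, (0, 1, 2))
    if risk.shape != time.shape:
        raise ValueError("one risk per record required")
    if np.any(~np.isfinite(risk)):
        raise ValueError("risks must be finite")

    cases = event == 1
    if horizon is not None:
        cases = cases & (time <= horizon)
    case_idx = np.flatnonzero(cases)
    if case_idx.size == 0:
        raise ValueError("no usable pairs: no cause events (by the horizon)")

    conc = 0.0
    n_usable = 0.0
    # chunk over cases to bound memory at n_chunk * n
    chunk = max(1, int(2_000_000 // max(time.size, 1)))
    for lo in range(0, case_idx.size, chunk):
        ci = case_idx[lo : lo + chunk]
        t_i = time[ci][:, None]
        r_i = risk[ci][:, None]
        usable = (time[None, :] > t_i) | (event[None, :] == 2)
        # a case cannot be paired with itself (its own time is not > t_i
        # and its event is not competing, but guard against t ties)
        usable[np.arange(ci.size), ci] = False
        # tied cause-event times are unusable
        usable &= ~((event[None, :] == 1) & (time[None, :] == t_i))
        greater = r_i > risk[None, :]
        equal = r_i == risk[None, :]
        conc += (usable & greater).sum() + 0.5 * (usable & equal).sum()
        n_usable += usable.sum()
    if n_usable == 0:
        raise ValueError("no usable pairs for concordance")
    return float(conc / n_usable)


@dataclass
class BootstrapResult:
    point: float
    lo: float
    hi: float
    n_reps: int

    def __iter__(self):
        return iter((self.point, self.lo, self.hi))


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    max_retries: int = 100,
) -> BootstrapResult:
    """Percentile bootstrap CI over patient-level resamples.

    ``statistic`` maps a cohort DataFrame to a scalar. Resamples on which
    the statistic fails (e.g. a resample with no events) are logged and
    redrawn up to ``max_retries`` times in total.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(cohort)
    point = float(statistic(cohort))
    values = np.empty(n_reps)
    retries = 0
    i = 0
    while i < n_reps:
        idx = rng.integers(0, n, n)
        sample = cohort.iloc[idx].reset_index(drop=True)
        try:
            values[i] = float(statistic(sample))
        except Exception as exc:  # noqa: BLE001 - resample-level failure
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    f"bootstrap statistic failed on {retries} resamples"
                ) from exc
            logger.warning("bootstrap resample failed (%s); redrawing", exc)
            continue
        i += 1
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(point=point, lo=float(lo), hi=float(hi), n_reps=n_reps)
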