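"""Decision curve analysis and clinical-impact projection.

Applies KRT-preparation decision rules (2-year predicted KRT risk
thresholds, eGFR thresholds, or their OR-combination), classifies each
flagged patient against KRT initiation within one year, and reports net
benefit

    NB(pt) = TP/n - (FP/n) * pt / (1 - pt)

alongside sensitivity, specificity, PPV and NPV, with treat-all and
treat-none reference strategies. Boundary conventions: risk rules are
strict ``>``, eGFR rules strict ``<``; the model-as-continuous-rule flags
``risk >= pt``. One year is 365.25 days; patients censored before one
year without KRT are excluded from the one-year classification
(complete-case), with the exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionRule",
    "ConfusionCounts",
    "DEFAULT_RULES",
    "apply_rule",
    "krt_within_year",
    "confusion",
    "net_benefit",
    "dca_curve",
]

ONE_YEAR = 365.25 / 365.25  # years


@dataclass(frozen=True)
class DecisionRule:
    """A KRT-preparation referral rule.

    ``risk_threshold``: flag when 2-year predicted KRT risk > risk_cut.
    ``egfr_threshold``: flag when eGFR < egfr_cut.
    ``combined``: logical OR of the two.
    ``model_risk``: flag when predicted risk >= the DCA threshold
    probability (the model used as a continuous rule; only meaningful
    inside :func:`dca_curve`).
    """

    kind: str
    risk_cut: float | None = None
    egfr_cut: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("risk_threshold", "egfr_threshold", "combined", "model_risk"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind in ("risk_threshold", "combined"):
            if self.risk_cut is None or not 0.0 < self.risk_cut < 1.0:
                raise ValueError("risk_cut must lie in (0, 1) for this rule kind")
        if self.kind in ("egfr_threshold", "combined"):
            if self.egfr_cut is None or self.egfr_cut <= 0:
                raise ValueError("egfr_cut must be positive for this rule kind")

    @property
    def name(self) -> str:
        if self.kind == "risk_threshold":
            return f"risk>{self.risk_cut:g}"
        if self.kind == "egfr_threshold":
            return f"egfr<{self.egfr_cut:g}"
        if self.kind == "combined":
            return f"risk>{self.risk_cut:g} or egfr<{self.egfr_cut:g}"
        return "model"


#: The rule set evaluated in the validation workflow: 2-year KRT risk
#: thresholds of 20-50%, eGFR thresholds of <30/<20/<15, and the
#: guideline combination (risk > 50% and/or eGFR < 15).
DEFAULT_RULES: tuple[DecisionRule, ...] = (
    DecisionRule("risk_threshold", risk_cut=0.2),
    DecisionRule("risk_threshold", risk_cut=0.3),
    DecisionRule("risk_threshold", risk_cut=0.4),
    DecisionRule("risk_threshold", risk_cut=0.5),
    DecisionRule("egfr_threshold", egfr_cut=30.0),
    DecisionRule("egfr_threshold", egfr_cut=20.0),
    DecisionRule("egfr_threshold", egfr_cut=15.0),
    DecisionRule("combined", risk_cut=0.5, egfr_cut=15.0),
)


def apply_rule(rule: DecisionRule, risk=None, egfr=None, pt: float | None = None):
    """Flag patients for KRT preparation under ``rule`` (vectorized)."""
    if rule.kind in ("risk_threshold", "combined", "model_risk") and risk is None:
        raise ValueError(f"rule {rule.name!r} requires predicted risks")
    if rule.kind in ("egfr_threshold", "combined") and egfr is None:
        raise ValueError(f"rule {rule.name!r} requires eGFR values")
    if rule.kind == "risk_threshold":
        return np.asarray(risk, dtype=float) > rule.risk_cut
    if rule.kind == "egfr_threshold":
        return np.asarray(egfr, dtype=float) < rule.egfr_cut
    if rule.kind == "combined":
        return (np.asarray(risk, dtype=float) > rule.risk_cut) | (
            np.asarray(egfr, dtype=float) < rule.egfr_cut
        )
    if pt is None:
        raise ValueError("model_risk rule needs the threshold probability pt")
    return np.asarray(risk, dtype=float) >= pt


def krt_within_year(cohort: pd.DataFrame, window: float = ONE_YEAR):
    """One-year KRT initiation status.

    Returns ``(status, determinate)``: ``status`` is True when KRT was
    initiated within the window; ``determinate`` is False for patients
    censored before the window without KRT (their status is unknowable).
    Death before the window is a determinate negative.
    """
    time = cohort["time_krt"].to_numpy(dtype=float)
    event = cohort["event_krt"].to_numpy(dtype=int)
    status = (event == 1) & (time <= window)
    determinate = status | (time >= window) | (event == 2)
    return status, determinate


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def _ratio(self, num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    @property
    def sensitivity(self):
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self):
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self):
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self):
        return self._ratio(self.tn, self.tn + self.fn)


def confusion(
    rule: DecisionRule,
    cohort: pd.DataFrame,
    risk=None,
    window: float = ONE_YEAR,
    pt: float | None = None,
) -> tuple[ConfusionCounts, int]:
    """Confusion counts of a rule against one-year KRT initiation.

    Returns ``(counts, n_excluded)`` where ``n_excluded`` is the number
    of patients censored before the window without KRT. Undefined metric
    ratios (zero denominators) are reported as ``None`` by the counts
    object rather than NaN.
    """
    egfr = cohort["egfr"].to_numpy(dtype=float) if "egfr" in cohort else None
    flagged = apply_rule(rule, risk=risk, egfr=egfr, pt=pt)
    status, determinate = krt_within_year(cohort, window=window)
    f, s = flagged[determinate], status[determinate]
    counts = ConfusionCounts(
        tp=int((f & s).sum()),
        fp=int((f & ~s).sum()),
        fn=int((~f & s).sum()),
        tn=int((~f & ~s).sum()),
    )
    return counts, int((~determinate).sum())


def net_benefit(counts: ConfusionCounts, pt: float) -> float:
    """Net benefit of a classification at threshold probability ``pt``."""
    if not 0.0 < pt < 1.0:
        raise ValueError("threshold probability must lie strictly in (0, 1)")
    if counts.n == 0:
        raise ValueError("empty classification")
    return counts.tp / counts.n - (counts.fp / counts.n) * (pt / (1.0 - pt))


def dca_curve(
    rules: Sequence[DecisionRule],
    cohort: pd.DataFrame,
    risk,
    pt_grid: Iterable[float] | None = None,
    window: float = ONE_YEAR,
    include_model_rule: bool = True,
) -> pd.DataFrame:
    """Net benefit of each rule over a threshold-probability grid.

    Long-format table (rule, pt, net_benefit) including the treat-all and
    treat-none references and, optionally, the model's own risk as a
    continuous rule (flag when risk >= pt). The best rule per pt is
    marked in the ``best`` column.
    """
    if pt_grid is None:
        pt_grid = np.round(np.arange(0.01, 0.5001, 0.01), 10)
    pt_grid = np.asarray(list(pt_grid), dtype=float)
    if pt_grid.size == 0:
        raise ValueError("threshold-probability grid must be non-empty")
    if np.any((pt_grid <= 0) | (pt_grid >= 1)):
        raise ValueError("threshold probabilities must lie strictly in (0, 1)")

    status, determinate = krt_within_year(cohort, window=window)
    n_det = int(determinate.sum())
    if n_det == 0:
        raise ValueError("no patient has a determinable one-year KRT status")
    n_pos = int(status[determinate].sum())

    all_rules: list[DecisionRule] = list(rules)
    if include_model_rule:
        all_rules.append(DecisionRule("model_risk"))

    rows = []
    for pt in pt_grid:
        # references
        treat_all = ConfusionCounts(tp=n_pos, fp=n_det - n_pos, fn=0, tn=0)
        rows.append({"rule": "treat_all", "pt": pt, "net_benefit": net_benefit(treat_all, pt)})
        rows.append({"rule": "treat_none", "pt": pt, "net_benefit": 0.0})
        for rule in all_rules:
            counts, _ = confusion(rule, cohort, risk=risk, window=window, pt=pt)
            rows.append({"rule": rule.name, "pt": pt, "net_benefit": net_benefit(counts, pt)})
    out = pd.DataFrame(rows)
    best = out.loc[out.groupby("pt")["net_benefit"].idxmax(), ["pt", "rule"]]
    best_map = dict(zip(best["pt"], best["rule"]))
    out["best"] = [best_map[pt] == r for pt, r in zip(out["pt"], out["rule"])]
    return out
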