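"""Synthetic advanced-CKD cohort generator.

Generates cohorts with the statistical structure the validation pipeline
assumes: baseline covariates matched to the marginals of a contemporary
advanced-CKD cohort (median age 54 [43-64] years, 52.4% male, median eGFR
22.3 [17.3-26.3] mL/min/1.73 m2, median uACR 549.4 [158.7-1248.3] mg/g),
outcome sequences drawn from a known multinomial model over the eight
KRT/CVD/death orderings, latent event times placed as uniform order
statistics within the horizon, and independent uniform administrative
censoring. Because the generating model is known, calibration,
discrimination and recalibration recovery are all testable.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .risk import (
    ALL_CATEGORIES,
    NO_EVENT,
    STATES,
    CoefficientSet,
    invert_egfr,
    predict_cohort,
)

__all__ = [
    "CohortSpec",
    "LAB_COLUMNS",
    "DEFAULT_STATE_TARGETS",
    "BALANCED_STATE_TARGETS",
    "EVENT_THINNING_2Y",
    "generate_covariates",
    "simulate_events",
    "generate_cohort",
    "sequence_labels",
    "make_reference_coefficients",
]

#: Laboratory analytes available for model augmentation, with units.
LAB_COLUMNS = (
    "albumin",  # g/L
    "total_cholesterol",  # mmol/L
    "hdl_cholesterol",  # mmol/L
    "hemoglobin",  # g/L
    "calcium",  # mmol/L
    "phosphorus",  # mmol/L
    "bicarbonate",  # mmol/L
)

_DEFAULT_LAB_MEANS = {
    "albumin": 38.0,
    "total_cholesterol": 4.8,
    "hdl_cholesterol": 1.2,
    "hemoglobin": 110.0,
    "calcium": 2.2,
    "phosphorus": 1.4,
    "bicarbonate": 22.0,
}
_DEFAULT_LAB_SDS = {
    "albumin": 6.0,
    "total_cholesterol": 1.2,
    "hdl_cholesterol": 0.35,
    "hemoglobin": 20.0,
    "calcium": 0.2,
    "phosphorus": 0.35,
    "bicarbonate": 4.0,
}


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the printed marginals of the validation cohort the
    pipeline emulates; continuous medians/IQRs are matched exactly for
    eGFR and uACR (truncated-normal and log-normal quantile transforms)
    and binaries are Bernoulli at the stated fractions. eGFR and uACR
    share a Gaussian copula with configurable negative rank correlation,
    giving a realistic risk spread.
    """

    n_patients: int = 1333
    seed: int = 0
    age_median: float = 54.0
    age_iqr: tuple[float, float] = (43.0, 64.0)
    pct_male: float = 0.524
    pct_black: float = 0.0
    pct_cvd_history: float = 0.131
    pct_diabetes: float = 0.264
    pct_smoking: float = 0.30
    sbp_mean: float = 135.0
    sbp_sd: float = 18.0
    egfr_median: float = 22.3
    egfr_iqr: tuple[float, float] = (17.3, 26.3)
    egfr_bounds: tuple[float, float] = (1.0, 30.0)
    uacr_median: float = 549.4
    uacr_iqr: tuple[float, float] = (158.7, 1248.3)
    egfr_uacr_rank_corr: float = -0.3
    lab_means: dict = field(default_factory=lambda: dict(_DEFAULT_LAB_MEANS))
    lab_sds: dict = field(default_factory=lambda: dict(_DEFAULT_LAB_SDS))
    censoring_min_years: float = 0.0
    censoring_admin_years: float = 6.0
    horizon_set: tuple[int, ...] = (2, 4)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients: must be >= 1")
        for name in ("pct_male", "pct_black", "pct_cvd_history", "pct_diabetes", "pct_smoking"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: fraction must lie in [0, 1], got {v}")
        lo, hi = self.egfr_bounds
        if not (0.0 < lo < hi <= 30.0):
            raise ValueError("egfr_bounds: must satisfy 0 < lo < hi <= 30 for advanced CKD")
        if not lo < self.egfr_median < hi:
            raise ValueError("egfr_median: must lie inside egfr_bounds")
        for name in ("age_iqr", "egfr_iqr", "uacr_iqr"):
            q1, q3 = getattr(self, name)
            if not q1 < q3:
                raise ValueError(f"{name}: lower quartile must be below upper quartile")
        if self.uacr_median <= 0:
            raise ValueError("uacr_median: must be positive")
        if self.sbp_sd <= 0 or self.sbp_mean <= 0:
            raise ValueError("sbp_mean/sbp_sd: must be positive")
        if not -1.0 < self.egfr_uacr_rank_corr < 1.0:
            raise ValueError("egfr_uacr_rank_corr: must lie in (-1, 1)")
        if self.censoring_admin_years <= 0:
            raise ValueError("censoring_admin_years: must be positive")
        if not 0.0 <= self.censoring_min_years < self.censoring_admin_years:
            raise ValueError(
                "censoring_min_years: must lie in [0, censoring_admin_years)"
            )
        missing = set(LAB_COLUMNS) - set(self.lab_means)
        if missing:
            raise ValueError(f"lab_means: missing analytes {sorted(missing)}")
        missing = set(LAB_COLUMNS) - set(self.lab_sds)
        if missing:
            raise ValueError(f"lab_sds: missing analytes {sorted(missing)}")

    # -- YAML I/O -----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["age_iqr"] = list(self.age_iqr)
        d["egfr_iqr"] = list(self.egfr_iqr)
        d["egfr_bounds"] = list(self.egfr_bounds)
        d["uacr_iqr"] = list(self.uacr_iqr)
        d["horizon_set"] = list(self.horizon_set)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("age_iqr", "egfr_iqr", "egfr_bounds", "uacr_iqr", "horizon_set"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


_IQR_TO_SD = 2.0 * stats.norm.ppf(0.75)  # ~1.349


def _trunc_norm_params(median: float, iqr: tuple[float, float], bounds: tuple[float, float]):
    """Location of a truncated normal whose median matches ``median``.

    The scale comes from the IQR of the untruncated normal; the location
    is then solved so the *truncated* median is exact.
    """
    sd = (iqr[1] - iqr[0]) / _IQR_TO_SD
    lo, hi = bounds

    def median_gap(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.median(a, b, loc=mu, scale=sd) - median

    mu = optimize.brentq(median_gap, lo - 5 * sd, hi + 5 * sd)
    return mu, sd


def generate_covariates(spec: CohortSpec) -> pd.DataFrame:
    """Draw baseline covariates for ``spec.n_patients`` patients.

    Reproducible for a fixed ``spec.seed``. Serum creatinine is derived
    by analytic inversion of the CKD-EPI equation so that eGFR, age, sex
    and race are internally consistent.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    age_sd = (spec.age_iqr[1] - spec.age_iqr[0]) / _IQR_TO_SD
    age = np.clip(rng.normal(spec.age_median, age_sd, n), 18.0, 90.0)

    male = rng.random(n) < spec.pct_male
    black = rng.random(n) < spec.pct_black
    cvd_history = rng.random(n) < spec.pct_cvd_history
    diabetes = rng.random(n) < spec.pct_diabetes
    smoking = rng.random(n) < spec.pct_smoking

    # Gaussian copula between eGFR and uACR (negative rank correlation).
    rho = 2.0 * math.sin(math.pi * spec.egfr_uacr_rank_corr / 6.0)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)

    mu_e, sd_e = _trunc_norm_params(spec.egfr_median, spec.egfr_iqr, spec.egfr_bounds)
    a, b = (spec.egfr_bounds[0] - mu_e) / sd_e, (spec.egfr_bounds[1] - mu_e) / sd_e
    egfr = stats.truncnorm.ppf(stats.norm.cdf(z1), a, b, loc=mu_e, scale=sd_e)

    sigma_ln = math.log(spec.uacr_iqr[1] / spec.uacr_iqr[0]) / _IQR_TO_SD
    uacr = np.exp(math.log(spec.uacr_median) + sigma_ln * z2)

    sbp = np.clip(rng.normal(spec.sbp_mean, spec.sbp_sd, n), 70.0, 250.0)

    cohort = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": age,
            "male": male.astype(int),
            "black": black.astype(int),
            "cvd_history": cvd_history.astype(int),
            "smoking": smoking.astype(int),
            "diabetes": diabetes.astype(int),
            "sbp": sbp,
            "egfr": egfr,
            "uacr": uacr,
        }
    )
    cohort["scr"] = invert_egfr(egfr, age, male, black)
    for lab in LAB_COLUMNS:
        mean, sd = spec.lab_means[lab], spec.lab_sds[lab]
        cohort[lab] = np.clip(rng.normal(mean, sd, n), max(mean - 5 * sd, 0.05), None)
    return cohort


# ---------------------------------------------------------------------------
# Outcome sequences
# ---------------------------------------------------------------------------

# Ordered events of each sequence. death_after_krt_cvd has two admissible
# internal orderings (KRT/CVD in either order before death); the simulator
# picks one uniformly.
_SEQUENCE_EVENTS: dict[str, tuple[tuple[str, ...], ...]] = {
    "krt_only": (("krt",),),
    "krt_after_cvd": (("cvd", "krt"),),
    "cvd_only": (("cvd",),),
    "cvd_after_krt": (("krt", "cvd"),),
    "death_only": (("death",),),
    "death_after_krt": (("krt", "death"),),
    "death_after_cvd": (("cvd", "death"),),
    "death_after_krt_cvd": (("krt", "cvd", "death"), ("cvd", "krt", "death")),
}

#: Exact distribution of the 2-year sequence label given the 4-year
#: category, when event times are uniform order statistics on (0, 4]
#: (each latent event independently falls in (0, 2] with probability 1/2).
EVENT_THINNING_2Y: dict[str, dict[str, float]] = {
    "krt_only": {NO_EVENT: 0.5, "krt_only": 0.5},
    "krt_after_cvd": {NO_EVENT: 0.25, "cvd_only": 0.5, "krt_after_cvd": 0.25},
    "cvd_only": {NO_EVENT: 0.5, "cvd_only": 0.5},
    "cvd_after_krt": {NO_EVENT: 0.25, "krt_only": 0.5, "cvd_after_krt": 0.25},
    "death_only": {NO_EVENT: 0.5, "death_only": 0.5},
    "death_after_krt": {NO_EVENT: 0.25, "krt_only": 0.5, "death_after_krt": 0.25},
    "death_after_cvd": {NO_EVENT: 0.25, "cvd_only": 0.5, "death_after_cvd": 0.25},
    "death_after_krt_cvd": {
        NO_EVENT: 1 / 8,
        "krt_only": 3 / 16,
        "cvd_only": 3 / 16,
        "krt_after_cvd": 3 / 16,
        "cvd_after_krt": 3 / 16,
        "death_after_krt_cvd": 1 / 8,
    },
    NO_EVENT: {NO_EVENT: 1.0},
}

EVENT_COLUMNS = (
    "time_krt",
    "event_krt",
    "time_cvd",
    "event_cvd",
    "time_death",
    "event_death",
    "follow_up_years",
    "seq_label_2y",
    "seq_label_4y",
)


def sequence_labels(cohort: pd.DataFrame, horizon: float) -> pd.Series:
    """Observed outcome-sequence label at ``horizon``.

    A deterministic function of the per-outcome (time, event) records:
    an outcome counts iff its event indicator marks the cause and its
    time is within the horizon; the label orders the observed outcomes.
    """
    inf = np.inf
    t_k = np.where((cohort["event_krt"] == 1) & (cohort["time_krt"] <= horizon),
                   cohort["time_krt"], inf)
    t_c = np.where((cohort["event_cvd"] == 1) & (cohort["time_cvd"] <= horizon),
                   cohort["time_cvd"], inf)
    t_d = np.where((cohort["event_death"] == 1) & (cohort["time_death"] <= horizon),
                   cohort["time_death"], inf)
    k, c, d = t_k < inf, t_c < inf, t_d < inf
    label = np.select(
        [
            k & c & d,
            k & d,
            c & d,
            d,
            k & c & (t_c < t_k),
            k & c,
            k,
            c,
        ],
        [
            "death_after_krt_cvd",
            "death_after_krt",
            "death_after_cvd",
            "death_only",
            "krt_after_cvd",
            "cvd_after_krt",
            "krt_only",
            "cvd_only",
        ],
        default=NO_EVENT,
    )
    return pd.Series(label, index=cohort.index, name=f"seq_label_{int(horizon)}y")


def simulate_events(
    cohort: pd.DataFrame,
    coefs: CoefficientSet,
    spec: CohortSpec,
    event_horizon: float = 4.0,
) -> pd.DataFrame:
    """Draw outcome sequences and event times for every patient.

    For each patient a category is drawn from the patient's multinomial
    state probabilities at the 4-year horizon; latent event times within
    the sequence are uniform order statistics on ``(0, event_horizon]``;
    independent administrative censoring
    ``U(censoring_min_years, censoring_admin_years)``
    is then applied. The 2-year label is derived from the same latent
    times (nested), never re-drawn.

    Returns a copy of ``cohort`` with per-outcome time/event columns
    (event codes: 0 censored, 1 cause, 2 death-as-competing), overall
    follow-up, and observed sequence labels at 2 and 4 years.
    """
    coefs.require_horizon(int(event_horizon))
    probs = predict_cohort(cohort, coefs, horizons=[int(event_horizon)])
    h = int(event_horizon)
    p = probs[[f"p_{c}_{h}y" for c in ALL_CATEGORIES]].to_numpy()

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 2]))
    n = len(cohort)
    u = rng.random(n)
    cat_idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    cat_idx = np.minimum(cat_idx, len(ALL_CATEGORIES) - 1)

    t_krt = np.full(n, np.nan)
    t_cvd = np.full(n, np.nan)
    t_death = np.full(n, np.nan)
    variant_u = rng.random(n)  # internal ordering for 3-event sequences
    event_u = rng.random((n, 3))

    for i_cat, cat in enumerate(ALL_CATEGORIES):
        idx = np.flatnonzero(cat_idx == i_cat)
        if idx.size == 0 or cat == NO_EVENT:
            continue
        variants = _SEQUENCE_EVENTS[cat]
        k = len(variants[0])
        times = np.sort(event_u[idx, :k] * event_horizon, axis=1)
        if len(variants) == 1:
            orders = [variants[0]] * idx.size
        else:
            orders = [variants[0] if v < 0.5 else variants[1] for v in variant_u[idx]]
        for row, (pi, order) in enumerate(zip(idx, orders)):
            for j, ev in enumerate(order):
                if ev == "krt":
                    t_krt[pi] = times[row, j]
                elif ev == "cvd":
                    t_cvd[pi] = times[row, j]
                else:
                    t_death[pi] = times[row, j]

    censor = rng.uniform(spec.censoring_min_years, spec.censoring_admin_years, n)

    out = cohort.copy()
    inf = np.inf
    tk = np.where(np.isnan(t_krt), inf, t_krt)
    tc = np.where(np.isnan(t_cvd), inf, t_cvd)
    td = np.where(np.isnan(t_death), inf, t_death)

    # death record: death is terminal, censored only administratively
    death_obs = td <= censor
    out["time_death"] = np.where(death_obs, td, censor)
    out["event_death"] = death_obs.astype(int)
    out["follow_up_years"] = out["time_death"]

    # cause-specific records with death as the competing event
    for name, t_cause in (("krt", tk), ("cvd", tc)):
        cause_obs = t_cause <= censor  # cause precedes death within a sequence
        competing = (~cause_obs) & death_obs
        out[f"time_{name}"] = np.where(
            cause_obs, t_cause, np.where(competing, td, censor)
        )
        out[f"event_{name}"] = np.where(cause_obs, 1, np.where(competing, 2, 0))

    out["seq_label_2y"] = sequence_labels(out, 2.0)
    out["seq_label_4y"] = sequence_labels(out, 4.0)
    return out


def generate_cohort(spec: CohortSpec, coefs: CoefficientSet) -> pd.DataFrame:
    """Covariates plus simulated outcomes in one call."""
    return simulate_events(generate_covariates(spec), coefs, spec)


# ---------------------------------------------------------------------------
# Reference coefficients
# ---------------------------------------------------------------------------

#: 4-year mean state-probability targets emulating the validation
#: cohort's outcome mix (KRT ~26%, CVD ~8%, death ~5% within 4 years).
DEFAULT_STATE_TARGETS: dict[str, float] = {
    "krt_only": 0.200,
    "krt_after_cvd": 0.012,
    "cvd_only": 0.032,
    "cvd_after_krt": 0.020,
    "death_only": 0.012,
    "death_after_krt": 0.020,
    "death_after_cvd": 0.008,
    "death_after_krt_cvd": 0.008,
}

#: Equal-mass targets (each sequence ~8.5%): the regime for estimator
#: self-consistency checks, where no sequence is so rare that its
#: crude-frequency logit is dominated by Monte-Carlo noise.
BALANCED_STATE_TARGETS: dict[str, float] = {s: 0.085 for s in STATES}

# Plausible covariate effects per outcome family (on the processed scale:
# per center-scale unit for age/eGFR/SBP, per decade of uACR).
_SLOPE_TEMPLATES: dict[str, dict[str, float]] = {
    "krt": {
        "egfr_c": -1.0,
        "log10_uacr": 0.8,
        "diabetes": 0.3,
        "sbp_c": 0.2,
        "age_c": -0.2,
        "male": 0.1,
    },
    "cvd": {
        "age_c": 0.5,
        "cvd_history": 1.0,
        "smoking": 0.4,
        "diabetes": 0.4,
        "sbp_c": 0.3,
        "egfr_c": -0.2,
    },
    "death": {
        "age_c": 0.7,
        "cvd_history": 0.6,
        "smoking": 0.3,
        "egfr_c": -0.3,
        "log10_uacr": 0.2,
        "male": 0.1,
    },
}

_STATE_FAMILIES: dict[str, tuple[str, ...]] = {
    "krt_only": ("krt",),
    "krt_after_cvd": ("krt", "cvd"),
    "cvd_only": ("cvd",),
    "cvd_after_krt": ("krt", "cvd"),
    "death_only": ("death",),
    "death_after_krt": ("krt", "death"),
    "death_after_cvd": ("cvd", "death"),
    "death_after_krt_cvd": ("krt", "cvd", "death"),
}


def _representative_point(spec: CohortSpec) -> dict[str, float]:
    """Processed covariates of the cohort's 'typical' patient."""
    return {
        "age_c": 0.0,
        "egfr_c": 0.0,
        "sbp_c": 0.0,
        "log10_uacr": math.log10(spec.uacr_median),
        "male": spec.pct_male,
        "black": spec.pct_black,
        "cvd_history": spec.pct_cvd_history,
        "smoking": spec.pct_smoking,
        "diabetes": spec.pct_diabetes,
    }


def _thinning_matrix() -> np.ndarray:
    """(9, 9) matrix T with T[i4, i2] = P(2y label | 4y category)."""
    idx = {c: i for i, c in enumerate(ALL_CATEGORIES)}
    T = np.zeros((len(ALL_CATEGORIES), len(ALL_CATEGORIES)))
    for cat4, dist in EVENT_THINNING_2Y.items():
        for cat2, w in dist.items():
            T[idx[cat4], idx[cat2]] = w
    return T


def make_reference_coefficients(
    seed: int,
    state_targets: Mapping[str, float] | None = None,
    slope_scale: float = 1.0,
    spec: CohortSpec | None = None,
    n_probe: int = 8000,
) -> CoefficientSet:
    """A fully populated synthetic coefficient set, deterministic per seed.

    This is a stand-in with clinically plausible effect directions (lower
    eGFR and higher uACR raise KRT risk; age, CVD history and smoking
    raise CVD/death risk), NOT the published model's coefficients, which
    are user-supplied input. Intercepts are moment-matched on a
    deterministic probe cohort drawn from ``spec`` so that the 4-year
    mean state probabilities equal ``state_targets`` and the 2-year block
    (sharing the slopes) equals the exact thinned 2-year distribution
    implied by uniform order-statistic event times — the two horizons are
    mutually consistent in the large for cohorts drawn from ``spec``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    spec = spec or CohortSpec()
    targets = dict(state_targets or DEFAULT_STATE_TARGETS)
    missing = set(STATES) - set(targets)
    if missing:
        raise ValueError(f"state_targets missing {sorted(missing)}")
    total = sum(targets[s] for s in STATES)
    if not 0.0 < total < 1.0:
        raise ValueError("state targets must sum to a value in (0, 1)")
    p0 = 1.0 - total

    xbar = _representative_point(spec)

    slopes: dict[str, dict[str, float]] = {}
    for state in STATES:
        fams = _STATE_FAMILIES[state]
        merged: dict[str, float] = {}
        for fam in fams:
            for name, val in _SLOPE_TEMPLATES[fam].items():
                merged[name] = merged.get(name, 0.0) + val / len(fams)
        jittered = {
            name: slope_scale * (val + rng.normal(0.0, 0.05 * abs(val) + 0.02))
            for name, val in merged.items()
        }
        slopes[state] = jittered

    def intercept_for(state: str, target_k: float, target_0: float) -> float:
        lp_at_xbar = sum(v * xbar[name] for name, v in slopes[state].items())
        return math.log(target_k / target_0) - lp_at_xbar

    p4 = {**{s: targets[s] for s in STATES}, NO_EVENT: p0}
    horizons: dict[int, dict[str, dict]] = {}
    for h in (4, 2):
        horizons[h] = {
            state: {
                "intercept": intercept_for(state, p4[state], p4[NO_EVENT]),
                "coefficients": dict(slopes[state]),
            }
            for state in STATES
        }

    centers = {"age": spec.age_median, "egfr": spec.egfr_median, "sbp": spec.sbp_mean}
    scales = {
        "age": (spec.age_iqr[1] - spec.age_iqr[0]) / _IQR_TO_SD,
        "egfr": (spec.egfr_iqr[1] - spec.egfr_iqr[0]) / _IQR_TO_SD,
        "sbp": spec.sbp_sd,
    }
    coefs = CoefficientSet(centers=centers, scales=scales, horizons=horizons)

    # moment-match intercepts on a deterministic probe cohort
    probe_spec = replace(spec, n_patients=int(n_probe), seed=int(seed) + 104729)
    probe = generate_covariates(probe_spec)

    def mean_probs(cs: CoefficientSet, h: int) -> np.ndarray:
        pr = predict_cohort(probe, cs, horizons=[h])
        return pr[[f"p_{c}_{h}y" for c in ALL_CATEGORIES]].to_numpy().mean(axis=0)

    def match(cs: CoefficientSet, h: int, tgt: np.ndarray) -> CoefficientSet:
        # iterate the marginal log-odds correction to a fixed point
        for _ in range(100):
            m = mean_probs(cs, h)
            gap = np.abs(m[:-1] - tgt[:-1]).max()
            if gap < 1e-9:
                break
            alphas = np.log(tgt[:-1] / (1 - tgt[:-1])) - np.log(m[:-1] / (1 - m[:-1]))
            cs = cs.shifted(alphas, h)
        return cs

    tgt4 = np.array([p4[c] for c in ALL_CATEGORIES])
    coefs = match(coefs, 4, tgt4)
    # implied 2-year distribution of the matched 4-year model on the probe
    p4_mat = predict_cohort(probe, coefs, horizons=[4])[
        [f"p_{c}_4y" for c in ALL_CATEGORIES]
    ].to_numpy()
    tgt2 = (p4_mat @ _thinning_matrix()).mean(axis=0)
    coefs = match(coefs, 2, tgt2)

    return CoefficientSet(
        centers=coefs.centers,
        scales=coefs.scales,
        horizons=coefs.horizons,
        version="1",
        provenance=f"synthetic reference coefficients (seed={seed})",
        metadata={"seed": int(seed), "slope_scale": slope_scale,
                  "state_targets": {s: targets[s] for s in STATES}},
    )
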