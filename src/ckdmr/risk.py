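"""Multinomial absolute-risk engine for advanced CKD.

Implements the risk-computation chain of the validated prediction model:
CKD-EPI 2009 eGFR from serum creatinine, covariate preprocessing
(center-scaling of age/eGFR/SBP, decadic log of uACR), evaluation of the
eight linear predictors of the joint outcome-sequence model at the 2- and
4-year horizons, conversion to multinomial state probabilities with
"no event" as the reference category, and consolidation of the eight
sequences into the three clinical outcomes: kidney replacement therapy
(KRT), cardiovascular disease (CVD) and all-cause death.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "NO_EVENT",
    "ALL_CATEGORIES",
    "KRT_STATES",
    "CVD_STATES",
    "DEATH_STATES",
    "PROCESSED_NAMES",
    "CoefficientSet",
    "compute_egfr",
    "invert_egfr",
    "preprocess",
    "linear_predictors",
    "state_probabilities",
    "consolidate",
    "predict_cohort",
]

# The eight outcome sequences, in the order of their linear-predictor
# contrasts against "no event". Each label records which of KRT / CVD /
# death occurred within the horizon and in what order.
STATES: tuple[str, ...] = (
    "krt_only",
    "krt_after_cvd",
    "cvd_only",
    "cvd_after_krt",
    "death_only",
    "death_after_krt",
    "death_after_cvd",
    "death_after_krt_cvd",
)
NO_EVENT = "no_event"
ALL_CATEGORIES: tuple[str, ...] = STATES + (NO_EVENT,)

# Consolidation: a sequence contributes to an outcome iff the outcome
# occurs anywhere in the sequence.
KRT_STATES = frozenset(
    {"krt_only", "krt_after_cvd", "cvd_after_krt", "death_after_krt", "death_after_krt_cvd"}
)
CVD_STATES = frozenset(
    {"krt_after_cvd", "cvd_only", "cvd_after_krt", "death_after_cvd", "death_after_krt_cvd"}
)
DEATH_STATES = frozenset(
    {"death_only", "death_after_krt", "death_after_cvd", "death_after_krt_cvd"}
)

#: Names of the processed covariates, i.e. the design columns every
#: coefficient block must name. ``age_c``/``egfr_c``/``sbp_c`` are
#: center-scaled, ``log10_uacr`` is ln(uACR)/ln(10); binaries are 0/1.
PROCESSED_NAMES: tuple[str, ...] = (
    "age_c",
    "egfr_c",
    "sbp_c",
    "log10_uacr",
    "male",
    "black",
    "cvd_history",
    "smoking",
    "diabetes",
)

HORIZONS: tuple[int, ...] = (2, 4)


# ---------------------------------------------------------------------------
# Coefficient set
# ---------------------------------------------------------------------------


@dataclass
class CoefficientSet:
    """Intercepts, coefficients and preprocessing constants of the model.

    One block per outcome sequence per horizon. The multinomial link uses
    "no event" as the reference category: block ``k`` parameterizes
    ``ln(p_k / p_no_event)``. Coefficient files supplied by users must
    follow this convention.

    Parameters
    ----------
    centers, scales : mapping
        Centering and (strictly positive) scaling constants for
        ``age`` (years), ``egfr`` (mL/min/1.73m2) and ``sbp`` (mmHg).
    horizons : mapping
        ``{horizon_years: {state: {"intercept": float,
        "coefficients": {name: float}}}}`` with exactly the eight states
        per horizon and coefficient names drawn from
        :data:`PROCESSED_NAMES`.
    """

    centers: dict[str, float]
    scales: dict[str, float]
    horizons: dict[int, dict[str, dict]]
    version: str = "1"
    provenance: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.horizons = {int(h): blocks for h, blocks in self.horizons.items()}
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        for key in ("age", "egfr", "sbp"):
            if key not in self.centers:
                raise ValueError(f"missing centering constant for {key!r}")
            if key not in self.scales:
                raise ValueError(f"missing scale constant for {key!r}")
            if not self.scales[key] > 0:
                raise ValueError(f"scale constant for {key!r} must be > 0")
        for h, blocks in self.horizons.items():
            missing = set(STATES) - set(blocks)
            if missing:
                raise ValueError(f"horizon {h}: missing blocks {sorted(missing)}")
            for state in STATES:
                block = blocks[state]
                if "intercept" not in block:
                    raise ValueError(f"horizon {h}, state {state!r}: no intercept")
                unknown = set(block.get("coefficients", {})) - set(PROCESSED_NAMES)
                if unknown:
                    raise ValueError(
                        f"horizon {h}, state {state!r}: unknown coefficient "
                        f"names {sorted(unknown)}"
                    )

    def require_horizon(self, horizon: int) -> None:
        if int(horizon) not in self.horizons:
            raise ValueError(
                f"unknown horizon {horizon!r}; available: {sorted(self.horizons)}"
            )

    # -- array views --------------------------------------------------

    def intercepts(self, horizon: int) -> np.ndarray:
        """Intercept vector over the 8 states (in :data:`STATES` order)."""
        self.require_horizon(horizon)
        blocks = self.horizons[int(horizon)]
        return np.array([blocks[s]["intercept"] for s in STATES], dtype=float)

    def coef_matrix(self, horizon: int) -> np.ndarray:
        """(8, n_features) coefficient matrix over :data:`PROCESSED_NAMES`."""
        self.require_horizon(horizon)
        blocks = self.horizons[int(horizon)]
        mat = np.zeros((len(STATES), len(PROCESSED_NAMES)))
        for i, s in enumerate(STATES):
            coefs = blocks[s].get("coefficients", {})
            for j, name in enumerate(PROCESSED_NAMES):
                mat[i, j] = coefs.get(name, 0.0)
        return mat

    def shifted(self, alphas: Mapping[str, float] | Sequence[float], horizon: int) -> "CoefficientSet":
        """Return a copy with intercepts of ``horizon`` shifted by ``alphas``.

        Only intercepts change; all other coefficients are carried over
        bit-identically.
        """
        self.require_horizon(horizon)
        if not isinstance(alphas, Mapping):
            alphas = dict(zip(STATES, alphas))
        new_horizons = {}
        for h, blocks in self.horizons.items():
            new_blocks = {}
            for state, block in blocks.items():
                nb = {
                    "intercept": block["intercept"],
                    "coefficients": dict(block.get("coefficients", {})),
                }
                if h == int(horizon):
                    nb["intercept"] = block["intercept"] + float(alphas.get(state, 0.0))
                new_blocks[state] = nb
            new_horizons[h] = new_blocks
        return CoefficientSet(
            centers=dict(self.centers),
            scales=dict(self.scales),
            horizons=new_horizons,
            version=self.version,
            provenance=self.provenance,
            metadata=dict(self.metadata),
        )

    # -- JSON I/O ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "provenance": self.provenance,
            "metadata": self.metadata,
            "centers": self.centers,
            "scales": self.scales,
            "horizons": {str(h): blocks for h, blocks in self.horizons.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        return cls(
            centers=dict(d["centers"]),
            scales=dict(d["scales"]),
            horizons={int(h): blocks for h, blocks in d["horizons"].items()},
            version=str(d.get("version", "1")),
            provenance=str(d.get("provenance", "")),
            metadata=dict(d.get("metadata", {})),
        )

    @classmethod
    def from_json(cls, path) -> "CoefficientSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# eGFR (CKD-EPI 2009 creatinine equation)
# ---------------------------------------------------------------------------


def compute_egfr(scr, age, male, black):
    """Estimated GFR (mL/min/1.73 m2) from serum creatinine (mg/dL).

    CKD-EPI 2009:
    ``141 * min(Scr/k, 1)**a * max(Scr/k, 1)**-1.209 * 0.993**age
    * 1.018 [if female] * 1.159 [if black]``
    with k = 0.7 (female) / 0.9 (male) and a = -0.329 (female) /
    -0.411 (male). Vectorized over array inputs.
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    male = np.asarray(male, dtype=bool)
    black = np.asarray(black, dtype=bool)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be strictly positive")
    if np.any(age <= 0):
        raise ValueError("age must be strictly positive")
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.411, -0.329)
    ratio = scr / kappa
    egfr = (
        141.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * np.where(male, 1.0, 1.018)
        * np.where(black, 1.159, 1.0)
    )
    return egfr if egfr.ndim else float(egfr)


def invert_egfr(egfr, age, male, black):
    """Serum creatinine (mg/dL) consistent with a given eGFR.

    Analytic inverse of the CKD-EPI equation (the piecewise power is
    strictly decreasing in creatinine, so the inverse is unique).
    """
    egfr = np.asarray(egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    male = np.asarray(male, dtype=bool)
    black = np.asarray(black, dtype=bool)
    if np.any(egfr <= 0):
        raise ValueError("egfr must be strictly positive")
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.411, -0.329)
    demo = 141.0 * 0.993 ** age * np.where(male, 1.0, 1.018) * np.where(black, 1.159, 1.0)
    r = egfr / demo  # = min(s,1)^alpha * max(s,1)^-1.209, s = scr/kappa
    s = np.where(r >= 1.0, r ** (1.0 / alpha), r ** (-1.0 / 1.209))
    scr = kappa * s
    return scr if scr.ndim else float(scr)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

RAW_PREDICTOR_COLUMNS = (
    "age",
    "sbp",
    "uacr",
    "male",
    "black",
    "cvd_history",
    "smoking",
    "diabetes",
)


def preprocess(
    cov: pd.DataFrame | Mapping,
    coefs: CoefficientSet,
    uacr_floor: float = 1.0,
) -> pd.DataFrame:
    """Processed design matrix from raw covariates.

    age/eGFR/SBP become ``(x - center) / scale``; uACR becomes
    ``ln(uacr) / ln(10)`` after flooring at ``uacr_floor`` mg/g (the floor
    avoids ``-inf`` for uACR reported as zero); binaries pass through as
    0/1. If ``egfr`` is present it takes precedence; otherwise it is
    derived from ``scr`` via :func:`compute_egfr`.
    """
    if not isinstance(cov, pd.DataFrame):
        cov = pd.DataFrame([dict(cov)])
    missing = [c for c in RAW_PREDICTOR_COLUMNS if c not in cov.columns]
    if missing:
        raise KeyError(f"missing covariate column(s): {missing}")
    if "egfr" in cov.columns and cov["egfr"].notna().all():
        egfr = cov["egfr"].to_numpy(dtype=float)
    elif "scr" in cov.columns:
        egfr = compute_egfr(
            cov["scr"].to_numpy(dtype=float),
            cov["age"].to_numpy(dtype=float),
            cov["male"].to_numpy(),
            cov["black"].to_numpy(),
        )
    else:
        raise KeyError("need either an 'egfr' or an 'scr' column")

    uacr = np.maximum(cov["uacr"].to_numpy(dtype=float), uacr_floor)
    out = pd.DataFrame(
        {
            "age_c": (cov["age"].to_numpy(dtype=float) - coefs.centers["age"])
            / coefs.scales["age"],
            "egfr_c": (np.asarray(egfr, dtype=float) - coefs.centers["egfr"])
            / coefs.scales["egfr"],
            "sbp_c": (cov["sbp"].to_numpy(dtype=float) - coefs.centers["sbp"])
            / coefs.scales["sbp"],
            "log10_uacr": np.log(uacr) / np.log(10.0),
            "male": cov["male"].to_numpy(dtype=float),
            "black": cov["black"].to_numpy(dtype=float),
            "cvd_history": cov["cvd_history"].to_numpy(dtype=float),
            "smoking": cov["smoking"].to_numpy(dtype=float),
            "diabetes": cov["diabetes"].to_numpy(dtype=float),
        },
        index=cov.index,
    )
    if not np.isfinite(out.to_numpy()).all():
        bad = out.index[~np.isfinite(out.to_numpy()).all(axis=1)].tolist()
        raise ValueError(f"non-finite processed covariates for rows {bad[:10]}")
    return out


def linear_predictors(
    processed: pd.DataFrame, coefs: CoefficientSet, horizon: int
) -> np.ndarray:
    """The 8 linear predictors ``LP_k = intercept_k + sum_j b_kj x_j``.

    Returns an ``(n, 8)`` array in :data:`STATES` order.
    """
    coefs.require_horizon(horizon)
    x = processed[list(PROCESSED_NAMES)].to_numpy(dtype=float)
    return coefs.intercepts(horizon) + x @ coefs.coef_matrix(horizon).T


def state_probabilities(lps: np.ndarray) -> pd.DataFrame:
    """Multinomial-logit probabilities from the 8 linear predictors.

    ``p_k = exp(LP_k) / (1 + sum_j exp(LP_j))`` and
    ``p_no_event = 1 / (1 + sum_j exp(LP_j))``, computed with max
    subtraction so arbitrarily large |LP| stay finite and the nine
    probabilities sum to one.
    """
    lps = np.atleast_2d(np.asarray(lps, dtype=float))
    if lps.shape[1] != len(STATES):
        raise ValueError(f"expected {len(STATES)} linear predictors, got {lps.shape[1]}")
    if not np.isfinite(lps).all():
        raise ValueError("linear predictors must be finite")
    full = np.concatenate([lps, np.zeros((lps.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    p = e / e.sum(axis=1, keepdims=True)
    return pd.DataFrame(p, columns=list(STATES) + [NO_EVENT])


def consolidate(probs: pd.DataFrame) -> pd.DataFrame:
    """Consolidated KRT / CVD / death risks from sequence probabilities.

    Each consolidated risk is the sum of the sequence probabilities whose
    sequence contains that outcome.
    """
    missing = [s for s in STATES if s not in probs.columns]
    if missing:
        raise ValueError(f"state probabilities not populated: missing {missing}")
    out = pd.DataFrame(index=probs.index)
    out["risk_krt"] = probs[sorted(KRT_STATES)].sum(axis=1)
    out["risk_cvd"] = probs[sorted(CVD_STATES)].sum(axis=1)
    out["risk_death"] = probs[sorted(DEATH_STATES)].sum(axis=1)
    return out


def predict_cohort(
    cohort: pd.DataFrame,
    coefs: CoefficientSet,
    horizons: Iterable[int] | None = None,
    uacr_floor: float = 1.0,
) -> pd.DataFrame:
    """Per-patient state probabilities and consolidated risks per horizon.

    Output columns are ``p_<state>_<h>y`` for the nine categories and
    ``risk_<outcome>_<h>y`` for the consolidated risks; the row index of
    ``cohort`` is preserved.
    """
    if horizons is None:
        horizons = sorted(coefs.horizons)
    processed = preprocess(cohort, coefs, uacr_floor=uacr_floor)
    pieces = []
    for h in horizons:
        lps = linear_predictors(processed, coefs, h)
        probs = state_probabilities(lps)
        probs.index = cohort.index
        cons = consolidate(probs)
        probs.columns = [f"p_{c}_{h}y" for c in probs.columns]
        cons.columns = [f"{c}_{h}y" for c in cons.columns]
        pieces.extend([probs, cons])
    return pd.concat(pieces, axis=1)
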