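"""End-to-end orchestration: configuration, I/O and the validation pipeline.

``run_pipeline`` reproduces the full external-validation workflow on any
conforming cohort: predict absolute risks, assess discrimination
(competing-risk C-index) and calibration (O/E ratio, quintile bins),
recalibrate the intercepts, re-validate, run the decision-curve /
clinical-impact analysis of KRT-preparation rules, and compare the base
model against laboratory-augmented Cox models. Every figure has a
co-emitted CSV of its numbers; the report JSON is deterministic for a
fixed seed and records a provenance block (seed, config hash, version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment as aug
from . import calibration as cal
from . import decision as dec
from .risk import STATES, CoefficientSet, predict_cohort
from .survival import bootstrap_ci, competing_risk_cindex
from .synthetic import LAB_COLUMNS

__all__ = [
    "PipelineConfig",
    "REQUIRED_COLUMNS",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
    "write_report",
    "read_report",
]

logger = logging.getLogger(__name__)

#: Mandatory cohort columns: model predictors plus per-outcome
#: time/event records (codes 0 censored / 1 cause / 2 competing death)
#: and overall follow-up, all in years. One baseline row per patient.
REQUIRED_COLUMNS = (
    "age",
    "male",
    "black",
    "cvd_history",
    "smoking",
    "diabetes",
    "sbp",
    "egfr",
    "uacr",
    "time_krt",
    "event_krt",
    "time_cvd",
    "event_cvd",
    "time_death",
    "event_death",
    "follow_up_years",
)


@dataclass
class PipelineConfig:
    """Configuration of the validation pipeline (YAML-serializable)."""

    cohort_csv: str = "cohort.csv"
    coefficients_json: str = "coefficients.json"
    out_dir: str = "out"
    horizons: tuple[int, ...] = (2, 4)
    n_boot: int = 1000
    bin_boot: int = 200
    seed: int = 0
    n_bins: int = 5
    pt_min: float = 0.01
    pt_max: float = 0.50
    pt_step: float = 0.01
    recal_mode: str = "one-step"
    # the multistate AJ frequencies are unbiased under censoring, unlike
    # the crude determinate-subset frequencies
    freq_method: str = "aj"
    # rare sequences (e.g. death after KRT and CVD by 2y) can have zero
    # observed events in cohorts of ~1000; the correction keeps Eq-style
    # intercept updating defined there
    continuity_correction: bool = True
    uacr_floor: float = 1.0
    do_validate: bool = True
    do_recalibrate: bool = True
    do_dca: bool = True
    do_augment: bool = True
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.bin_boot < 1:
            raise ValueError("bootstrap replications must be >= 1")
        self.horizons = tuple(int(h) for h in self.horizons)

    def pt_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.pt_min, self.pt_max + self.pt_step / 2, self.pt_step), 10
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            d = dataclasses.asdict(self)
            d["horizons"] = list(self.horizons)
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "horizons" in d:
            d["horizons"] = tuple(d["horizons"])
        return cls(**d)

    def hash(self) -> str:
        """Digest of the analysis-relevant configuration (the output
        location is provenance-neutral)."""
        d = dataclasses.asdict(self)
        d["horizons"] = list(self.horizons)
        d.pop("out_dir")
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------


def read_cohort(path, require_events: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Unknown columns are preserved (and ignored by the models); rows with
    missing values in mandatory columns are refused (dropped, with a
    logged count) because the pipeline assumes complete predictor data;
    eGFR >= 30 draws a warning (the model targets advanced CKD) but the
    rows are retained.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort CSV {path}: {exc}") from exc
    required = REQUIRED_COLUMNS if require_events else REQUIRED_COLUMNS[:9]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV {path} is missing mandatory column(s): {missing}")
    incomplete = df[list(required)].isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dropping %d row(s) with missing mandatory values (pipeline requires "
            "complete data; impute upstream if needed)",
            int(incomplete.sum()),
        )
        df = df.loc[~incomplete].reset_index(drop=True)
    high = df["egfr"] >= 30
    if high.any():
        logger.warning(
            "%d row(s) have eGFR >= 30 mL/min/1.73m2; the model targets advanced "
            "CKD — rows retained",
            int(high.sum()),
        )
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def _validate_stage(
    cohort: pd.DataFrame,
    risks: pd.DataFrame,
    config: PipelineConfig,
    rng: np.random.Generator,
) -> dict:
    """C-index, O/E and calibration bins per outcome and horizon."""
    out: dict = {}
    bins_frames = []
    for h in config.horizons:
        out[f"{h}y"] = {}
        for outcome in cal.OUTCOMES:
            col = f"risk_{outcome}_{h}y"
            data = cohort.copy()
            data["_risk"] = risks[col].to_numpy()

            def cindex_stat(df, _o=outcome, _h=h):
                return competing_risk_cindex(
                    df["_risk"], df[f"time_{_o}"], df[f"event_{_o}"], horizon=_h
                )

            ci = bootstrap_ci(cindex_stat, data, n_reps=config.n_boot, seed=rng)

            def oe_stat(df, _o=outcome, _h=h):
                return cal.oe_ratio(
                    cal.observed_risk(df, _o, _h), float(df["_risk"].mean())
                )

            oe = bootstrap_ci(oe_stat, data, n_reps=config.n_boot, seed=rng)
            bins = cal.calibration_bins(
                risks[col].to_numpy(),
                cohort,
                outcome,
                h,
                n_bins=config.n_bins,
                n_boot=config.bin_boot,
                seed=rng,
            )
            bins.insert(0, "outcome", outcome)
            bins.insert(0, "horizon", h)
            bins_frames.append(bins)
            out[f"{h}y"][outcome] = {
                "cindex": ci.point,
                "cindex_lo": ci.lo,
                "cindex_hi": ci.hi,
                "oe_ratio": oe.point,
                "oe_lo": oe.lo,
                "oe_hi": oe.hi,
                "observed": cal.observed_risk(cohort, outcome, h),
                "expected": float(risks[col].mean()),
            }
    out["_bins"] = pd.concat(bins_frames, ignore_index=True)
    return out


def _plot_calibration(bins: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    horizons = sorted(bins["horizon"].unique())
    fig, axes = plt.subplots(
        len(horizons), 3, figsize=(11, 3.6 * len(horizons)), squeeze=False
    )
    for i, h in enumerate(horizons):
        for j, outcome in enumerate(cal.OUTCOMES):
            ax = axes[i][j]
            sub = bins[(bins["horizon"] == h) & (bins["outcome"] == outcome)]
            ax.errorbar(
                sub["mean_predicted"],
                sub["observed"],
                yerr=[
                    sub["observed"] - sub["observed_lo"],
                    sub["observed_hi"] - sub["observed"],
                ],
                fmt="^",
                capsize=3,
            )
            lim = max(0.05, sub[["mean_predicted", "observed_hi"]].to_numpy().max() * 1.1)
            ax.plot([0, lim], [0, lim], "k:", lw=1)
            ax.set_xlabel("predicted probability")
            ax.set_ylabel("observed probability")
            ax.set_title(f"{outcome.upper()} at {h} years")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_dca(dca: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for rule, sub in dca.groupby("rule"):
        style = {"treat_all": "k--", "treat_none": "k-"}.get(rule)
        if style:
            ax.plot(sub["pt"], sub["net_benefit"], style, lw=1, label=rule)
        else:
            ax.plot(sub["pt"], sub["net_benefit"], lw=1.2, label=rule)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_ylim(bottom=max(-0.05, dca["net_benefit"].min() - 0.02))
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and write all artifacts to ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    Deterministic given the seed: stage RNG streams are spawned from
    independent, stage-named children of the master seed, so toggling a
    stage off does not shift the randomness of the others.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(config.cohort_csv)
    coefs = CoefficientSet.from_json(config.coefficients_json)
    for h in config.horizons:
        coefs.require_horizon(h)

    def stage_rng(stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))

    risks = predict_cohort(
        cohort, coefs, horizons=config.horizons, uacr_floor=config.uacr_floor
    )
    risks_path = out_dir / "predicted_risks.csv"
    pd.concat([cohort[["patient_id"]] if "patient_id" in cohort else
               pd.DataFrame(index=cohort.index), risks], axis=1).to_csv(
        risks_path, index=False
    )

    report: dict = {
        "provenance": {
            "seed": int(config.seed),
            "config_hash": config.hash(),
            "package": "ckdmr",
            "n_patients": int(len(cohort)),
            "horizons": list(config.horizons),
        }
    }

    if config.do_validate:
        val = _validate_stage(cohort, risks, config, stage_rng(1))
        bins = val.pop("_bins")
        bins.to_csv(out_dir / "calibration_bins.csv", index=False)
        if config.make_plots:
            _plot_calibration(bins, out_dir / "calibration.png")
        report["validation"] = val

    recal_coefs = coefs
    if config.do_recalibrate:
        recal_report = {}
        for h in config.horizons:
            recal_coefs, res = cal.recalibrate(
                recal_coefs,
                cohort,
                h,
                mode=config.recal_mode,
                freq_method=config.freq_method,
                continuity_correction=config.continuity_correction,
                uacr_floor=config.uacr_floor,
            )
            recal_report[f"{h}y"] = {
                "alphas": {s: res.alphas[s] for s in STATES},
                "observed_frequencies": res.observed,
                "n_used": res.n_used,
                "n_iterations": res.n_iterations,
                "converged": res.converged,
                "mode": res.mode,
            }
        recal_coefs.to_json(out_dir / "coefficients_recalibrated.json")
        report["recalibration"] = recal_report

        risks_post = predict_cohort(
            cohort, recal_coefs, horizons=config.horizons, uacr_floor=config.uacr_floor
        )
        if config.do_validate:
            val_post = _validate_stage(cohort, risks_post, config, stage_rng(2))
            bins_post = val_post.pop("_bins")
            bins_post.to_csv(out_dir / "calibration_bins_recalibrated.csv", index=False)
            if config.make_plots:
                _plot_calibration(bins_post, out_dir / "calibration_recalibrated.png")
            report["validation_recalibrated"] = val_post
    else:
        risks_post = risks

    if config.do_dca:
        # decision rules use the 2-year KRT risk of the updated model
        h_dca = 2 if 2 in config.horizons else config.horizons[0]
        krt_risk = risks_post[f"risk_krt_{h_dca}y"].to_numpy()
        dca = dec.dca_curve(
            dec.DEFAULT_RULES, cohort, krt_risk, pt_grid=config.pt_grid()
        )
        dca.to_csv(out_dir / "dca.csv", index=False)
        if config.make_plots:
            _plot_dca(dca, out_dir / "dca.png")
        impact_rows = []
        for rule in dec.DEFAULT_RULES:
            counts, n_excl = dec.confusion(rule, cohort, risk=krt_risk)
            impact_rows.append(
                {
                    "rule": rule.name,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "n_excluded": n_excl,
                    "sensitivity": counts.sensitivity,
                    "specificity": counts.specificity,
                    "ppv": counts.ppv,
                    "npv": counts.npv,
                }
            )
        impact = pd.DataFrame(impact_rows)
        impact.to_csv(out_dir / "impact.csv", index=False)
        report["decision_analysis"] = {
            "horizon_used": h_dca,
            "impact": impact_rows,
        }

    if config.do_augment:
        rng = stage_rng(3)
        importance_frames = []
        grams_predictors = [
            "age",
            "male",
            "cvd_history",
            "smoking",
            "diabetes",
            "sbp",
            "egfr",
            "uacr",
        ]
        for outcome in cal.OUTCOMES:
            imp = aug.relative_importance(
                cohort, grams_predictors + list(LAB_COLUMNS), outcome
            )
            importance_frames.append(imp)
        importance = pd.concat(importance_frames, ignore_index=True)
        importance.to_csv(out_dir / "importance.csv", index=False)
        auc_table = aug.compare_models(
            cohort,
            recal_coefs,
            n_boot=min(config.n_boot, 200),
            seed=rng,
            uacr_floor=config.uacr_floor,
        )
        auc_table.to_csv(out_dir / "auc_comparison.csv", index=False)
        report["augmentation"] = {
            "auc_comparison": auc_table.to_dict(orient="records"),
            "importance_csv": "importance.csv",
        }

    write_report(report, out_dir)
    return report


def write_report(report: dict, out_dir) -> Path:
    path = Path(out_dir) / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_report(out_dir) -> dict:
    with open(Path(out_dir) / "report.json") as fh:
        return json.load(fh)
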