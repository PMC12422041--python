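"""Synthetic-cohort generator tests: determinism, marginal matching,
label consistency, model consistency of the simulated event sequences,
and the reference coefficient factory."""

import numpy as np
import pandas as pd
import pytest

import ckdmr as m
from ckdmr.risk import ALL_CATEGORIES, PROCESSED_NAMES, STATES
from ckdmr.synthetic import _thinning_matrix

from conftest import SEED


def zero_coefs():
    blocks = {
        h: {s: {"intercept": 0.0, "coefficients": {k: 0.0 for k in PROCESSED_NAMES}}
            for s in STATES}
        for h in (2, 4)
    }
    return m.CoefficientSet(
        centers={"age": 54.0, "egfr": 22.3, "sbp": 135.0},
        scales={"age": 15.0, "egfr": 6.7, "sbp": 18.0},
        horizons=blocks,
    )


class TestCovariates:
    def test_determinism(self, ref_coefs):
        spec = m.CohortSpec(n_patients=300, seed=5)
        a = m.generate_cohort(spec, ref_coefs)
        b = m.generate_cohort(m.CohortSpec(n_patients=300, seed=5), ref_coefs)
        pd.testing.assert_frame_equal(a, b)

    def test_single_row_has_all_columns(self):
        table = m.generate_covariates(m.CohortSpec(n_patients=1, seed=1))
        assert len(table) == 1
        for col in ("age", "male", "black", "sbp", "egfr", "uacr", "scr") + m.LAB_COLUMNS:
            assert col in table.columns

    def test_degenerate_bernoulli(self):
        table = m.generate_covariates(m.CohortSpec(n_patients=500, seed=2, pct_black=0.0))
        assert table["black"].sum() == 0

    def test_binary_marginals_within_3_binomial_sd(self, calib_cohort):
        n = len(calib_cohort)
        for col, p in (("male", 0.524), ("cvd_history", 0.131), ("diabetes", 0.264)):
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(calib_cohort[col].mean() - p) < 3 * sd

    def test_continuous_medians_within_5pct(self, calib_cohort):
        assert calib_cohort["age"].median() == pytest.approx(54.0, rel=0.05)
        assert calib_cohort["egfr"].median() == pytest.approx(22.3, rel=0.05)
        assert calib_cohort["uacr"].median() == pytest.approx(549.4, rel=0.05)
        assert calib_cohort["sbp"].mean() == pytest.approx(135.0, rel=0.05)

    def test_egfr_within_advanced_ckd_range(self, calib_cohort):
        assert calib_cohort["egfr"].between(0, 30, inclusive="neither").all()

    def test_egfr_uacr_negative_rank_correlation(self, calib_cohort):
        rho = calib_cohort[["egfr", "uacr"]].corr(method="spearman").iloc[0, 1]
        assert rho == pytest.approx(-0.3, abs=0.05)

    def test_scr_consistent_with_egfr(self, calib_cohort):
        back = m.compute_egfr(
            calib_cohort["scr"], calib_cohort["age"],
            calib_cohort["male"].astype(bool), calib_cohort["black"].astype(bool),
        )
        np.testing.assert_allclose(back, calib_cohort["egfr"], rtol=1e-8)

    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("n_patients", 0, "n_patients"),
            ("pct_male", 1.5, "pct_male"),
            ("egfr_median", 45.0, "egfr_median"),
            ("censoring_admin_years", -1.0, "censoring_admin_years"),
        ],
    )
    def test_invalid_spec_names_field(self, field, value, match):
        with pytest.raises(ValueError, match=match):
            m.CohortSpec(**{field: value})

    def test_yaml_roundtrip(self, tmp_path):
        spec = m.CohortSpec(n_patients=77, seed=9, pct_smoking=0.4)
        spec.to_yaml(tmp_path / "spec.yaml")
        assert m.CohortSpec.from_yaml(tmp_path / "spec.yaml") == spec


class TestSimulatedEvents:
    def test_uniform_multinomial_frequencies(self):
        """Zero linear predictors make all nine categories equiprobable."""
        spec = m.CohortSpec(
            n_patients=9000, seed=SEED, censoring_min_years=10.0,
            censoring_admin_years=50.0,
        )
        cohort = m.generate_cohort(spec, zero_coefs())
        freqs = cohort["seq_label_4y"].value_counts(normalize=True)
        sd = np.sqrt((1 / 9) * (8 / 9) / 9000)
        for cat in ALL_CATEGORIES:
            assert abs(freqs[cat] - 1 / 9) < 3 * sd

    def test_monte_carlo_convergence_to_model_probabilities(self, ref_coefs):
        spec = m.CohortSpec(
            n_patients=50_000, seed=SEED, censoring_min_years=10.0,
            censoring_admin_years=50.0,
        )
        cohort = m.generate_cohort(spec, ref_coefs)
        risks = m.predict_cohort(cohort, ref_coefs, horizons=[4])
        freqs = cohort["seq_label_4y"].value_counts(normalize=True)
        for cat in ALL_CATEGORIES:
            p = risks[f"p_{cat}_4y"].mean()
            sd = np.sqrt(p * (1 - p) / len(cohort))
            assert abs(freqs.get(cat, 0.0) - p) < 3.5 * sd

    def test_administrative_cutoff(self, ref_coefs):
        spec = m.CohortSpec(n_patients=400, seed=3, censoring_admin_years=0.5)
        cohort = m.generate_cohort(spec, ref_coefs)
        assert (cohort["follow_up_years"] <= 0.5).all()
        assert (cohort["time_krt"] <= 0.5 + 1e-12).all()

    def test_label_consistency_recomputable(self, censored_cohort):
        for h in (2.0, 4.0):
            recomputed = m.sequence_labels(censored_cohort, h)
            stored = censored_cohort[f"seq_label_{int(h)}y"]
            assert (recomputed.to_numpy() == stored.to_numpy()).all()

    def test_event_time_ordering_within_sequences(self, calib_cohort):
        c = calib_cohort
        both = (c["event_krt"] == 1) & (c["event_cvd"] == 1)
        lab = m.sequence_labels(c, 50.0)
        after = both & lab.isin(["cvd_after_krt"])
        assert (c.loc[after, "time_krt"] < c.loc[after, "time_cvd"]).all()
        died = c["event_death"] == 1
        assert (c.loc[died & (c["event_krt"] == 1), "time_krt"]
                <= c.loc[died & (c["event_krt"] == 1), "time_death"]).all()

    def test_nested_two_year_labels_match_thinning_map(self, calib_cohort, ref_coefs):
        """2-year labels derive from the 4-year latent times: their
        distribution equals the thinned 4-year distribution."""
        risks = m.predict_cohort(calib_cohort, ref_coefs, horizons=[4])
        p4 = risks[[f"p_{c}_4y" for c in ALL_CATEGORIES]].to_numpy()
        implied = (p4 @ _thinning_matrix()).mean(axis=0)
        freqs = calib_cohort["seq_label_2y"].value_counts(normalize=True)
        for i, cat in enumerate(ALL_CATEGORIES):
            sd = np.sqrt(max(implied[i] * (1 - implied[i]), 1e-9) / len(calib_cohort))
            assert abs(freqs.get(cat, 0.0) - implied[i]) < 4 * sd

    def test_covariate_coefficient_mismatch_is_schema_error(self, ref_coefs):
        cohort = m.generate_covariates(m.CohortSpec(n_patients=5, seed=1))
        with pytest.raises(KeyError):
            m.simulate_events(cohort.drop(columns=["uacr"]), ref_coefs,
                              m.CohortSpec(n_patients=5, seed=1))


class TestReferenceCoefficients:
    def test_deterministic_per_seed(self, tmp_path):
        a, b = m.make_reference_coefficients(4), m.make_reference_coefficients(4)
        a.to_json(tmp_path / "a.json")
        b.to_json(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
        assert m.make_reference_coefficients(5).to_dict() != a.to_dict()

    def test_structural_contract(self, ref_coefs):
        assert set(ref_coefs.horizons) == {2, 4}
        for h in (2, 4):
            assert set(ref_coefs.horizons[h]) == set(STATES)
        assert all(v > 0 for v in ref_coefs.scales.values())

    def test_plausible_effect_directions(self, ref_coefs):
        blocks = ref_coefs.horizons[4]
        assert blocks["krt_only"]["coefficients"]["egfr_c"] < 0
        assert blocks["krt_only"]["coefficients"]["log10_uacr"] > 0
        assert blocks["death_only"]["coefficients"]["age_c"] > 0
        assert blocks["cvd_only"]["coefficients"]["cvd_history"] > 0

    def test_moment_matching_hits_targets(self, ref_coefs):
        """Mean predicted state probabilities on a fresh default cohort
        sit near the stated targets at both horizons."""
        cohort = m.generate_covariates(m.CohortSpec(n_patients=20_000, seed=123))
        risks = m.predict_cohort(cohort, ref_coefs, horizons=[4])
        for s, target in m.DEFAULT_STATE_TARGETS.items():
            assert risks[f"p_{s}_4y"].mean() == pytest.approx(target, rel=0.1, abs=0.003)
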