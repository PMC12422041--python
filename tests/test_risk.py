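"""Risk-engine unit tests: eGFR formula, preprocessing, multinomial link,
consolidation, and the vectorized cohort chain against a straight-line
scalar re-implementation."""

import math

import numpy as np
import pandas as pd
import pytest

import ckdmr as m
from ckdmr.risk import PROCESSED_NAMES, STATES


def make_random_coefs(rng, horizons=(2, 4)):
    """A structurally valid coefficient set with random entries."""
    blocks = {
        h: {
            s: {
                "intercept": float(rng.normal()),
                "coefficients": {name: float(rng.normal()) for name in PROCESSED_NAMES},
            }
            for s in STATES
        }
        for h in horizons
    }
    return m.CoefficientSet(
        centers={"age": 54.0, "egfr": 22.3, "sbp": 135.0},
        scales={"age": 15.0, "egfr": 6.7, "sbp": 18.0},
        horizons=blocks,
    )


def random_cohort(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 74, n),
            "male": rng.integers(0, 2, n),
            "black": rng.integers(0, 2, n),
            "cvd_history": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
            "diabetes": rng.integers(0, 2, n),
            "sbp": rng.uniform(90, 200, n),
            "egfr": rng.uniform(5, 29, n),
            "uacr": rng.lognormal(6, 1.5, n),
        }
    )


class TestEgfr:
    def test_boundary_at_kappa_reduces_to_demographic_factor(self):
        # at Scr = kappa both piecewise power terms equal one
        for age in (30.0, 54.0, 70.0):
            assert m.compute_egfr(0.7, age, male=False, black=False) == pytest.approx(
                141.0 * 0.993**age * 1.018, rel=1e-12
            )
            assert m.compute_egfr(0.9, age, male=True, black=False) == pytest.approx(
                141.0 * 0.993**age, rel=1e-12
            )

    def test_reference_value_female_age50(self):
        # direct evaluation of the equation at Scr=0.7, age 50
        assert m.compute_egfr(0.7, 50, male=False, black=False) == pytest.approx(
            101.0251, abs=1e-3
        )

    def test_race_factor_is_multiplicative(self, rng):
        scr, age = 2.4, 61.0
        ratio = m.compute_egfr(scr, age, True, True) / m.compute_egfr(scr, age, True, False)
        assert ratio == pytest.approx(1.159, rel=1e-12)

    def test_continuous_at_kappa(self):
        eps = 1e-9
        lo = m.compute_egfr(0.7 - eps, 45, False, False)
        hi = m.compute_egfr(0.7 + eps, 45, False, False)
        assert lo == pytest.approx(hi, rel=1e-6)

    @pytest.mark.parametrize("scr,age", [(0.0, 50.0), (-1.0, 50.0), (1.0, 0.0)])
    def test_domain_errors(self, scr, age):
        with pytest.raises(ValueError):
            m.compute_egfr(scr, age, False, False)

    def test_inversion_roundtrip(self, rng):
        age = rng.uniform(20, 74, 200)
        male = rng.integers(0, 2, 200).astype(bool)
        black = rng.integers(0, 2, 200).astype(bool)
        egfr = rng.uniform(3, 120, 200)
        scr = m.invert_egfr(egfr, age, male, black)
        np.testing.assert_allclose(m.compute_egfr(scr, age, male, black), egfr, rtol=1e-10)


class TestPreprocess:
    def test_uacr_decadic_log(self, ref_coefs):
        row = dict(age=54.0, male=1, black=0, cvd_history=0, smoking=0, diabetes=0,
                   sbp=135.0, egfr=22.3, uacr=10.0)
        out = m.preprocess(pd.DataFrame([row]), ref_coefs)
        assert out["log10_uacr"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        row["uacr"] = 549.4
        out = m.preprocess(pd.DataFrame([row]), ref_coefs)
        assert out["log10_uacr"].iloc[0] == pytest.approx(math.log(549.4) / math.log(10), rel=1e-12)
        assert out["log10_uacr"].iloc[0] == pytest.approx(2.7399, abs=1e-4)

    def test_centering_identity(self, ref_coefs):
        row = dict(age=ref_coefs.centers["age"], male=0, black=0, cvd_history=0,
                   smoking=0, diabetes=0, sbp=135.0, egfr=22.3, uacr=100.0)
        out = m.preprocess(pd.DataFrame([row]), ref_coefs)
        assert out["age_c"].iloc[0] == 0.0

    def test_uacr_floor_prevents_log_of_zero(self, ref_coefs):
        row = dict(age=50.0, male=0, black=0, cvd_history=0, smoking=0, diabetes=0,
                   sbp=135.0, egfr=20.0, uacr=0.0)
        out = m.preprocess(pd.DataFrame([row]), ref_coefs)
        assert out["log10_uacr"].iloc[0] == 0.0  # floored at 1 mg/g

    def test_missing_covariate_is_schema_error(self, ref_coefs):
        with pytest.raises(KeyError, match="uacr"):
            m.preprocess(pd.DataFrame([{"age": 50}]), ref_coefs)

    def test_provided_egfr_wins_over_scr(self, ref_coefs):
        row = dict(age=50.0, male=0, black=0, cvd_history=0, smoking=0, diabetes=0,
                   sbp=135.0, egfr=20.0, scr=0.7, uacr=100.0)
        out = m.preprocess(pd.DataFrame([row]), ref_coefs)
        expected = (20.0 - ref_coefs.centers["egfr"]) / ref_coefs.scales["egfr"]
        assert out["egfr_c"].iloc[0] == pytest.approx(expected)


class TestLinearPredictorsAndLink:
    def test_zero_model_gives_zero_lps_and_uniform_probs(self, rng):
        coefs = make_random_coefs(rng)
        for h in (2, 4):
            for s in STATES:
                coefs.horizons[h][s]["intercept"] = 0.0
                coefs.horizons[h][s]["coefficients"] = {k: 0.0 for k in PROCESSED_NAMES}
        cohort = random_cohort(rng, 5)
        lps = m.linear_predictors(m.preprocess(cohort, coefs), coefs, 2)
        np.testing.assert_array_equal(lps, 0.0)
        probs = m.state_probabilities(lps)
        np.testing.assert_allclose(probs.to_numpy(), 1.0 / 9.0, atol=1e-14)

    def test_intercept_shift_moves_lps_exactly(self, rng):
        coefs = make_random_coefs(rng)
        cohort = random_cohort(rng, 10)
        proc = m.preprocess(cohort, coefs)
        base = m.linear_predictors(proc, coefs, 4)
        alphas = rng.normal(size=8)
        shifted = m.linear_predictors(proc, coefs.shifted(alphas, 4), 4)
        np.testing.assert_allclose(
            shifted - base, np.tile(alphas, (len(cohort), 1)), atol=1e-12
        )

    def test_dot_product_oracle(self, rng):
        coefs = make_random_coefs(rng)
        cohort = random_cohort(rng, 20)
        proc = m.preprocess(cohort, coefs)
        lps = m.linear_predictors(proc, coefs, 2)
        for i in range(len(cohort)):
            for k, s in enumerate(STATES):
                block = coefs.horizons[2][s]
                expected = block["intercept"] + sum(
                    block["coefficients"][name] * proc[name].iloc[i]
                    for name in PROCESSED_NAMES
                )
                assert lps[i, k] == pytest.approx(expected, abs=1e-12)

    def test_link_hand_value(self):
        lps = np.zeros((1, 8))
        lps[0, 0] = math.log(8.0)
        probs = m.state_probabilities(lps)
        assert probs["krt_only"].iloc[0] == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("scale", [1.0, 50.0, 700.0])
    def test_normalization_is_stable(self, rng, scale):
        lps = rng.normal(size=(50, 8)) * scale
        probs = m.state_probabilities(lps)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs.to_numpy() >= 0).all()


class TestLinkProperties:
    """Invariants of the multinomial link over arbitrary linear predictors."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    lp_arrays = st.lists(
        st.floats(min_value=-700, max_value=700, allow_nan=False), min_size=8, max_size=8
    )

    @given(lps=lp_arrays)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_probabilities_normalized_and_bounded(self, lps):
        probs = m.state_probabilities(np.array([lps]))
        arr = probs.to_numpy()
        assert abs(arr.sum() - 1.0) < 1e-12
        assert (arr >= 0).all() and (arr <= 1).all()

    @given(lps=lp_arrays)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_consolidated_risks_within_event_mass(self, lps):
        probs = m.state_probabilities(np.array([lps]))
        cons = m.consolidate(probs)
        bound = 1.0 - probs["no_event"].iloc[0]
        assert (cons.iloc[0] <= bound + 1e-12).all()
        assert (cons.iloc[0] >= 0).all()


class TestConsolidate:
    def test_uniform_enumeration(self):
        probs = m.state_probabilities(np.zeros((1, 8)))
        cons = m.consolidate(probs)
        assert cons["risk_krt"].iloc[0] == pytest.approx(5 / 9, abs=1e-14)
        assert cons["risk_cvd"].iloc[0] == pytest.approx(5 / 9, abs=1e-14)
        assert cons["risk_death"].iloc[0] == pytest.approx(4 / 9, abs=1e-14)

    def test_point_mass(self):
        probs = pd.DataFrame([{s: 0.0 for s in STATES} | {"krt_only": 1.0, "no_event": 0.0}])
        cons = m.consolidate(probs)
        assert cons.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_bounded_by_event_mass(self, rng):
        probs = m.state_probabilities(rng.normal(size=(100, 8)))
        cons = m.consolidate(probs)
        bound = 1.0 - probs["no_event"]
        for col in cons:
            assert (cons[col] <= bound + 1e-12).all()

    def test_unpopulated_probabilities_error(self):
        with pytest.raises(ValueError, match="missing"):
            m.consolidate(pd.DataFrame({"krt_only": [0.5]}))


class TestPredictCohort:
    def test_matches_scalar_chain_and_row_independence(self, rng, ref_coefs):
        cohort = random_cohort(rng, 6)
        risks = m.predict_cohort(cohort, ref_coefs)
        single = m.predict_cohort(cohort.iloc[[2]], ref_coefs)
        pd.testing.assert_frame_equal(risks.iloc[[2]], single)
        perm = rng.permutation(len(cohort))
        permuted = m.predict_cohort(cohort.iloc[perm].reset_index(drop=True), ref_coefs)
        np.testing.assert_allclose(permuted.to_numpy(), risks.iloc[perm].to_numpy())

    def test_straight_line_oracle(self, rng):
        """Full vectorized chain equals an unvectorized per-patient walk."""
        coefs = make_random_coefs(rng)
        cohort = random_cohort(rng, 100)
        risks = m.predict_cohort(cohort, coefs, horizons=[4])
        for i in range(len(cohort)):
            r = cohort.iloc[i]
            age_c = (r["age"] - coefs.centers["age"]) / coefs.scales["age"]
            egfr_c = (r["egfr"] - coefs.centers["egfr"]) / coefs.scales["egfr"]
            sbp_c = (r["sbp"] - coefs.centers["sbp"]) / coefs.scales["sbp"]
            x = {
                "age_c": age_c, "egfr_c": egfr_c, "sbp_c": sbp_c,
                "log10_uacr": math.log(max(r["uacr"], 1.0)) / math.log(10),
                "male": r["male"], "black": r["black"],
                "cvd_history": r["cvd_history"], "smoking": r["smoking"],
                "diabetes": r["diabetes"],
            }
            exps = []
            for s in STATES:
                block = coefs.horizons[4][s]
                lp = block["intercept"] + sum(
                    block["coefficients"][k] * v for k, v in x.items()
                )
                exps.append(math.exp(lp))
            denom = 1.0 + sum(exps)
            krt = sum(
                e for e, s in zip(exps, STATES) if s in m.KRT_STATES
            ) / denom
            assert risks[f"risk_krt_4y"].iloc[i] == pytest.approx(krt, abs=1e-10)
            assert risks[f"p_no_event_4y"].iloc[i] == pytest.approx(1 / denom, abs=1e-10)

    def test_monotonicity_in_krt_intercept(self, rng, ref_coefs):
        cohort = random_cohort(rng, 20)
        base = m.predict_cohort(cohort, ref_coefs, horizons=[2])
        bumped = m.predict_cohort(
            cohort, ref_coefs.shifted({"krt_only": 0.5}, 2), horizons=[2]
        )
        assert (bumped["risk_krt_2y"] > base["risk_krt_2y"]).all()
        assert (bumped["p_no_event_2y"] < base["p_no_event_2y"]).all()


class TestCoefficientSetValidation:
    def test_missing_block_rejected(self, rng):
        coefs = make_random_coefs(rng)
        d = coefs.to_dict()
        del d["horizons"]["2"]["krt_only"]
        with pytest.raises(ValueError, match="missing blocks"):
            m.CoefficientSet.from_dict(d)

    def test_nonpositive_scale_rejected(self, rng):
        coefs = make_random_coefs(rng)
        d = coefs.to_dict()
        d["scales"]["egfr"] = 0.0
        with pytest.raises(ValueError, match="scale"):
            m.CoefficientSet.from_dict(d)

    def test_unknown_coefficient_name_rejected(self, rng):
        coefs = make_random_coefs(rng)
        d = coefs.to_dict()
        d["horizons"]["4"]["cvd_only"]["coefficients"]["bmi"] = 1.0
        with pytest.raises(ValueError, match="unknown coefficient"):
            m.CoefficientSet.from_dict(d)

    def test_json_roundtrip(self, tmp_path, ref_coefs):
        path = tmp_path / "coefs.json"
        ref_coefs.to_json(path)
        loaded = m.CoefficientSet.from_json(path)
        assert loaded.to_dict() == ref_coefs.to_dict()

    def test_unknown_horizon_error(self, ref_coefs, rng):
        cohort = random_cohort(rng, 3)
        with pytest.raises(ValueError, match="horizon"):
            m.linear_predictors(m.preprocess(cohort, ref_coefs), ref_coefs, 7)
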