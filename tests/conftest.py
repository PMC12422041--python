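import numpy as np
import pytest

import ckdmr as m

SEED = 0


@pytest.fixture(scope="session")
def ref_coefs():
    """Reference coefficient set with realistic outcome mix."""
    return m.make_reference_coefficients(SEED)


@pytest.fixture(scope="session")
def balanced_coefs():
    """Coefficient set with near-equal sequence probabilities (~8.5% each),
    the regime where per-state frequencies are estimated precisely."""
    return m.make_reference_coefficients(SEED, state_targets=m.BALANCED_STATE_TARGETS)


@pytest.fixture(scope="session")
def calib_cohort(ref_coefs):
    """Perfectly calibrated cohort, n=5000, no censoring before 4 years."""
    spec = m.CohortSpec(
        n_patients=5000, seed=SEED, censoring_min_years=10.0, censoring_admin_years=50.0
    )
    return m.generate_cohort(spec, ref_coefs)


@pytest.fixture(scope="session")
def balanced_cohort(balanced_coefs):
    """n=10000 from the balanced model, no censoring before 4 years."""
    spec = m.CohortSpec(
        n_patients=10_000,
        seed=SEED,
        censoring_min_years=10.0,
        censoring_admin_years=50.0,
    )
    return m.generate_cohort(spec, balanced_coefs)


@pytest.fixture(scope="session")
def censored_cohort(ref_coefs):
    """n=2000 under the default administrative-censoring window."""
    spec = m.CohortSpec(n_patients=2000, seed=SEED)
    return m.generate_cohort(spec, ref_coefs)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
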