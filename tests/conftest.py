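import numpy as np
import pytest

import vegfmon as v


@pytest.fixture(scope="session")
def small_cohort():
    """Three-biomarker, 20-patient cohort shared by read-only tests."""
    return v.generate_cohort([v.TIE2_SPEC, v.CK18_SPEC, v.KTRANS_SPEC],
                             n_patients=20, seed=101)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Noise-free, no-missingness cohort: values equal the model exactly."""
    import dataclasses
    specs = [dataclasses.replace(v.TIE2_SPEC, noise_sd=1e-12)]
    return v.generate_cohort(specs, n_patients=8, missing_rate=0.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
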