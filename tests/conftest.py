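import numpy as np
import pandas as pd
import pytest

from mci_harmonix import (
    CohortSpec,
    adni_like_spec,
    default_generator_config,
    generate_cohort,
    oasis_like_spec,
)


@pytest.fixture(scope="session")
def adni_cohort():
    """97 HC / 24 uHC synthetic cohort with the default calibration."""
    spec = adni_like_spec(seed=0)
    return generate_cohort(spec, default_generator_config(spec), seed=0)


@pytest.fixture(scope="session")
def oasis_cohort():
    """413 HC / 106 uHC age-matched synthetic cohort."""
    spec = oasis_like_spec(seed=0)
    return generate_cohort(spec, default_generator_config(spec), seed=0)


@pytest.fixture(scope="session")
def small_balanced_cohort():
    """60/60 cohort for fast classifier checks."""
    spec = CohortSpec(n_hc=60, n_uhc=60, seed=7)
    return generate_cohort(spec, default_generator_config(spec), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
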