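import warnings

import numpy as np
import pytest

import remodelscore as rs

warnings.filterwarnings("ignore", category=RuntimeWarning, module="remodelscore")


@pytest.fixture(scope="session")
def demo_cohort():
    """Mid-sized default-structure cohort with ground truth."""
    cohort, truth = rs.simulate_cohort(rs.SimConfig(n_subjects=200, seed=7))
    return cohort, truth


@pytest.fixture(scope="session")
def demo_model(demo_cohort):
    """Pipeline fitted once on the demo cohort (reused across tests)."""
    cohort, _ = demo_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rs.fit_pipeline(cohort, seed=7)


@pytest.fixture(scope="session")
def clean_cohort(demo_cohort):
    """Preprocessed (standardized) demo cohort and its transform."""
    cohort, _ = demo_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean, model, report = rs.preprocess_cohort(cohort)
    return clean, model, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
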