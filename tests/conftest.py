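import numpy as np
import pandas as pd
import pytest

from deptraj.simulate import GeneratorConfig, generate_cohort
from deptraj.smfq import fitting_sample, score_table


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=2000, seed 7), reused read-only."""
    return generate_cohort(GeneratorConfig(n_subjects=2000, seed=7))


@pytest.fixture(scope="session")
def default_fit_sample(default_cohort):
    """Scored and eligibility-filtered long table for the default cohort."""
    return fitting_sample(score_table(default_cohort.occasions))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def make_two_class_data(
    n=300, means=(2.0, 20.0), pi=0.5, residual_sd=0.5, seed=0, n_occ=5
):
    """Flat well-separated two-class longitudinal data."""
    rng = np.random.default_rng(seed)
    cls = (rng.random(n) < pi).astype(int)
    ages = np.linspace(10, 25, n_occ)
    rows = []
    for i in range(n):
        for a in ages:
            rows.append(
                {
                    "subject_id": f"S{i:04d}",
                    "age": a,
                    "score": means[cls[i]] + rng.normal(0, residual_sd),
                    "true_class": cls[i],
                }
            )
    return pd.DataFrame(rows)
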