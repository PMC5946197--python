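import numpy as np
import pandas as pd
import pytest

from metscreen.cohort import DEFAULT_AGE_GROUPS, assign_age_group
from metscreen.indices import add_indices
from metscreen.mets import (
    ContinuousScoreSpec,
    PediatricPercentileTables,
    classify_cohort,
    continuous_mets_score,
)
from metscreen.simulate import default_stratum_specs, generate_full_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort, ~1/20th of the default stratum sizes."""
    return generate_full_cohort(default_stratum_specs(n_scale=0.05), seed=11)


@pytest.fixture(scope="session")
def analysis_df():
    """Mid-sized cohort with indices, MetS labels and the continuous score."""
    cohort = generate_full_cohort(default_stratum_specs(n_scale=0.2), seed=7)
    df = add_indices(cohort.data)
    tables = PediatricPercentileTables.from_cohort(df)
    df = classify_cohort(df, percentile_tables=tables)
    df["mets_score"] = continuous_mets_score(df, ContinuousScoreSpec())
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
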