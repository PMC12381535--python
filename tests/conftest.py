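import numpy as np
import pandas as pd
import pytest

from derga import (
    CohortTable,
    SplitProtocol,
    default_schema,
    default_signal,
    generate_cohort,
)

SCHEMA = default_schema()


@pytest.fixture(scope="session")
def schema():
    return SCHEMA


@pytest.fixture(scope="session")
def small_cohort():
    """200-record synthetic cohort with the default planted signal."""
    return generate_cohort(200, seed=42)


@pytest.fixture(scope="session")
def cohort564():
    """Study-sized cohort (564 records) with the default planted signal."""
    return generate_cohort(564, seed=7)


def threshold_cohort(n=300, seed=0, feature="crea_day2", margin=0.05):
    """Cohort whose outcome is a noise-free tertile threshold of one feature.

    The outcome is a deterministic step function of ``feature`` alone, and
    records within a relative ``margin`` of the cut points are dropped, so a
    single tree split per cut separates the classes exactly: any pattern
    containing the feature reaches test accuracy 1.0.
    """
    table = generate_cohort(2 * n, seed=seed)
    df = table.data.copy()
    x = df[feature].to_numpy()
    lo, hi = np.quantile(x, [1 / 3, 2 / 3])
    band = margin * (x.max() - x.min())
    keep = (np.abs(x - lo) > band) & (np.abs(x - hi) > band)
    df = df.loc[keep].head(n).reset_index(drop=True)
    x = df[feature].to_numpy()
    df["outcome"] = np.where(x < lo, "alive", np.where(x < hi, "dead", "alive_lt24"))
    return CohortTable(df, schema=SCHEMA, provenance="synthetic:threshold")


@pytest.fixture(scope="session")
def sep_cohort():
    return threshold_cohort()


@pytest.fixture(scope="session")
def tiny_protocol():
    return SplitProtocol(n_splits=2, n_seeds=2, master_seed=0)


@pytest.fixture(scope="session")
def one_protocol():
    return SplitProtocol(n_splits=1, n_seeds=1, master_seed=0)
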