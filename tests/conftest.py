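import numpy as np
import pandas as pd
import pytest

import diagref as dg


@pytest.fixture(scope="session")
def male_config():
    return dg.default_params("male")


@pytest.fixture(scope="session")
def dataset_2k():
    """Fixed-seed male-default cohort, n = 2000, null covariate effects."""
    cfg = dg.default_params("male", n=2000, seed=20260)
    df, truth = dg.sample_dataset(cfg)
    return df, truth


@pytest.fixture(scope="session")
def dataset_2k_cov():
    """Fixed-seed cohort with realistic covariate effects, n = 2000."""
    cfg = dg.default_params("male", n=2000, seed=20261, realistic_covariates=True)
    df, truth = dg.sample_dataset(cfg)
    return df, truth


@pytest.fixture(scope="session")
def big_sample():
    """One large male-default cohort (n = 200000) for Monte-Carlo checks."""
    cfg = dg.default_params("male", n=200_000, seed=991)
    df, truth = dg.sample_dataset(cfg)
    return df, truth


def make_cell_records(cell_outcomes: dict) -> pd.DataFrame:
    """Records from {(origin, destination): (n_owob, n_not)} counts."""
    rows = []
    for (o, d), (n1, n0) in cell_outcomes.items():
        rows.extend([(o, d, 1)] * n1)
        rows.extend([(o, d, 0)] * n0)
    df = pd.DataFrame(rows, columns=["origin", "destination", "outcome"])
    df["weight"] = 1.0
    return df
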