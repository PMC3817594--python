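import math

import numpy as np
import pandas as pd
import pytest

from snowcross import (
    CountDataset,
    LandscapeConfig,
    SimulationTruth,
    generate_predictors,
    simulate_counts,
    standardize_predictors,
)


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    return LandscapeConfig(n_highway_points=120, n_transect_points=80, seed=11)


@pytest.fixture(scope="session")
def predictor_table(small_config) -> pd.DataFrame:
    return generate_predictors(small_config)


@pytest.fixture(scope="session")
def standardized_table(small_config, predictor_table):
    table, params = standardize_predictors(
        predictor_table, columns=small_config.predictor_names
    )
    return table, params


@pytest.fixture(scope="session")
def zip_truth() -> SimulationTruth:
    return SimulationTruth(
        family="zip",
        count_coefficients={"intercept": math.log(2.0)},
        zero_coefficients={"intercept": math.log(0.4 / 0.6)},  # pi = 0.4
    )


def intercept_only_dataset(n: int, truth: SimulationTruth, seed: int) -> CountDataset:
    """Counts with no predictors (empty design beyond the intercept)."""
    empty = pd.DataFrame(index=range(n))
    return simulate_counts(empty, truth, seed=seed)


@pytest.fixture(scope="session")
def zip_dataset(zip_truth) -> CountDataset:
    return intercept_only_dataset(2000, zip_truth, seed=5)
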