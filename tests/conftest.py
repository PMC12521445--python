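import numpy as np
import pandas as pd
import pytest

from rootmeta import dataset, effect_size
from rootmeta.synthetic_data import (
    TruthRecord,
    default_truth,
    generate_meta_dataset,
    write_observations_csv,
)


@pytest.fixture(scope="session")
def small_truth() -> TruthRecord:
    return default_truth()


@pytest.fixture(scope="session")
def small_observations(small_truth) -> pd.DataFrame:
    """A compact generated dataset shared across tests (seed 42)."""
    return generate_meta_dataset(
        small_truth, n_studies_per_factor=4, obs_per_study=6, seed=42,
        n_sites=30, control_series_per_site=1,
    )


@pytest.fixture(scope="session")
def observations_csv(tmp_path_factory, small_observations):
    path = tmp_path_factory.mktemp("data") / "observations.csv"
    write_observations_csv(small_observations, path)
    return path


@pytest.fixture(scope="session")
def harmonized(observations_csv) -> pd.DataFrame:
    result = dataset.read_observations(observations_csv)
    assert not result.issues
    table, _ = dataset.harmonize(result.table)
    return table


@pytest.fixture(scope="session")
def effects(harmonized) -> pd.DataFrame:
    table, _ = effect_size.compute_effects(harmonized)
    return table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
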