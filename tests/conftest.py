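"""Shared fixtures: worked fixture, synthetic benchmark, cached CV runs."""

from pathlib import Path

import numpy as np
import pytest

from acpred import (
    GeneratorConfig,
    cross_validate,
    encode_dataset,
    feature_matrix,
    generate_dataset,
    generate_worked_fixture,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def worked_fixture():
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def golden_table():
    import pandas as pd

    return pd.read_csv(DATA_DIR / "worked_features_golden.csv")


@pytest.fixture(scope="session")
def synthetic_dataset():
    """The stated synthetic benchmark: 200/class, enrichment 3, seed 7."""
    return generate_dataset(GeneratorConfig(n_positive=200, n_negative=200, seed=7))


@pytest.fixture(scope="session")
def synthetic_Xy(synthetic_dataset):
    X, y = feature_matrix(encode_dataset(synthetic_dataset))
    return X, y


@pytest.fixture(scope="session")
def lstm_cv_report(synthetic_dataset):
    """Full 5-fold LSTM cross-validation on the synthetic benchmark.

    Computed once per session (~40 s) and shared by the sanity and
    acceptance tests.
    """
    return cross_validate(synthetic_dataset, "lstm", n_folds=5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
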