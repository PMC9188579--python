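import numpy as np
import pandas as pd
import pytest

from morbidmine import generate, run_pipeline, small_config

#: The five printed patient lists used throughout as the canonical
#: mining example (60% minimum support).
WORKED_EXAMPLE = [
    {"I10", "G47", "E78"},
    {"I10", "E78"},
    {"G47"},
    {"I10", "R06"},
    {"I10", "R06", "E78"},
]


def random_transactions(rng, n_patients, n_items=8, density=0.35):
    """Random transaction sets over a small item universe."""
    items = [f"I{k:02d}" for k in range(n_items)]
    return [
        {items[j] for j in range(n_items) if rng.random() < density}
        for _ in range(n_patients)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220611)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared by integration-style tests."""
    return generate(small_config(seed=11))


@pytest.fixture(scope="session")
def small_result(small_dataset):
    demo, dx, _ = small_dataset
    return run_pipeline(demo, dx)


def make_demographics(rows):
    return pd.DataFrame(rows, columns=["patient_id", "race", "age", "bmi"])


def make_diagnoses(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "encounter_id", "date", "code", "code_system"]
    )
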