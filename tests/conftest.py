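import numpy as np
import pandas as pd
import pytest

from igensig import FeatureMatrix, generate_cohorts, train
from igensig.simulate import SimConfig


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic study: labeled cohort, labels, reference, truth."""
    return generate_cohorts(SimConfig())


@pytest.fixture(scope="session")
def default_artifact(default_cohort):
    fm, labels, reference, _ = default_cohort
    return train(fm, labels, reference)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for pipeline mechanics (not for power-sensitive checks)."""
    cfg = SimConfig(
        n_patients=60, n_reference=200, n_blocks=10, block_size=6,
        n_predictive_blocks=4, seed=11,
    )
    return generate_cohorts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_feature_matrix(rng, n_patients=50, n_features=200, density=0.25):
    inc = (rng.random((n_patients, n_features)) < density).astype(np.uint8)
    return FeatureMatrix(
        [f"P{i:03d}" for i in range(n_patients)],
        [f"F{j:03d}" for j in range(n_features)],
        inc,
    )


def toy_labels(values, patients=None):
    patients = patients or [f"P{i}" for i in range(len(values))]
    return pd.Series(
        np.asarray(values, dtype=np.int8),
        index=pd.Index(patients, name="patient_id"),
        name="response",
    )
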