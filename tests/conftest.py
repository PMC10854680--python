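import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

import sepsislupi as sl


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic cohort with shortened (60 s) ECG segments.

    Class effects are at their defaults; the shortened segments keep the
    session fast while exercising every pipeline stage.
    """
    cfg = sl.cohort2_config(n_patients=40, ecg_duration_s=60.0, seed=20240901)
    return sl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return sl.featurize_instances(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(171717)
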