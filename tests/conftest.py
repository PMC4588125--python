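import numpy as np
import pytest

from tvconn import SyntheticConfig, checkerboard_design, simulate_cohort
from tvconn.pipeline import preprocess_subject


@pytest.fixture(scope="session")
def design():
    return checkerboard_design()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_cohort(design):
    """One 6-subject default cohort plus its preprocessed FC/BOLD series."""
    config = SyntheticConfig(n_subjects=6, seed=42)
    dataset = simulate_cohort(config)
    bold, fc = [], []
    for series, motion in zip(dataset.subjects, dataset.motion):
        b, f = preprocess_subject(series, design, motion=motion)
        bold.append(b)
        fc.append(f)
    return dataset, bold, fc
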