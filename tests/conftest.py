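import numpy as np
import pytest

from decorrnet import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small single-scanner dataset: 6 patients, 3 controls, 3 slices, 24x24."""
    spec = synthetic.CohortSpec(image_size=(24, 24), slices_per_subject=3,
                                seed=7)
    return synthetic.generate_singlescanner_imbalanced(spec, 6, 3)


@pytest.fixture(scope="session")
def tiny_multiscanner():
    """Two-scanner dataset: patients on A only, controls on both."""
    spec = synthetic.CohortSpec(image_size=(24, 24), slices_per_subject=3,
                                seed=11)
    return synthetic.generate_multiscanner(spec, n_patient_a=6, n_control_a=3,
                                           n_control_b=5)
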