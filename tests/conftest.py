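import numpy as np
import pytest

import lsaccum as L


@pytest.fixture(scope="session")
def reference_batch():
    """A moderate batch at the best-fit parameters (beta = 1.4)."""
    return L.run_batch(
        L.reference_params(),
        L.reference_noise_params(),
        600,
        master_seed=101,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort for structural tests."""
    config = L.CohortConfig(
        n_subjects=4, trials_per_subject=30, master_seed=3,
        n_calibration_trials=48,
    )
    return config, L.generate_cohort(config)
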