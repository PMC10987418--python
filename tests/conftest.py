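import numpy as np
import pytest

from hospect.pipeline import StudyConfig, dose_replicate_comparison, run_phantom_study
from hospect.recon import OsemParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_result():
    """One fixed-seed end-to-end phantom study at the desk scale.

    Shared by the figure-ordering, scatter-estimate and dosimetry checks;
    64^3 grid at 4 mm, 64 projections, the full 341 MBq loading.
    """
    return run_phantom_study(seed=1, cfg=StudyConfig(n_projections=64))


@pytest.fixture(scope="session")
def dose_replicates():
    """Paired DEW/TEW dosimetry over 10 independent simulated acquisitions."""
    return dose_replicate_comparison(seed=1, n_replicates=10)
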