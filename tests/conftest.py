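import numpy as np
import pytest

from microstates import (
    SynthConfig,
    generate_cohort,
    make_prototype_maps,
    standard_1020_16,
)


@pytest.fixture(scope="session")
def montage():
    return standard_1020_16()


@pytest.fixture(scope="session")
def prototypes(montage):
    return make_prototype_maps(montage, k=4)


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny high-SNR two-group cohort reused across integration tests."""
    cfg = SynthConfig(
        n_subjects_per_group=2, epochs_per_subject=(4, 6), snr=5.0, seed=42
    )
    return generate_cohort(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
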