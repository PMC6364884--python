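import numpy as np
import pytest

from lc_contrast.phantom import PhantomSpec, SequenceSpec, generate_cohort


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    """Idealised cohort: no noise, no rater jitter, no partial volume."""
    return PhantomSpec(
        sequence_specs=(SequenceSpec("c10", 10.0),),
        n_subjects=3,
        rater_jitter=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_spec):
    return generate_cohort(noiseless_spec)


@pytest.fixture(scope="session")
def noisy_spec() -> PhantomSpec:
    """Small noisy cohort used by statistics-level tests."""
    return PhantomSpec(
        sequence_specs=(
            SequenceSpec("c5", 5.0, noise_sigma=0.02),
            SequenceSpec("c0", 0.0, noise_sigma=0.02),
        ),
        n_subjects=6,
        rater_jitter=0.1,
        seed=23,
    )


@pytest.fixture(scope="session")
def noisy_cohort(noisy_spec):
    return generate_cohort(noisy_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
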