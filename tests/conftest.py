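import numpy as np
import pytest

from bootimpute import (
    GenerationConfig,
    MaskedCohort,
    generate_cohort,
    guided_example_spec,
    impose_missingness,
)

# One seed for the whole suite; every fixture derives from it so runs are
# exactly reproducible.
SUITE_SEED = 11


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def guided_masked() -> MaskedCohort:
    """The worked example's dataset: n = 3500 synthetic cohort with 5/15/30%
    missingness on x1/x3/x4 (joints 0.02 / 0.075)."""
    rng = np.random.default_rng(SUITE_SEED)
    cohort = generate_cohort(GenerationConfig.default(3500), rng)
    return impose_missingness(cohort, guided_example_spec(cohort), rng)


@pytest.fixture(scope="session")
def big_cohort():
    """A large complete cohort for calibration checks."""
    rng = np.random.default_rng(3)
    return generate_cohort(GenerationConfig.default(100_000), rng)


@pytest.fixture(scope="session")
def big_guided_masked(big_cohort) -> MaskedCohort:
    """The worked example's missingness mechanism applied at n = 100 000."""
    return impose_missingness(
        big_cohort, guided_example_spec(big_cohort), np.random.default_rng(4)
    )


@pytest.fixture(scope="session")
def small_masked() -> MaskedCohort:
    """A modest cohort (n = 800) with pattern-E missingness for unit tests."""
    from bootimpute import pattern_spec

    rng = np.random.default_rng(8)
    cohort = generate_cohort(GenerationConfig.default(800), rng)
    return impose_missingness(cohort, pattern_spec("E", cohort), rng)


class FixedUniform:
    """A random-stream stub yielding a fixed uniform vector (for closed-form
    checks of the inverse-transform sampler)."""

    def __init__(self, u):
        self.u = np.atleast_1d(np.asarray(u, dtype=float))

    def uniform(self, size=None):
        assert size is None or size == self.u.size
        return self.u.copy()


@pytest.fixture()
def fixed_uniform():
    return FixedUniform
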