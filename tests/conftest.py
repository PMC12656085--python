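import numpy as np
import pytest

from emgassess import SyntheticConfig, simulate_cohort
from emgassess.pipeline import cohort_feature_table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort for unit tests: fewer subjects and attempts, shorter
    recordings, same signal model as the default conditions."""
    return SyntheticConfig(
        n_subjects=10,
        attempts_per_gesture=5,
        rest_duration_s=10.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    return cohort_feature_table(small_cohort)


@pytest.fixture(scope="session")
def random_segments(rng):
    """100 random positive 750-sample 'envelope-like' signals for the
    feature-oracle suite (smoothed rectified noise at varied scales)."""
    segs = []
    for _ in range(100):
        raw = rng.normal(size=750)
        kernel = np.ones(rng.integers(3, 40))
        smooth = np.convolve(raw, kernel / kernel.size, mode="same")
        scale = 10.0 ** rng.uniform(-2, 2)
        segs.append(np.abs(smooth) * scale)
    return segs
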