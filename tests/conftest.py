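import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def ar1_series(rng, n, mu, phi, sigma2):
    """Reference AR(1) renderer, independent of the package's generator."""
    y = np.empty(n)
    y[0] = mu + np.sqrt(sigma2 / (1 - phi**2)) * rng.standard_normal()
    eps = np.sqrt(sigma2) * rng.standard_normal(n)
    for t in range(1, n):
        y[t] = mu + phi * (y[t - 1] - mu) + eps[t]
    return y


@pytest.fixture(scope="session")
def contrast_events():
    """Events from a small day/night contrast cohort, shared across tests."""
    from elf_expochar import pipeline, segmentation, synthetic

    cohort = synthetic.daynight_contrast_cohort(n_subjects=10, seed=7)
    days = pipeline._load_days(pipeline.RunConfig(cohort=cohort))
    events = pipeline.segment_days(days, pipeline.SegmentationSettings())
    return segmentation.events_to_frame(events)
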