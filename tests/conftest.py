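import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-effect synthetic cohort, 30 control / 10 benign / 30 malignant."""
    from utfmp.synth import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_control=30, n_benign=10, n_malignant=30, seed=42))


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from utfmp.features import build_feature_table
    from utfmp.pipeline import profiles_from_spectra
    from utfmp.preprocess import SmoothingConfig

    spectra, metadata = small_cohort
    profiles = profiles_from_spectra(spectra, SmoothingConfig())
    return build_feature_table(profiles, metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
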