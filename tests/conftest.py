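import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_params():
    """A very small study for fast structural tests."""
    from ecoglearn.synthgen import StudyParams

    return StudyParams(
        n_sessions=3, trials_per_session=2, trial_duration=4.0,
        n_channels=6, sampling_rate=150.0, band_centers=(10, 20, 40),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_params):
    from ecoglearn.synthgen import generate_study

    return generate_study(tiny_params)


@pytest.fixture(scope="session")
def desk_view():
    """Featurized desk-scale study shared by the slower analysis tests."""
    from ecoglearn.experiments import DatasetView
    from ecoglearn.features import FeatureConfig, featurize_study
    from ecoglearn.synthgen import desk_scale_params, generate_study

    params = desk_scale_params(seed=7)
    sessions, truth = generate_study(params)
    cfg = FeatureConfig(band_centers=params.band_centers)
    epochs = featurize_study(sessions, cfg)
    return DatasetView.from_epochs(epochs), epochs, truth, params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
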