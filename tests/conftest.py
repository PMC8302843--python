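import numpy as np
import pytest

import emgface as ef


@pytest.fixture(scope="session")
def profile():
    return ef.default_activation_matrix()


@pytest.fixture(scope="session")
def small_dataset(profile):
    """Two batches (gains 1x / 2x), 2 recordings per cell: 140 recordings."""
    cfg = ef.GeneratorConfig(recordings_per_class=2, seed=11)
    return cfg, ef.generate_dataset(cfg, profile)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    _, recs = small_dataset
    return ef.extract_features_from_recordings(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(signals, **kwargs):
    kwargs.setdefault("label", ef.ExpressionLabel("happiness", 3))
    return ef.Recording(signals=signals, **kwargs)
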