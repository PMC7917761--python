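import numpy as np
import pytest

import thermalign as ta

# Small frames and face widths keep unit-test datasets fast to render and train.
TINY_WIDTHS = {60: 56.0, 90: 40.0, 120: 30.0}


@pytest.fixture(scope="session")
def tiny_spec():
    return ta.ProtocolSpec(
        n_subjects=3,
        images_per_subject=9,
        image_size=(200, 150),
        target_widths=dict(TINY_WIDTHS),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_spec):
    return ta.generate_study(tiny_spec)


@pytest.fixture(scope="session")
def tiny_config():
    return ta.TrainConfig(T=3, K=25, F=3, P=80, n_candidates=80, seed=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_study, tiny_config):
    return ta.train_csr(tiny_study, tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
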