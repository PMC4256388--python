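import numpy as np
import pytest

import jointcodes as jc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 classes x 2 subjects x 1 rep, 60 frames, 8 joints."""
    cfg = jc.SynthConfig(
        n_classes=3, n_subjects=2, reps_per_subject=1, n_frames=60, n_joints=8, seed=7
    )
    return jc.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_config():
    return jc.PipelineConfig.small(n_words=8, top_l=8, r3=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_config):
    with pytest.warns(UserWarning, match="not over-complete"):
        model = jc.train_pipeline(tiny_dataset, tiny_config)
    return model
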