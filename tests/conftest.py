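import numpy as np
import pytest

from wavebeat import cv, synth


@pytest.fixture()
def rng():
    return np.random.default_rng(20170720)


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap 6-record dataset with all six classes present."""
    cfg = synth.SynthConfig(n_records=6, beats_per_record=60,
                            between_subject_sd=0.2, noise_sd=0.03, seed=11)
    return synth.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return cv.extract_beat_table(small_dataset)
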