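import numpy as np
import pytest

import pareidolia as p


@pytest.fixture(scope="session")
def tiny_stimuli():
    """Six-item toy design: two exemplars per category."""
    return p.make_stimulus_set(2)


@pytest.fixture(scope="session")
def stimuli8():
    return p.make_stimulus_set(8)


@pytest.fixture(scope="session")
def small_meg():
    """A small but signal-bearing MEG dataset (3 subjects, 6 exemplars/cat)."""
    cfg = p.SyntheticMEGConfig(
        n_subjects=3, n_channels=32, n_exemplars_per_category=6,
        n_runs=2, repeats_per_run=4, sample_rate_hz=100.0,
        epoch_ms=(-100.0, 390.0), seed=11,
    )
    return p.generate_meg_dataset(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
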