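"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from neurosong import synthetic
from neurosong.audio import log_compress


@pytest.fixture(scope="session")
def small_stimulus():
    """40 s song-like stimulus, 16 bins, vocals at 10-25 s."""
    return synthetic.generate_stimulus(
        duration_s=40.0, tempo_bpm=100.0, vocal_interval=(10.0, 25.0), seed=101, n_bins=16
    )


@pytest.fixture(scope="session")
def small_cohort(small_stimulus):
    """Mixed cohort (2 per archetype + 4 noise) with moderate noise, 16x20 STRFs."""
    electrodes = synthetic.generate_electrodes(
        {"onset": 2, "sustained": 2, "late_onset": 2, "rhythmic": 2},
        n_noise=4, seed=7, noise_sd=0.5, n_bins=16, n_lags=20,
    )
    hfa = synthetic.simulate_hfa(small_stimulus, electrodes, seed=11)
    return electrodes, hfa


@pytest.fixture(scope="session")
def small_spec_log(small_stimulus):
    return log_compress(small_stimulus.spectrogram)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
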