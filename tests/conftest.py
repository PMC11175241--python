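"""Shared fixtures: schedules and small synthetic recordings."""

import numpy as np
import pytest

import amciscreen as acs


@pytest.fixture(scope="session")
def full_schedule():
    """The six-frequency IPS paradigm: 10 s stimulation + 10 s rest."""
    return acs.make_ips_schedule([3, 5, 10, 12, 15, 20], 10, 10)


@pytest.fixture
def single_block_schedule():
    return acs.make_ips_schedule([10], 10, 0)


@pytest.fixture
def make_recording():
    """Factory: build a 19-channel recording from a raw signal matrix."""

    def _make(signal, schedule, fs=200.0):
        return acs.EEGRecording(np.asarray(signal, dtype=float),
                                acs.CHANNELS_1020, fs, schedule)

    return _make


@pytest.fixture
def sinusoid_recording(single_block_schedule, make_recording):
    """Noise-free 10 Hz unit sinusoid on every channel (10 s block)."""
    t = np.arange(2000) / 200.0
    sig = np.tile(np.sin(2 * np.pi * 10.0 * t), (19, 1))
    return make_recording(sig, single_block_schedule)
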