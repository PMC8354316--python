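"""Shared builders for the test suite: sinusoid recordings, hand-made
band-power series, and a small cached synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from eegsync.containers import DEFAULT_CHANNELS, BandPowerSeries, EEGRecording
from eegsync.simulate import StudyConfig, simulate_study


def make_recording(
    signal: np.ndarray,
    fs: float = 256.0,
    channels=DEFAULT_CHANNELS,
    subject: str = "s01",
    stimulus: str = "stim01",
) -> EEGRecording:
    """Broadcast a 1-D signal (or pass a 2-D matrix) into a recording."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = np.tile(signal, (len(channels), 1))
    return EEGRecording(
        subject_id=subject,
        stimulus_id=stimulus,
        fs=fs,
        channel_labels=channels,
        samples=signal,
    )


def make_band_power(
    subject: str,
    values: np.ndarray,
    channels=("C3", "Cz", "C4"),
    band: str = "alpha",
    stimulus: str = "stim01",
    frame_valid=None,
) -> BandPowerSeries:
    """Band-power series from a (n_frames, n_channels) value matrix."""
    values = np.asarray(values, dtype=float)
    n_frames, n_ch = values.shape
    power = np.zeros((n_ch, 1, n_frames))
    power[:, 0, :] = values.T
    if frame_valid is None:
        frame_valid = np.ones(n_frames, dtype=bool)
    return BandPowerSeries(
        subject_id=subject,
        stimulus_id=stimulus,
        channel_labels=tuple(channels),
        band_names=(band,),
        bands={band: (8.0, 12.0)},
        frame_times=np.arange(n_frames) * 0.25 + 0.25,
        power=power,
        frame_valid=np.asarray(frame_valid, dtype=bool),
    )


@pytest.fixture(scope="session")
def small_study():
    """A 4-subject, 3-stimulus, 6 s study reused by I/O and CLI tests."""
    cfg = StudyConfig(
        n_subjects=4, n_stimuli=3, duration_s=6.0, seed=11, artifact_rate=0.0
    )
    recordings, truth, table = simulate_study(cfg)
    return cfg, recordings, truth, table
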