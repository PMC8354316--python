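"""Sliding-window band power.

Each recording is cut into 500 ms windows advanced by 250 ms.  Every
window is a single Hann-tapered FFT periodogram (one-sided, density
scaling, μV²/Hz); a band's value is the mean of the PSD bins whose
centre frequency falls inside the band, edges inclusive.  At 256 Hz a
500 ms window gives 2 Hz bin spacing, so the five bands cover bins
{2}, {4, 6}, {8, 10, 12}, {14..24} and {26..40} Hz.

Frames that overlap any invalid sample (artifact mask) are flagged
``frame_valid = False`` and excluded from every downstream average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from .containers import DEFAULT_BANDS, BandPowerSeries, EEGRecording


class SpectralError(ValueError):
    pass


@dataclass
class SpectralConfig:
    window_s: float = 0.5
    step_s: float = 0.25
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.step_s <= 0:
            raise SpectralError("window_s and step_s must be positive")
        if self.step_s > self.window_s:
            raise SpectralError("step_s must not exceed window_s")


def frame_count(n_samples: int, fs: float, cfg: SpectralConfig | None = None) -> int:
    """T = floor((duration − window) / step) + 1 on the sample grid."""
    cfg = cfg or SpectralConfig()
    win = int(round(cfg.window_s * fs))
    step = int(round(cfg.step_s * fs))
    if n_samples < win:
        raise SpectralError("recording shorter than one analysis window")
    return (n_samples - win) // step + 1


def compute_band_power(
    rec: EEGRecording, cfg: SpectralConfig | None = None
) -> BandPowerSeries:
    """Band power per channel per frame for one recording."""
    cfg = cfg or SpectralConfig()
    if rec.fs < 128:
        raise SpectralError("band decomposition needs fs >= 128 Hz")
    win = int(round(cfg.window_s * rec.fs))
    step = int(round(cfg.step_s * rec.fs))
    n = rec.n_samples
    if n < win:
        raise SpectralError(
            f"recording of {n} samples shorter than one {win}-sample window"
        )

    frames = sliding_window_view(rec.samples, win, axis=1)[:, ::step, :]
    freqs, psd = signal.periodogram(
        frames, fs=rec.fs, window="hann", scaling="density", detrend=False, axis=-1
    )

    band_names = tuple(cfg.bands)
    n_ch, n_frames = frames.shape[0], frames.shape[1]
    power = np.empty((n_ch, len(band_names), n_frames))
    for bi, name in enumerate(band_names):
        lo, hi = cfg.bands[name]
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise SpectralError(f"band {name}: no PSD bins inside [{lo}, {hi}] Hz")
        power[:, bi, :] = psd[:, :, sel].mean(axis=-1)

    valid_windows = sliding_window_view(rec.mask, win)[::step]
    frame_valid = valid_windows.all(axis=-1)

    starts = np.arange(n_frames) * step
    frame_times = starts / rec.fs + cfg.window_s / 2.0

    return BandPowerSeries(
        subject_id=rec.subject_id,
        stimulus_id=rec.stimulus_id,
        channel_labels=rec.channel_labels,
        band_names=band_names,
        bands=dict(cfg.bands),
        frame_times=frame_times,
        power=power,
        frame_valid=frame_valid,
    )
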