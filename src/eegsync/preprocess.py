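"""EEG decontamination: mains notch, slow-drift removal, amplitude gating.

The chain is a 50 Hz IIR notch and a 0.1 Hz high-pass Butterworth, both
applied forward and backward (zero net phase shift), followed by masking
of samples whose absolute amplitude on any channel strictly exceeds
400 μV.  Artifact handling is exclusion, not interpolation: flagged
samples — extended by a ±250 ms guard band so no later band-power frame
straddles an excursion — are simply dropped from downstream averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EEGRecording

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    highpass_hz: float = 0.1
    artifact_uv: float = 400.0
    filter_order: int = 4
    notch_bandwidth_hz: float = 2.0
    guard_s: float = 0.25           # mask extension around each excursion

    def __post_init__(self) -> None:
        if not (0 < self.highpass_hz < self.notch_hz):
            raise PreprocessError("require 0 < highpass_hz < notch_hz")
        if self.artifact_uv <= 0:
            raise PreprocessError("artifact_uv must be positive")


def notch_filter(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Zero-phase IIR notch at ``cfg.notch_hz`` (−3 dB width ``notch_bandwidth_hz``)."""
    cfg = cfg or PreprocessConfig()
    if cfg.notch_hz >= rec.fs / 2:
        raise PreprocessError(
            f"notch at {cfg.notch_hz} Hz is at/above Nyquist ({rec.fs / 2} Hz)"
        )
    q = cfg.notch_hz / cfg.notch_bandwidth_hz
    b, a = signal.iirnotch(cfg.notch_hz, q, fs=rec.fs)
    out = rec.copy()
    out.samples = signal.filtfilt(b, a, out.samples, axis=1)
    return out


def highpass_filter(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Zero-phase Butterworth high-pass at ``cfg.highpass_hz``."""
    cfg = cfg or PreprocessConfig()
    if cfg.highpass_hz >= rec.fs / 2:
        raise PreprocessError("high-pass corner at/above Nyquist")
    sos = signal.butter(
        cfg.filter_order, cfg.highpass_hz, btype="highpass", fs=rec.fs, output="sos"
    )
    out = rec.copy()
    # a corner this low settles over seconds; pad generously (capped at
    # the signal length) to keep edge transients below 1% in the passband
    padlen = min(out.n_samples - 1, int(round(3.0 * rec.fs / cfg.highpass_hz)))
    out.samples = signal.sosfiltfilt(sos, out.samples, axis=1, padlen=padlen)
    return out


def reject_artifacts(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Invalidate samples where any channel strictly exceeds the gate.

    The gate is strict (``|x| > artifact_uv``): a sample at exactly the
    threshold survives.  Each excursion's mask is dilated by
    ``cfg.guard_s`` on both sides.  Idempotent: sample values are never
    modified, so re-application reproduces the same mask.
    """
    cfg = cfg or PreprocessConfig()
    out = rec.copy()
    bad = (np.abs(out.samples) > cfg.artifact_uv).any(axis=0)
    if bad.any():
        guard = int(round(cfg.guard_s * rec.fs))
        if guard > 0:
            kernel = np.ones(2 * guard + 1, dtype=int)
            bad = np.convolve(bad.astype(int), kernel, mode="same") > 0
        out.mask = out.mask & ~bad
    frac_bad = 1.0 - out.mask.mean()
    if frac_bad > 0.5:
        out.quality_flag = True
        logger.warning(
            "recording (%s, %s): %.0f%% of samples invalid after artifact gate",
            rec.subject_id,
            rec.stimulus_id,
            100 * frac_bad,
        )
    return out


def preprocess(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Full chain: notch → high-pass → artifact gate (gate on raw amplitudes).

    The amplitude gate is evaluated on the signal entering it, i.e. after
    filtering, matching a pipeline in which decontamination precedes
    quality control.
    """
    cfg = cfg or PreprocessConfig()
    return reject_artifacts(highpass_filter(notch_filter(rec, cfg), cfg), cfg)
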