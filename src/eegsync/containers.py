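"""In-memory data model for multi-subject, per-stimulus EEG studies.

The study design is a fully crossed grid: every subject hears every
stimulus, EEG is recorded on nine 10/20 scalp channels, and each
(subject, stimulus) pair yields one fixed-length segment.  Stimulus-level
metadata (artist, single-release status, streaming counts), per-subject
likeability ratings and optional externally supplied engagement scores
live in a :class:`StimulusTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Default montage: frontal, central and parietal rows of the 10/20 system.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "POz", "P4",
)

#: Canonical EEG frequency bands, Hz (inclusive edges).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 25.0),
    "gamma": (26.0, 40.0),
}

#: Genres offered in the preference ranking question.
GENRES: tuple[str, ...] = (
    "rock", "pop", "alternative", "hiphop/rap", "jazz/blues", "r&b",
)


class ValidationError(ValueError):
    """Raised when an input table or recording violates its invariants."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed into the expected data model."""


@dataclass
class EEGRecording:
    """One subject's EEG segment for one stimulus.

    Parameters
    ----------
    subject_id, stimulus_id
        Identifiers; any hashable string/int.
    fs
        Sampling rate in Hz.
    channel_labels
        Ordered, unique channel names; one row of ``samples`` each.
    samples
        ``(n_channels, n_samples)`` float array in microvolts.
    mask
        Per-sample validity flags, shape ``(n_samples,)``.  ``True`` means
        the sample is usable; artifact rejection clears flags.
    quality_flag
        Set when more than half of the samples were invalidated.
    """

    subject_id: str
    stimulus_id: str
    fs: float
    channel_labels: Sequence[str]
    samples: np.ndarray
    mask: Optional[np.ndarray] = None
    quality_flag: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a (channels, time) matrix")
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        labels = list(self.channel_labels)
        if len(labels) != len(set(labels)):
            raise ValidationError("channel labels must be unique")
        if len(labels) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(labels)} labels for {self.samples.shape[0]} channel rows"
            )
        self.channel_labels = tuple(labels)
        if self.mask is None:
            self.mask = np.ones(self.samples.shape[1], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.samples.shape[1],):
                raise ValidationError("mask length must equal sample count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None
        return self.samples[idx]

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            subject_id=self.subject_id,
            stimulus_id=self.stimulus_id,
            fs=self.fs,
            channel_labels=self.channel_labels,
            samples=self.samples.copy(),
            mask=self.mask.copy(),
            quality_flag=self.quality_flag,
        )


@dataclass
class BandPowerSeries:
    """Sliding-window band power for one recording.

    ``power`` has shape ``(n_channels, n_bands, n_frames)`` in μV²/Hz
    (mean spectral density over each band's bins).  Frames are 500 ms
    windows advanced by 250 ms; ``frame_times`` are the window centres.
    """

    subject_id: str
    stimulus_id: str
    channel_labels: tuple[str, ...]
    band_names: tuple[str, ...]
    bands: dict[str, tuple[float, float]]
    frame_times: np.ndarray
    power: np.ndarray
    frame_valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.power.shape[2]

    def band_matrix(self, band: str, channels: Sequence[str]) -> np.ndarray:
        """Return an ``(n_frames, n_channels)`` slice of one band."""
        bi = self.band_names.index(band)
        ci = [self.channel_labels.index(c) for c in channels]
        return self.power[ci, bi, :].T


@dataclass
class SynchronyResult:
    """Pooled inter-subject synchrony for one stimulus (0–100 scale)."""

    stimulus_id: str
    synchrony: float
    pair_matrix: np.ndarray          # N x N mean |r| per subject pair
    time_course: np.ndarray          # per-frame mean |r| (unscaled, 0-1)
    frame_times: np.ndarray
    n_valid_frames: int
    n_skipped_pair_frames: int       # zero-variance / invalid pair-frames
    subject_ids: tuple[str, ...] = ()


@dataclass
class FAAResult:
    """Frontal alpha asymmetry, ln(alpha PSD at F4) − ln(alpha PSD at F3)."""

    subject_id: str
    stimulus_id: str
    faa: float
    n_frames_used: int
    n_frames_dropped: int


@dataclass
class StimulusTable:
    """Joined study tables keyed by stimulus.

    ``meta`` is a stimulus-level frame (index ``stimulus_id``) with columns
    ``artist``, ``single_flag``, ``streams_early``, ``streams_late``
    (streams in millions).  ``ratings`` and ``engagement`` are wide frames
    (index ``subject_id``, columns ``stimulus_id``); ratings are forced
    1–5 integers, engagement probabilities lie in [0, 1].
    ``genre_favorite`` maps each subject to their top-ranked genre.
    """

    meta: pd.DataFrame
    ratings: pd.DataFrame
    engagement: Optional[pd.DataFrame] = None
    genre_favorite: Optional[pd.Series] = None
    genre_ranks: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.meta.index.has_duplicates:
            dups = self.meta.index[self.meta.index.duplicated()].tolist()
            raise ValidationError(f"duplicate stimulus_id: {dups}")
        for col in ("streams_early", "streams_late"):
            if col in self.meta and (self.meta[col] < 0).any():
                raise ValidationError(f"{col} must be non-negative")
        if self.ratings.isna().any().any():
            raise ValidationError("ratings must have no missing cells")
        vals = self.ratings.to_numpy()
        if not np.isin(vals, [1, 2, 3, 4, 5]).all():
            bad = sorted(set(vals.ravel()) - {1, 2, 3, 4, 5})
            raise ValidationError(f"ratings outside 1-5: {bad}")
        if set(self.ratings.columns) != set(self.meta.index):
            raise ValidationError("ratings columns must match stimulus ids")
        if self.engagement is not None:
            e = self.engagement.to_numpy(dtype=float)
            if np.isnan(e).any() or (e < 0).any() or (e > 1).any():
                raise ValidationError("engagement scores must lie in [0, 1]")

    @property
    def subject_ids(self) -> list:
        return list(self.ratings.index)

    @property
    def stimulus_ids(self) -> list:
        return list(self.meta.index)

    def long(self) -> pd.DataFrame:
        """Observation-level frame: one row per (subject, stimulus)."""
        out = (
            self.ratings.stack()
            .rename("rating")
            .rename_axis(["subject_id", "stimulus_id"])
            .reset_index()
        )
        if self.engagement is not None:
            eng = (
                self.engagement.stack()
                .rename("engagement")
                .rename_axis(["subject_id", "stimulus_id"])
                .reset_index()
            )
            out = out.merge(eng, on=["subject_id", "stimulus_id"], how="left")
        out = out.merge(
            self.meta.reset_index().rename(columns={"index": "stimulus_id"}),
            on="stimulus_id",
            how="left",
        )
        return out
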