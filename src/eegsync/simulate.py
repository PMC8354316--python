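"""Synthetic multi-subject EEG study with known ground truth.

Emulates a music neuroforecasting experiment: N subjects listen to the
same short song fragments while 9-channel EEG is recorded.  Each channel
mixes a stimulus-locked 10 Hz alpha component (identical envelope across
subjects, per-stimulus coupling weight ``w``), an idiosyncratic alpha
oscillation at a subject-specific frequency, 1/f pink noise and broadband
white noise.  Frontal channels F3/F4 carry a valence-driven asymmetry so
that expected frontal alpha asymmetry (FAA) increases with stimulus
valence.  Occasional high-amplitude square pulses emulate movement
artifacts exceeding the 400 μV rejection gate.

Outcomes are drawn from a log-linear model of streaming counts in true
synchrony and single-release status; likeability ratings follow a
cumulative-logit ordinal model centred on valence; engagement scores are
logistic transforms of a latent with a configurable (negative by default)
loading on ratings.

Every quantity is reproducible bit-exactly from ``(StudyConfig, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .containers import DEFAULT_CHANNELS, EEGRecording, StimulusTable

#: Mean |Pearson r| of two independent 15-sample Gaussian vectors,
#: 2 / ((m-2) * B(1/2, (m-2)/2)) at m = 15.  Used only to anchor the
#: generative "true synchrony" predictor on the 0-100 pipeline scale.
NULL_ABS_R15 = 0.2170824665016328

_GAMMA_UPPER_HZ = 40.0

# Sub-stream tags for seed derivation (arbitrary fixed integers).
_TAG_SUBJECT = 100
_TAG_RECORDING = 101
_TAG_STIMULUS = 102
_TAG_OUTCOMES = 200


class ConfigurationError(ValueError):
    """Invalid study configuration; the message names the offending field."""


def _per_stimulus(value, n: int, name: str, dtype=float) -> np.ndarray:
    arr = np.asarray(value, dtype=dtype)
    if arr.ndim == 0:
        arr = np.full(n, arr[()], dtype=dtype)
    if arr.shape != (n,):
        raise ConfigurationError(f"{name}: expected {n} per-stimulus values")
    return arr


def _default_valence(n: int) -> np.ndarray:
    """Ramp over [-1, 1] reordered (evens ascending, odds descending) so it
    is nearly uncorrelated with the default coupling ramp."""
    ramp = np.linspace(-1.0, 1.0, n)
    order = np.concatenate([np.arange(0, n, 2), np.arange(1, n, 2)[::-1]])
    out = np.empty(n)
    out[order] = ramp
    return out


def _default_singles(artist: np.ndarray) -> np.ndarray:
    """Promotional singles: every third song per artist, at most four.

    Mirrors four singles out of 11-13 album tracks at full scale while
    keeping the flag non-constant for small stimulus counts.
    """
    flags = np.zeros(len(artist), dtype=bool)
    for label in pd.unique(artist):
        idx = np.flatnonzero(artist == label)
        flags[idx[::3][:4]] = True
    return flags


@dataclass
class StudyConfig:
    """Parameters of the simulated study.

    Defaults mirror the emulated experiment: 30 subjects, 24 stimuli of
    24 s at 256 Hz on the nine-channel 10/20 montage, with two artists
    splitting the stimuli 13/11.  Amplitudes are in μV; the pink-noise
    level is set so the alpha-band SNR is ≈ 1 at coupling w = 0.5.
    """

    n_subjects: int = 30
    n_stimuli: int = 24
    duration_s: float = 24.0
    fs: float = 256.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    shared_weight: object = None        # per-stimulus w in [0, 1]
    valence: object = None              # per-stimulus scalar
    single_flag: object = None          # per-stimulus bool
    artist_label: object = None         # per-stimulus category (2 levels)
    beta0: float = 0.5
    beta_synch: float = 0.02            # per synchrony point (0-100 scale)
    beta_single: float = 0.75
    noise_sd: float = 0.3
    growth_factor: float = 3.0          # late streams / early streams
    artifact_rate: float = 0.5          # expected >400 μV excursions / minute
    alpha_amp: float = 4.0              # μV, alpha component base amplitude
    pink_amp: float = 10.3              # μV RMS of 1/f noise (alpha SNR ≈ 1 at w = 0.5)
    white_amp: float = 1.0              # μV SD of broadband noise
    faa_offset_sd: float = 0.2          # SD of per-subject asymmetry offset
    phase_spread: float = 1.0           # subject phases ~ U(0, 2π·spread)
    engagement_loading: float = -1.0    # latent-engagement loading on ratings
    engagement_base: float = -2.0       # latent intercept (mean score ≈ 0.12)
    rating_cutpoints: tuple[float, ...] = (-1.5, -0.5, 0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects: must be at least 2")
        if self.n_stimuli < 1:
            raise ConfigurationError("n_stimuli: must be at least 1")
        if self.fs <= 2 * _GAMMA_UPPER_HZ:
            raise ConfigurationError(
                f"fs: must exceed twice the gamma upper edge ({2 * _GAMMA_UPPER_HZ} Hz)"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s: must be positive")
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact_rate: must be non-negative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be non-negative")
        self.channels = tuple(self.channels)
        n = self.n_stimuli
        if self.shared_weight is None:
            self.shared_weight = np.linspace(0.15, 0.75, n)
        self.shared_weight = _per_stimulus(self.shared_weight, n, "shared_weight")
        if (self.shared_weight < 0).any() or (self.shared_weight > 1).any():
            raise ConfigurationError("shared_weight: values must lie in [0, 1]")
        if self.valence is None:
            self.valence = _default_valence(n)
        self.valence = _per_stimulus(self.valence, n, "valence")
        if self.artist_label is None:
            n_a = int(round(n * 13 / 24)) if n > 1 else 1
            self.artist_label = np.array(
                ["r&b"] * n_a + ["pop"] * (n - n_a), dtype=object
            )
        self.artist_label = np.asarray(self.artist_label, dtype=object)
        if self.artist_label.shape != (n,):
            raise ConfigurationError("artist_label: expected one label per stimulus")
        if self.single_flag is None:
            self.single_flag = _default_singles(self.artist_label)
        self.single_flag = _per_stimulus(self.single_flag, n, "single_flag", dtype=bool)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def subject_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(self.n_subjects)]

    @property
    def stimulus_ids(self) -> list[str]:
        return [f"stim{k + 1:02d}" for k in range(self.n_stimuli)]


@dataclass
class GroundTruth:
    """Latent state of one simulated study (reproducible from config+seed)."""

    shared_weight: np.ndarray
    valence: np.ndarray
    single_flag: np.ndarray
    artist_label: np.ndarray
    true_synchrony: np.ndarray          # generative predictor, 0-100 scale
    expected_log_streams: np.ndarray    # beta0 + b_s * synch + b_1 * single
    faa_offset: np.ndarray              # per-subject asymmetry offset
    subject_phase: np.ndarray
    subject_freq: np.ndarray            # idiosyncratic alpha frequency, Hz
    artifact_indices: dict = field(default_factory=dict)


def true_synchrony_scale(w: np.ndarray) -> np.ndarray:
    """Map coupling weight to the generative synchrony predictor.

    Interpolates between the independent-noise floor (100·E|r| for
    15-sample windows) at w = 0 and perfect synchrony at w = 1.  This is
    the predictor the outcome model is driven by, not a claim about the
    value the measurement pipeline recovers.
    """
    return 100.0 * (NULL_ABS_R15 + (1.0 - NULL_ABS_R15) * np.asarray(w))


def _smooth_envelope(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Rectified < 2 Hz Gaussian noise, normalised to unit mean."""
    sos = signal.butter(4, 2.0, btype="low", fs=fs, output="sos")
    env = np.abs(signal.sosfiltfilt(sos, rng.standard_normal(n)))
    m = env.mean()
    return env / m if m > 0 else env


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-amplitude noise with unit RMS (flat below 1 Hz)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0))
    spectrum = shaping * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _inject_artifacts(
    rng: np.random.Generator, x: np.ndarray, fs: float, rate_per_min: float
) -> np.ndarray:
    """Add square pulses of 450-800 μV, 100-300 ms; return their indices."""
    n_ch, n = x.shape
    lam = rate_per_min * (n / fs) / 60.0
    n_art = rng.poisson(lam) if lam > 0 else 0
    hit: list[np.ndarray] = []
    for _ in range(n_art):
        dur = int(rng.uniform(0.100, 0.300) * fs)
        start = int(rng.integers(0, max(1, n - dur)))
        amp = rng.uniform(450.0, 800.0) * (1 if rng.random() < 0.5 else -1)
        ch = int(rng.integers(0, n_ch))
        x[ch, start : start + dur] += amp
        hit.append(np.arange(start, min(start + dur, n)))
    if hit:
        return np.unique(np.concatenate(hit))
    return np.empty(0, dtype=int)


def make_ground_truth(config: StudyConfig) -> GroundTruth:
    """Draw the latent study state (no EEG synthesis).

    Cheap enough for outcome-model Monte-Carlo loops; ``simulate_eeg``
    starts from the same state, so the two stay consistent for a given
    (config, seed).  ``artifact_indices`` is filled only by
    :func:`simulate_eeg`.
    """
    cfg = config
    seed = int(cfg.seed)
    subj_rng = np.random.default_rng([_TAG_SUBJECT, seed])
    phases = subj_rng.uniform(0.0, 2.0 * np.pi * cfg.phase_spread, cfg.n_subjects)
    freqs = subj_rng.uniform(8.0, 12.0, cfg.n_subjects)
    offsets = cfg.faa_offset_sd * subj_rng.standard_normal(cfg.n_subjects)
    ts = true_synchrony_scale(cfg.shared_weight)
    return GroundTruth(
        shared_weight=cfg.shared_weight.copy(),
        valence=cfg.valence.copy(),
        single_flag=cfg.single_flag.copy(),
        artist_label=cfg.artist_label.copy(),
        true_synchrony=ts,
        expected_log_streams=cfg.beta0
        + cfg.beta_synch * ts
        + cfg.beta_single * cfg.single_flag.astype(float),
        faa_offset=offsets,
        subject_phase=phases,
        subject_freq=freqs,
    )


def simulate_eeg(config: StudyConfig) -> tuple[list[EEGRecording], GroundTruth]:
    """Generate one EEG recording per (subject, stimulus) plus ground truth.

    Channel model (μV), for subject s, stimulus k with coupling w and
    valence v::

        g_c * alpha_amp * [ w · A_k(t) sin(2π·10·t + φ_s)
                            + (1−w) · A_sk(t) sin(2π f_s t + ψ_sk) ]
        + pink_amp · pink(t) + white_amp · ε(t)

    where A_k is a smooth stimulus-specific envelope shared by all
    subjects, A_sk an idiosyncratic envelope, f_s ∈ [8, 12] Hz, and the
    alpha gain g_c is exp(±(v + o_s)/2) on F4/F3 (1 elsewhere) so that
    expected FAA = ln PSD(F4) − ln PSD(F3) grows with valence.
    """
    cfg = config
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    seed = int(cfg.seed)

    truth = make_ground_truth(cfg)
    phases, freqs, offsets = truth.subject_phase, truth.subject_freq, truth.faa_offset

    shared_env = [
        _smooth_envelope(np.random.default_rng([_TAG_STIMULUS, seed, k]), n, cfg.fs)
        for k in range(cfg.n_stimuli)
    ]

    try:
        i_f3 = cfg.channels.index("F3")
        i_f4 = cfg.channels.index("F4")
    except ValueError:
        i_f3 = i_f4 = -1

    recordings: list[EEGRecording] = []
    for s, sid in enumerate(cfg.subject_ids):
        for k, kid in enumerate(cfg.stimulus_ids):
            rng = np.random.default_rng([_TAG_RECORDING, seed, s, k])
            w = cfg.shared_weight[k]
            shared = shared_env[k] * np.sin(2 * np.pi * 10.0 * t + phases[s])
            idio_env = _smooth_envelope(rng, n, cfg.fs)
            psi = rng.uniform(0.0, 2.0 * np.pi)
            idio = idio_env * np.sin(2 * np.pi * freqs[s] * t + psi)
            # power-preserving mix: amplitude weights sqrt(w), sqrt(1-w)
            # keep total alpha power flat in w, so synchrony responds to the
            # shared fraction rather than to a coupling-dependent SNR.
            alpha = cfg.alpha_amp * (
                np.sqrt(w) * shared + np.sqrt(1.0 - w) * idio
            )

            gain = np.ones(len(cfg.channels))
            if i_f4 >= 0:
                asym = cfg.valence[k] + offsets[s]
                gain[i_f4] = np.exp(+asym / 2.0)
                gain[i_f3] = np.exp(-asym / 2.0)

            x = gain[:, None] * alpha[None, :]
            for c in range(len(cfg.channels)):
                x[c] += cfg.pink_amp * _pink_noise(rng, n, cfg.fs)
                x[c] += cfg.white_amp * rng.standard_normal(n)

            art_idx = _inject_artifacts(rng, x, cfg.fs, cfg.artifact_rate)
            truth.artifact_indices[(sid, kid)] = art_idx
            recordings.append(
                EEGRecording(
                    subject_id=sid,
                    stimulus_id=kid,
                    fs=cfg.fs,
                    channel_labels=cfg.channels,
                    samples=x,
                )
            )
    return recordings, truth


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_outcomes(truth: GroundTruth, config: StudyConfig) -> StimulusTable:
    """Draw outcome tables from the generative model.

    log(streams_early) = β₀ + β_synch·synchrony + β_single·single + ε,
    ε ~ N(0, noise_sd²); streams are reported in millions.  Late streams
    are early streams times a fixed growth factor with independent
    log-normal noise.  Ratings follow a cumulative-logit model with fixed
    cutpoints centred on stimulus valence; engagement is a logistic
    transform of a latent with a (default negative) loading on ratings.
    """
    cfg = config
    rng = np.random.default_rng([_TAG_OUTCOMES, int(cfg.seed)])
    n_k, n_s = cfg.n_stimuli, cfg.n_subjects

    log_early = truth.expected_log_streams + cfg.noise_sd * rng.standard_normal(n_k)
    streams_early = np.exp(log_early)
    streams_late = (
        streams_early
        * cfg.growth_factor
        * np.exp(cfg.noise_sd * rng.standard_normal(n_k))
    )

    latent = truth.valence[None, :] + rng.logistic(0.0, 1.0, size=(n_s, n_k))
    cut = np.asarray(cfg.rating_cutpoints)
    ratings = 1 + (latent[:, :, None] > cut[None, None, :]).sum(axis=2)

    eng_latent = (
        cfg.engagement_base
        + cfg.engagement_loading * (ratings - 3.0) / 2.0
        + 0.5 * rng.standard_normal((n_s, n_k))
    )
    engagement = _sigmoid(eng_latent)

    # Genre favourites roughly matching the emulated sample: ~53% pop fans.
    probs = {"pop": 16 / 30, "r&b": 5 / 30}
    others = [g for g in ("rock", "alternative", "hiphop/rap", "jazz/blues")]
    for g in others:
        probs[g] = (1 - sum([16 / 30, 5 / 30])) / len(others)
    genres = list(probs)
    fav = rng.choice(genres, size=n_s, p=[probs[g] for g in genres])
    ranks = []
    for f in fav:
        rest = [g for g in genres if g != f]
        rng.shuffle(rest)
        ranks.append([f] + rest)

    sids, kids = cfg.subject_ids, cfg.stimulus_ids
    meta = pd.DataFrame(
        {
            "artist": truth.artist_label,
            "single_flag": truth.single_flag,
            "streams_early": streams_early,
            "streams_late": streams_late,
        },
        index=pd.Index(kids, name="stimulus_id"),
    )
    ratings_df = pd.DataFrame(ratings, index=pd.Index(sids, name="subject_id"), columns=kids)
    engagement_df = pd.DataFrame(
        engagement, index=pd.Index(sids, name="subject_id"), columns=kids
    )
    rank_df = pd.DataFrame(
        ranks,
        index=pd.Index(sids, name="subject_id"),
        columns=[f"rank_{i + 1}" for i in range(len(genres))],
    )
    return StimulusTable(
        meta=meta,
        ratings=ratings_df,
        engagement=engagement_df,
        genre_favorite=pd.Series(fav, index=ratings_df.index, name="favorite"),
        genre_ranks=rank_df,
    )


def simulate_study(config: StudyConfig):
    """Convenience wrapper: EEG, ground truth and outcome tables in one call."""
    recordings, truth = simulate_eeg(config)
    table = simulate_outcomes(truth, config)
    return recordings, truth, table
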