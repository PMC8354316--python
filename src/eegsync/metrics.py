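"""Stimulus-level neural metrics: inter-subject synchrony and FAA.

Neural synchrony
----------------
For one stimulus, take every subject's alpha-band power over the central
electrodes (C3, Cz, C4) on the 250 ms frame grid.  At each frame t, a
subject's local response is the 5-frame × 3-electrode patch t−2..t+2
(±750 ms of underlying signal once the 500 ms analysis windows are
accounted for), flattened to a 15-vector.  For every ordered subject
pair (i, j), i ≠ j, the Pearson correlation of the two patches is taken,
its absolute value averaged over pairs and then over frames, and the
result scaled by 100:

    synchrony = 100 · (1/T) Σ_t [ 1/(N(N−1)) Σ_{i≠j} |cor(X_i, X_j)| ]

Edge frames lacking a full ±2 neighbourhood are skipped (no padding),
as are frames overlapping masked samples and patches with zero variance.

Frontal alpha asymmetry
-----------------------
FAA = ln PSD(alpha, F4) − ln PSD(alpha, F3) per frame, averaged over
valid frames per (subject, stimulus); the group value per stimulus is
the mean over subjects.  Positive FAA indexes relative left-frontal
activation (approach motivation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .containers import (
    BandPowerSeries,
    FAAResult,
    StimulusTable,
    SynchronyResult,
    ValidationError,
)


class MetricError(ValueError):
    pass


@dataclass
class SynchronyConfig:
    electrodes: tuple[str, ...] = ("C3", "Cz", "C4")
    band: str = "alpha"
    half_width_frames: int = 2
    scale: float = 100.0
    #: optional moving-average width (frames) applied to the reported
    #: time course only; never part of the scalar.
    smooth_frames: int = 0

    def __post_init__(self) -> None:
        if self.half_width_frames < 1:
            raise MetricError("half_width_frames must be >= 1")
        self.electrodes = tuple(self.electrodes)


def _patches(bp: BandPowerSeries, cfg: SynchronyConfig):
    """Flattened centred windows and their validity for one subject.

    Returns ``(W, valid)`` with ``W`` of shape ``(T − 2h, (2h+1)·E)``;
    row t corresponds to centre frame t + h of the original grid.
    """
    m = bp.band_matrix(cfg.band, cfg.electrodes)  # (T, E)
    h = cfg.half_width_frames
    width = 2 * h + 1
    if m.shape[0] < width:
        raise MetricError(
            f"series has {m.shape[0]} frames; need at least {width} for a window"
        )
    w = sliding_window_view(m, width, axis=0)      # (T-2h, E, width)
    w = w.transpose(0, 2, 1).reshape(w.shape[0], width * m.shape[1])
    valid = sliding_window_view(bp.frame_valid, width).all(axis=-1)
    return np.ascontiguousarray(w, dtype=np.float64), valid


def window_correlation(
    bp_i: BandPowerSeries,
    bp_j: BandPowerSeries,
    t: int,
    cfg: SynchronyConfig | None = None,
) -> float:
    """Signed Pearson r between two subjects' flattened patches at frame t.

    ``t`` indexes the original frame grid; the patch spans t−h..t+h.
    Returns NaN when either patch has zero variance (the pair-frame is
    skipped and counted by :func:`neural_synchrony`).
    """
    cfg = cfg or SynchronyConfig()
    h = cfg.half_width_frames
    if bp_i.n_frames != bp_j.n_frames:
        raise MetricError("band-power series do not share a frame grid")
    if t - h < 0 or t + h >= bp_i.n_frames:
        raise MetricError(f"frames {t - h}..{t + h} outside the grid")
    wi, vi = _patches(bp_i, cfg)
    wj, vj = _patches(bp_j, cfg)
    x, y = wi[t - h], wj[t - h]
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = float(xc @ xc)
    ssy = float(yc @ yc)
    if ssx <= 0.0 or ssy <= 0.0:
        return float("nan")
    return float(xc @ yc) / math.sqrt(ssx * ssy)


def neural_synchrony(
    series: Sequence[BandPowerSeries], cfg: SynchronyConfig | None = None
) -> SynchronyResult:
    """Pooled synchrony over all subjects for one stimulus.

    Frames with fewer than two valid ordered pairs are excluded from the
    scalar.  The ordered-pair denominator N(N−1) equals the unordered
    mean for this symmetric kernel.
    """
    cfg = cfg or SynchronyConfig()
    n = len(series)
    if n < 2:
        raise MetricError("neural synchrony needs at least 2 subjects")
    stim = {bp.stimulus_id for bp in series}
    if len(stim) > 1:
        raise MetricError(f"series mix stimuli: {sorted(stim)}")
    t_all = {bp.n_frames for bp in series}
    if len(t_all) > 1:
        raise MetricError("series do not share a frame grid")

    h = cfg.half_width_frames
    pw = []
    pv = []
    for bp in series:
        w, v = _patches(bp, cfg)
        pw.append(w)
        pv.append(v)
    w = np.stack(pw)                       # (N, Tc, K)
    valid = np.stack(pv)                   # (N, Tc)
    n_sub, t_c, _ = w.shape

    wc = w - w.mean(axis=-1, keepdims=True)
    ss = (wc**2).sum(axis=-1)
    zero_var = ss <= 0.0
    usable = valid & ~zero_var

    num = np.einsum("itk,jtk->ijt", wc, wc)
    den = np.sqrt(ss[:, None, :] * ss[None, :, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        absr = np.abs(num / den)

    pair_ok = usable[:, None, :] & usable[None, :, :]
    eye = np.eye(n_sub, dtype=bool)
    pair_ok &= ~eye[:, :, None]
    vals = np.where(pair_ok, absr, 0.0)

    # Accumulate pair sums row by row: a fixed left-to-right order keeps
    # the scalar reproducible against a direct loop evaluation.
    acc = np.zeros(t_c)
    for row in vals.reshape(n_sub * n_sub, t_c):
        acc = acc + row
    counts = pair_ok.sum(axis=(0, 1))

    included = counts >= 2
    if not included.any():
        n_bad = int((~valid).sum())
        raise MetricError(
            "no frame has two valid pairs "
            f"({n_bad} of {valid.size} subject-frames invalid, "
            f"{int(zero_var.sum())} zero-variance patches)"
        )
    frame_means = np.full(t_c, np.nan)
    frame_means[included] = acc[included] / counts[included]

    total = 0.0
    for fm in frame_means[included]:
        total += fm
    synchrony = cfg.scale * total / int(included.sum())

    with np.errstate(invalid="ignore"):
        pair_counts = pair_ok.sum(axis=2)
        pair_matrix = np.where(
            pair_counts > 0, vals.sum(axis=2) / np.maximum(pair_counts, 1), np.nan
        )
    np.fill_diagonal(pair_matrix, np.nan)

    time_course = frame_means.copy()
    if cfg.smooth_frames > 1:
        k = np.ones(cfg.smooth_frames) / cfg.smooth_frames
        tc_s = np.convolve(np.nan_to_num(time_course), k, mode="same")
        norm = np.convolve((~np.isnan(time_course)).astype(float), k, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            time_course = np.where(norm > 0, tc_s / norm, np.nan)

    frame_times = series[0].frame_times[h : h + t_c]
    n_off = n_sub * (n_sub - 1)
    skipped = int(n_off * t_c - pair_ok.sum())
    return SynchronyResult(
        stimulus_id=series[0].stimulus_id,
        synchrony=float(synchrony),
        pair_matrix=pair_matrix,
        time_course=time_course,
        frame_times=frame_times,
        n_valid_frames=int(included.sum()),
        n_skipped_pair_frames=skipped,
        subject_ids=tuple(bp.subject_id for bp in series),
    )


def compute_faa(
    bp: BandPowerSeries, band: str = "alpha", left: str = "F3", right: str = "F4"
) -> FAAResult:
    """Mean over valid frames of ln(power at F4) − ln(power at F3)."""
    for ch in (left, right):
        if ch not in bp.channel_labels:
            raise MetricError(f"channel {ch} absent from series")
    m = bp.band_matrix(band, (left, right))  # (T, 2): [:,0]=F3, [:,1]=F4
    ok = bp.frame_valid & (m > 0).all(axis=1)
    dropped = int((bp.frame_valid & ~(m > 0).all(axis=1)).sum())
    if not ok.any():
        raise MetricError(
            f"({bp.subject_id}, {bp.stimulus_id}): no valid frame with positive "
            f"{left}/{right} {band} power"
        )
    faa = float(np.mean(np.log(m[ok, 1]) - np.log(m[ok, 0])))
    return FAAResult(
        subject_id=bp.subject_id,
        stimulus_id=bp.stimulus_id,
        faa=faa,
        n_frames_used=int(ok.sum()),
        n_frames_dropped=dropped,
    )


def faa_frame(results: Iterable[FAAResult]) -> pd.DataFrame:
    """Wide (subject × stimulus) frame of FAA values."""
    rows = [
        {"subject_id": r.subject_id, "stimulus_id": r.stimulus_id, "faa": r.faa}
        for r in results
    ]
    return pd.DataFrame(rows).pivot(
        index="subject_id", columns="stimulus_id", values="faa"
    )


def aggregate_faa(results: Iterable[FAAResult]) -> pd.Series:
    """Group-level FAA: mean over subjects per stimulus."""
    wide = faa_frame(results)
    return wide.mean(axis=0).rename("faa")


def attach_engagement(table: StimulusTable, scores) -> StimulusTable:
    """Join externally supplied engagement probabilities onto the table.

    ``scores`` may be a wide (subject × stimulus) DataFrame, a long frame
    with columns (subject_id, stimulus_id, engagement), or a mapping
    keyed by (subject_id, stimulus_id).  Every cell must be present and
    lie in [0, 1].
    """
    if isinstance(scores, Mapping):
        long = pd.DataFrame(
            [(s, k, v) for (s, k), v in scores.items()],
            columns=["subject_id", "stimulus_id", "engagement"],
        )
        wide = long.pivot(index="subject_id", columns="stimulus_id", values="engagement")
    elif isinstance(scores, pd.DataFrame) and "engagement" in scores.columns:
        wide = scores.pivot(index="subject_id", columns="stimulus_id", values="engagement")
    else:
        wide = pd.DataFrame(scores)

    want_rows = list(table.ratings.index)
    want_cols = list(table.ratings.columns)
    missing = [
        (s, k)
        for s in want_rows
        for k in want_cols
        if s not in wide.index or k not in wide.columns or pd.isna(wide.at[s, k])
    ]
    if missing:
        raise ValidationError(f"engagement scores missing for: {missing[:10]}")
    wide = wide.loc[want_rows, want_cols]
    arr = wide.to_numpy(dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        bad = arr[(arr < 0) | (arr > 1)]
        raise ValidationError(f"engagement scores outside [0, 1]: {bad[:5]}")
    return StimulusTable(
        meta=table.meta,
        ratings=table.ratings,
        engagement=wide,
        genre_favorite=table.genre_favorite,
        genre_ranks=table.genre_ranks,
    )
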