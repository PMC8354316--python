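"""File formats: long-CSV EEG, study tables (CSV), ground truth (JSON).

EEG travels as a tidy long CSV with columns
``subject_id, stimulus_id, channel, sample_index, microvolts`` — one row
per sample.  Sample indices are 0-based; stimulus segments are half-open
``[onset, onset + duration)``.  Study tables are plain CSVs:

* ``metadata.csv``  — stimulus_id, artist, single_flag, streams_early,
  streams_late (streams in millions unless ``units='raw'``)
* ``ratings.csv``   — subject_id, stimulus_id, rating (1–5)
* ``engagement.csv``— subject_id, stimulus_id, engagement (optional)
* ``genres.csv``    — subject_id, rank_1 .. rank_6 (or a ``favorite``
  column)
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import EEGRecording, FormatError, StimulusTable, ValidationError
from .simulate import GroundTruth

EEG_COLUMNS = ["subject_id", "stimulus_id", "channel", "sample_index", "microvolts"]


def write_recordings(recordings: Iterable[EEGRecording], path) -> Path:
    """Write recordings as one long CSV (format ``csv``)."""
    path = Path(path)
    chunks = []
    for rec in recordings:
        n = rec.n_samples
        for ci, ch in enumerate(rec.channel_labels):
            chunks.append(
                pd.DataFrame(
                    {
                        "subject_id": rec.subject_id,
                        "stimulus_id": rec.stimulus_id,
                        "channel": ch,
                        "sample_index": np.arange(n),
                        "microvolts": rec.samples[ci],
                    }
                )
            )
    # %.17g + round_trip parsing on read keeps samples bit-exact
    pd.concat(chunks, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return path


def read_recordings(path, format: str = "csv", fs: float = 256.0) -> list[EEGRecording]:
    """Read per-stimulus recordings from a long CSV.

    All (subject, stimulus) groups must carry the same channel label set;
    a missing channel or ragged sample grid raises :class:`FormatError`
    naming the offender.  The sampling rate is not stored in the CSV and
    must be supplied.
    """
    if format != "csv":
        raise FormatError(
            f"format {format!r} not supported; EEG interchange uses long CSV"
        )
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = [c for c in EEG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")

    label_sets = {
        key: tuple(sorted(g["channel"].unique()))
        for key, g in df.groupby(["subject_id", "stimulus_id"], sort=True)
    }
    reference = next(iter(label_sets.values()))
    for (subj, stim), labels in label_sets.items():
        if labels != reference:
            absent = sorted(set(reference) - set(labels))
            raise FormatError(
                f"subject {subj}, stimulus {stim}: channel set mismatch "
                f"(missing {absent or 'none'}, has extra "
                f"{sorted(set(labels) - set(reference)) or 'none'})"
            )

    recordings = []
    for (subj, stim), g in df.groupby(["subject_id", "stimulus_id"], sort=True):
        wide = g.pivot(index="sample_index", columns="channel", values="microvolts")
        if wide.isna().any().any():
            bad = wide.columns[wide.isna().any()].tolist()
            raise FormatError(
                f"subject {subj}, stimulus {stim}: ragged samples in channels {bad}"
            )
        # keep first-appearance channel order from the file
        order = list(dict.fromkeys(g["channel"]))
        recordings.append(
            EEGRecording(
                subject_id=str(subj),
                stimulus_id=str(stim),
                fs=fs,
                channel_labels=order,
                samples=wide[order].to_numpy().T,
            )
        )
    return recordings


def segment_recording(
    rec: EEGRecording, onsets_s: Sequence[float], duration_s: float, stimulus_ids=None
) -> list[EEGRecording]:
    """Cut a continuous recording into half-open per-stimulus segments."""
    n_seg = int(round(duration_s * rec.fs))
    out = []
    ids = stimulus_ids or [f"stim{i + 1:02d}" for i in range(len(onsets_s))]
    for onset, sid in zip(onsets_s, ids):
        start = int(round(onset * rec.fs))
        stop = start + n_seg
        if stop > rec.n_samples:
            raise FormatError(
                f"segment {sid} at {onset}s runs past the end of the recording"
            )
        out.append(
            EEGRecording(
                subject_id=rec.subject_id,
                stimulus_id=sid,
                fs=rec.fs,
                channel_labels=rec.channel_labels,
                samples=rec.samples[:, start:stop].copy(),
                mask=rec.mask[start:stop].copy(),
            )
        )
    return out


def write_tables(table: StimulusTable, outdir) -> dict[str, Path]:
    """Write metadata/ratings/engagement/genres CSVs; return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    meta = table.meta.reset_index()
    paths["metadata"] = outdir / "metadata.csv"
    meta.to_csv(paths["metadata"], index=False)

    long_r = (
        table.ratings.stack()
        .rename("rating")
        .rename_axis(["subject_id", "stimulus_id"])
        .reset_index()
    )
    paths["ratings"] = outdir / "ratings.csv"
    long_r.to_csv(paths["ratings"], index=False)

    if table.engagement is not None:
        long_e = (
            table.engagement.stack()
            .rename("engagement")
            .rename_axis(["subject_id", "stimulus_id"])
            .reset_index()
        )
        paths["engagement"] = outdir / "engagement.csv"
        long_e.to_csv(paths["engagement"], index=False)

    if table.genre_ranks is not None or table.genre_favorite is not None:
        g = pd.DataFrame(index=table.ratings.index)
        if table.genre_favorite is not None:
            g["favorite"] = table.genre_favorite
        if table.genre_ranks is not None:
            g = g.join(table.genre_ranks)
        paths["genres"] = outdir / "genres.csv"
        g.reset_index().to_csv(paths["genres"], index=False)
    return paths


def read_tables(
    metadata_path,
    ratings_path,
    engagement_path=None,
    genres_path=None,
    units: str = "millions",
) -> StimulusTable:
    """Assemble a :class:`StimulusTable` from CSVs, validating invariants.

    ``units='raw'`` divides stream counts by 10⁶ on read.
    """
    meta = pd.read_csv(metadata_path)
    if "stimulus_id" not in meta.columns:
        raise FormatError("metadata: missing stimulus_id column")
    if meta["stimulus_id"].duplicated().any():
        dups = meta.loc[meta["stimulus_id"].duplicated(), "stimulus_id"].tolist()
        raise ValidationError(f"duplicate stimulus_id: {dups}")
    meta = meta.set_index("stimulus_id")
    if units == "raw":
        for col in ("streams_early", "streams_late"):
            if col in meta:
                meta[col] = meta[col] / 1e6
    elif units != "millions":
        raise FormatError(f"unknown units {units!r}; use 'millions' or 'raw'")
    if "single_flag" in meta:
        meta["single_flag"] = meta["single_flag"].astype(bool)

    ratings_long = pd.read_csv(ratings_path)
    for c in ("subject_id", "stimulus_id", "rating"):
        if c not in ratings_long.columns:
            raise FormatError(f"ratings: missing column {c}")
    bad = ratings_long[~ratings_long["rating"].isin([1, 2, 3, 4, 5])]
    if len(bad):
        raise ValidationError(
            f"ratings outside 1-5: {bad['rating'].unique().tolist()}"
        )
    ratings = ratings_long.pivot(
        index="subject_id", columns="stimulus_id", values="rating"
    )
    if ratings.isna().any().any():
        raise ValidationError("ratings grid has missing (subject, stimulus) cells")
    ratings = ratings.astype(int)

    engagement = None
    if engagement_path is not None:
        e = pd.read_csv(engagement_path)
        engagement = e.pivot(
            index="subject_id", columns="stimulus_id", values="engagement"
        )

    favorite = ranks = None
    if genres_path is not None:
        g = pd.read_csv(genres_path).set_index("subject_id")
        if "favorite" in g.columns:
            favorite = g["favorite"]
        rank_cols = [c for c in g.columns if c.startswith("rank_")]
        if rank_cols:
            ranks = g[rank_cols]
            if favorite is None:
                favorite = ranks["rank_1"].rename("favorite")
    return StimulusTable(
        meta=meta,
        ratings=ratings,
        engagement=engagement,
        genre_favorite=favorite,
        genre_ranks=ranks,
    )


def write_ground_truth(truth: GroundTruth, path) -> Path:
    path = Path(path)
    payload = {
        "shared_weight": truth.shared_weight.tolist(),
        "valence": truth.valence.tolist(),
        "single_flag": truth.single_flag.astype(bool).tolist(),
        "artist_label": list(truth.artist_label),
        "true_synchrony": truth.true_synchrony.tolist(),
        "expected_log_streams": truth.expected_log_streams.tolist(),
        "faa_offset": truth.faa_offset.tolist(),
        "subject_phase": truth.subject_phase.tolist(),
        "subject_freq": truth.subject_freq.tolist(),
        "artifact_indices": {
            f"{s}|{k}": v.tolist() for (s, k), v in truth.artifact_indices.items()
        },
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        shared_weight=np.array(d["shared_weight"]),
        valence=np.array(d["valence"]),
        single_flag=np.array(d["single_flag"], dtype=bool),
        artist_label=np.array(d["artist_label"], dtype=object),
        true_synchrony=np.array(d["true_synchrony"]),
        expected_log_streams=np.array(d["expected_log_streams"]),
        faa_offset=np.array(d["faa_offset"]),
        subject_phase=np.array(d["subject_phase"]),
        subject_freq=np.array(d["subject_freq"]),
        artifact_indices={
            tuple(k.split("|")): np.array(v, dtype=int)
            for k, v in d["artifact_indices"].items()
        },
    )
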