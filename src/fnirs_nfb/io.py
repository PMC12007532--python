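"""File formats: tabular recordings, SNIRF-style HDF5, events, behavior.

The canonical tabular dialect is UTF-8 tab-separated with a header row,
dot decimals, and times in seconds from recording start.  A recording is
one row per sample per channel (``time_s, channel, hemisphere, hbo,
hbr``); events are one row per condition interval; behavioral tables are
one row per trial.  Round trips preserve sample values to better than
1e-9.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .core import EventSchedule, HbRecording

_FLOAT_FMT = "%.12g"


class SchemaError(ValueError):
    """A file does not match the expected schema."""


# ---------------------------------------------------------------------------
# Recording TSV
# ---------------------------------------------------------------------------

RECORDING_COLUMNS = ("time_s", "channel", "hemisphere", "hbo", "hbr")


def write_recording_tsv(recording: HbRecording, path) -> None:
    n, c = recording.n_samples, recording.n_channels
    t = recording.time
    df = pd.DataFrame({
        "time_s": np.repeat(t, c),
        "channel": np.tile(recording.channels, n),
        "hemisphere": np.tile(recording.hemispheres, n),
        "hbo": recording.hbo.ravel(),
        "hbr": recording.hbr.ravel(),
    })
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz\t{recording.sample_rate}\n")
        fh.write(f"# feedback_channel\t{recording.feedback_channel}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_recording_tsv(path) -> HbRecording:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("\t")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    unknown = set(df.columns) - set(RECORDING_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown recording columns: {sorted(unknown)}")
    missing = set(RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing recording columns: {sorted(missing)}")
    if df.duplicated(subset=["time_s", "channel"]).any():
        raise SchemaError("duplicate (time, channel) rows")
    channels = list(dict.fromkeys(df["channel"]))
    hemis = [df.loc[df["channel"] == ch, "hemisphere"].iloc[0] for ch in channels]
    times = np.sort(df["time_s"].unique())
    if np.any(np.diff(times) <= 0):
        raise SchemaError("non-monotone time axis")
    wide_o = df.pivot(index="time_s", columns="channel", values="hbo")
    wide_r = df.pivot(index="time_s", columns="channel", values="hbr")
    if wide_o.isna().any().any() or wide_r.isna().any().any():
        raise SchemaError("missing samples for some (time, channel) pairs")
    if "sample_rate_hz" in meta:
        fs = float(meta["sample_rate_hz"])
    else:
        fs = 1.0 / float(np.median(np.diff(times)))
    fb = meta.get("feedback_channel", channels[0])
    return HbRecording(
        sample_rate=fs, channels=channels, hemispheres=hemis,
        feedback_channel=fb,
        hbo=wide_o[channels].to_numpy(), hbr=wide_r[channels].to_numpy(),
    )


# ---------------------------------------------------------------------------
# SNIRF-style HDF5
# ---------------------------------------------------------------------------

def write_recording_snirf(recording: HbRecording, path) -> None:
    """Write the recording as an HDF5 file following the SNIRF layout
    (/nirs/data1/dataTimeSeries with HbO/HbR measurement-list entries).
    Channel names, hemisphere labels and the feedback channel are stored as
    additional datasets so a round trip is lossless."""
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        d = f.create_group("nirs/data1")
        series = np.hstack([recording.hbo, recording.hbr])
        d.create_dataset("dataTimeSeries", data=series)
        d.create_dataset("time", data=recording.time)
        for i, label in enumerate(["HbO"] * recording.n_channels
                                  + ["HbR"] * recording.n_channels, start=1):
            ml = d.create_group(f"measurementList{i}")
            ch = (i - 1) % recording.n_channels
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel", data=label)
        meta = f.create_group("nirs/metaDataTags")
        meta.create_dataset("channelNames",
                            data=[c.encode() for c in recording.channels])
        meta.create_dataset("hemispheres",
                            data=[h.encode() for h in recording.hemispheres])
        meta.create_dataset("feedbackChannel", data=recording.feedback_channel)
        meta.create_dataset("sampleRate", data=recording.sample_rate)


def read_recording_snirf(path) -> HbRecording:
    with h5py.File(path, "r") as f:
        d = f["nirs/data1"]
        series = d["dataTimeSeries"][()]
        meta = f["nirs/metaDataTags"]
        channels = [c.decode() for c in meta["channelNames"][()]]
        hemis = [h.decode() for h in meta["hemispheres"][()]]
        fb = meta["feedbackChannel"][()]
        fb = fb.decode() if isinstance(fb, bytes) else str(fb)
        fs = float(meta["sampleRate"][()])
    n_ch = len(channels)
    if series.shape[1] != 2 * n_ch:
        raise SchemaError("dataTimeSeries width does not match channel list")
    return HbRecording(
        sample_rate=fs, channels=channels, hemispheres=hemis,
        feedback_channel=fb, hbo=series[:, :n_ch], hbr=series[:, n_ch:],
    )


# ---------------------------------------------------------------------------
# Events and behavior tables
# ---------------------------------------------------------------------------

def write_events_tsv(schedule: EventSchedule, path) -> None:
    schedule.events.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events_tsv(path) -> EventSchedule:
    df = pd.read_csv(path, sep="\t")
    missing = set(EventSchedule.REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing event columns: {sorted(missing)}")
    try:
        return EventSchedule(df)
    except ValueError as exc:
        raise SchemaError(str(exc)) from None


BEHAVIOR_COLUMNS = ("participant", "group", "time", "task", "block",
                    "block_type", "trial_validity", "condition", "rt", "correct")


def write_behavior_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_behavior_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing behavior columns: {sorted(missing)}")
    if (df["rt"] <= 0).any():
        raise SchemaError("reaction times must be positive")
    df["correct"] = df["correct"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Results JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results_json(payload: dict, path) -> None:
    """Deterministic result serialization: sorted keys, no timestamps."""
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
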