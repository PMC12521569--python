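"""Session container I/O: HDF5 (primary) and a plain-CSV fallback.

The HDF5 layout stores ``raw`` (or ``trace465``/``trace405``) and ``speed``
datasets, event-time datasets ``cue``/``lick``/``delivery``, and the pulse
schedule plus animal metadata as root attributes.  Datasets are written
without embedded timestamps so identical sessions produce byte-identical
files.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import SessionMeta, SessionRecording
from .signal import ChannelTrace, PulseSchedule

__all__ = [
    "write_session_h5",
    "read_session_h5",
    "write_session_csv",
    "read_session_csv",
    "write_ground_truth_csv",
]

_META_ATTRS = ("mouse_id", "session_id", "diet", "condition", "sex")


def _dset(g: h5py.Group, name: str, data: np.ndarray) -> None:
    g.create_dataset(name, data=np.asarray(data, dtype=float), track_times=False)


def write_session_h5(rec: SessionRecording, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=True) as f:
        if rec.raw_samples is not None:
            _dset(f, "raw", rec.raw_samples)
        else:
            _dset(f, "trace465", rec.trace465.values)
            if rec.trace405 is not None:
                _dset(f, "trace405", rec.trace405.values)
        _dset(f, "cue", rec.cue_times)
        _dset(f, "lick", rec.lick_times)
        _dset(f, "delivery", rec.delivery_times)
        _dset(f, "speed", rec.speed_samples)
        f.attrs["speed_rate"] = rec.speed_rate
        s = rec.schedule
        f.attrs["cycle_period"] = s.cycle_period
        f.attrs["ch465_window"] = list(s.ch465_window)
        f.attrs["ch405_window"] = list(s.ch405_window)
        f.attrs["raw_rate"] = s.raw_rate
        for name in _META_ATTRS:
            f.attrs[name] = getattr(rec.meta, name)
        f.attrs["body_weight"] = rec.meta.body_weight
    return path


def read_session_h5(path: str | os.PathLike) -> SessionRecording:
    with h5py.File(path, "r") as f:
        schedule = PulseSchedule(
            cycle_period=float(f.attrs["cycle_period"]),
            ch465_window=tuple(f.attrs["ch465_window"]),
            ch405_window=tuple(f.attrs["ch405_window"]),
            raw_rate=float(f.attrs["raw_rate"]),
        )
        meta = SessionMeta(
            **{k: str(f.attrs[k]) for k in _META_ATTRS},
            body_weight=float(f.attrs["body_weight"]),
        )
        kw = {}
        if "raw" in f:
            kw["raw_samples"] = f["raw"][:]
        else:
            kw["trace465"] = ChannelTrace(f["trace465"][:], rate=schedule.output_rate,
                                          channel="465")
            if "trace405" in f:
                kw["trace405"] = ChannelTrace(f["trace405"][:],
                                              rate=schedule.output_rate, channel="405")
        return SessionRecording(
            meta=meta, schedule=schedule,
            cue_times=f["cue"][:], lick_times=f["lick"][:],
            delivery_times=f["delivery"][:], speed_samples=f["speed"][:],
            speed_rate=float(f.attrs["speed_rate"]), **kw,
        )


def write_session_csv(rec: SessionRecording, events_path, samples_path) -> None:
    """Plain-CSV fallback: one events table and one samples table."""
    ev = []
    for kind, times in (("cue", rec.cue_times), ("lick", rec.lick_times),
                        ("delivery", rec.delivery_times)):
        ev.extend({"kind": kind, "time": float(t)} for t in times)
    pd.DataFrame(ev, columns=["kind", "time"]).to_csv(events_path, index=False)
    if rec.raw_samples is not None:
        df = pd.DataFrame({"value": rec.raw_samples})
        df.insert(0, "stream", "raw")
    else:
        df = pd.DataFrame({"value": rec.trace465.values})
        df.insert(0, "stream", "trace465")
    df.to_csv(samples_path, index=False)


def read_session_csv(events_path, samples_path, meta: SessionMeta,
                     schedule: PulseSchedule | None = None) -> SessionRecording:
    schedule = schedule or PulseSchedule()
    ev = pd.read_csv(events_path)
    sm = pd.read_csv(samples_path)
    times = lambda kind: ev.loc[ev["kind"] == kind, "time"].to_numpy()
    kw = {}
    stream = sm["stream"].iloc[0]
    if stream == "raw":
        kw["raw_samples"] = sm["value"].to_numpy()
    else:
        kw["trace465"] = ChannelTrace(sm["value"].to_numpy(),
                                      rate=schedule.output_rate, channel="465")
    return SessionRecording(meta=meta, schedule=schedule, cue_times=times("cue"),
                            lick_times=times("lick"),
                            delivery_times=times("delivery"), **kw)


def write_ground_truth_csv(truths, path) -> Path:
    """Ground-truth sidecar: one row per trial across all sessions."""
    frames = []
    for gt in truths:
        df = gt.trials.copy()
        df.insert(0, "session", gt.session_id)
        df.insert(1, "mouse", gt.mouse_id)
        df.insert(2, "group", gt.group)
        df["seed_key"] = "-".join(map(str, gt.seed_key))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path
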