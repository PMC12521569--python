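"""Session containers: one head-fixed feeding recording per object.

A session holds either the raw multiplexed photodetector stream (raw-level)
or already-demultiplexed 50 Hz channel traces (trace-level), together with
the behavioral event streams (cue onsets, licks, liquid-diet delivery
pulses), treadmill speed, and animal metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .signal import ChannelTrace, PulseSchedule

__all__ = ["SessionMeta", "SessionRecording"]


@dataclass
class SessionMeta:
    mouse_id: str
    session_id: str
    diet: str = "NCD"
    condition: str = "NCD"
    body_weight: float = float("nan")  # grams
    sex: str = "U"


@dataclass
class SessionRecording:
    """One recording session.

    Exactly one of ``raw_samples`` (photodetector stream at
    ``schedule.raw_rate``) or ``trace465`` (50 Hz demultiplexed trace) must
    be present; trace-level sessions may also carry ``trace405``.
    """

    meta: SessionMeta
    schedule: PulseSchedule = field(default_factory=PulseSchedule)
    raw_samples: Optional[np.ndarray] = None
    trace465: Optional[ChannelTrace] = None
    trace405: Optional[ChannelTrace] = None
    cue_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    delivery_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    speed_samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    speed_rate: float = 10.0

    def __post_init__(self) -> None:
        for name in ("cue_times", "lick_times", "delivery_times", "speed_samples"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.raw_samples is not None:
            self.raw_samples = np.asarray(self.raw_samples, dtype=float)
        if self.raw_samples is None and self.trace465 is None:
            raise ValueError("session needs raw_samples or a 465 nm trace")
        cues = self.cue_times
        if cues.size and np.any(np.diff(cues) <= 0):
            raise ValueError("cue_times must be strictly increasing")
        dur = self.duration
        for name in ("cue_times", "lick_times", "delivery_times"):
            t = getattr(self, name)
            if t.size and (t.min() < 0 or t.max() > dur + 1e-9):
                raise ValueError(f"{name} fall outside the recording [0, {dur:.3f}] s")

    @property
    def level(self) -> str:
        return "raw" if self.raw_samples is not None else "trace"

    @property
    def duration(self) -> float:
        if self.raw_samples is not None:
            return self.raw_samples.size / self.schedule.raw_rate
        return self.trace465.duration
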