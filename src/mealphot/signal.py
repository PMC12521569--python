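"""Reconstruction of per-channel fluorescence from a time-division-multiplexed
photodetector stream, and trace-level normalisation.

A single photodetector samples fluorescence while two excitation LEDs are
pulsed in alternation within a fixed cycle (by default 20 ms: 465 nm on for
6 ms, then 405 nm on for 14 ms).  Demultiplexing takes the median of the raw
samples falling inside each channel's pulse window, yielding one sample per
cycle (50 Hz for the default schedule).  The signal channel is then low-pass
filtered and, downstream, converted to dF/F and to per-animal Z units.

The Z normalisation follows the convention of computing a single mean and
standard deviation per animal over the concatenation of all analysed samples
from that animal's included sessions, so that Z units are comparable across
sessions and days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "PulseSchedule",
    "ChannelTrace",
    "AnimalZStats",
    "demultiplex",
    "demultiplex_stream",
    "lowpass",
    "fit_animal_zstats",
    "apply_zscore",
]


@dataclass(frozen=True)
class PulseSchedule:
    """LED pulse timing within one excitation cycle.

    Defaults encode a 20 ms cycle with the 465 nm LED on for the first 6 ms
    and the 405 nm LED on for the remaining 14 ms, sampled at 1 kHz.
    """

    cycle_period: float = 0.020
    ch465_window: tuple[float, float] = (0.0, 0.006)  # (offset, duration) s
    ch405_window: tuple[float, float] = (0.006, 0.014)
    raw_rate: float = 1000.0

    def __post_init__(self) -> None:
        spc = self.cycle_period * self.raw_rate
        if abs(spc - round(spc)) > 1e-9 or round(spc) < 1:
            raise ValueError(
                f"raw_rate x cycle_period must be an integer sample count, got {spc}"
            )
        for name, (off, dur) in (("465", self.ch465_window), ("405", self.ch405_window)):
            if dur <= 0:
                raise ValueError(f"channel {name} window duration must be > 0")
            if off < 0 or off + dur > self.cycle_period + 1e-12:
                raise ValueError(f"channel {name} window does not fit in the cycle")
        a0, a1 = self.ch465_window[0], sum(self.ch465_window)
        b0, b1 = self.ch405_window[0], sum(self.ch405_window)
        if max(a0, b0) < min(a1, b1):
            raise ValueError("channel pulse windows overlap")

    @property
    def samples_per_cycle(self) -> int:
        return round(self.cycle_period * self.raw_rate)

    @property
    def output_rate(self) -> float:
        """Rate of the demultiplexed trace (one sample per cycle)."""
        return 1.0 / self.cycle_period

    def window_indices(self, channel: str) -> np.ndarray:
        """Raw-sample indices within a cycle belonging to ``channel``."""
        try:
            off, dur = {"465": self.ch465_window, "405": self.ch405_window}[str(channel)]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}; expected '465' or '405'")
        i0 = round(off * self.raw_rate)
        n = round(dur * self.raw_rate)
        if n < 1:
            raise ValueError(f"channel {channel} window shorter than one raw sample")
        return np.arange(i0, i0 + n)


@dataclass
class ChannelTrace:
    """Single-channel fluorescence trace at the demultiplexed rate."""

    values: np.ndarray
    rate: float = 50.0
    channel: str = "465"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


def demultiplex_stream(
    raw: np.ndarray, schedule: PulseSchedule, channel: str = "465"
) -> ChannelTrace:
    """Extract one channel from a raw multiplexed sample stream.

    One output sample per pulse cycle, the median of the raw samples falling
    in that channel's pulse window.  A trailing partial cycle is dropped.
    """
    raw = np.asarray(raw, dtype=float)
    spc = schedule.samples_per_cycle
    n_cycles = raw.size // spc
    if n_cycles == 0:
        raise ValueError("raw stream shorter than one pulse cycle")
    idx = schedule.window_indices(channel)
    cycles = raw[: n_cycles * spc].reshape(n_cycles, spc)
    values = np.median(cycles[:, idx], axis=1)
    return ChannelTrace(values, rate=schedule.output_rate, channel=channel, t0=0.0)


def demultiplex(rec, channel: str = "465") -> ChannelTrace:
    """Demultiplex a session recording; raw-level sessions are demodulated,
    trace-level sessions return the stored channel trace directly."""
    if getattr(rec, "raw_samples", None) is not None:
        return demultiplex_stream(rec.raw_samples, rec.schedule, channel)
    trace = {"465": rec.trace465, "405": rec.trace405}.get(str(channel))
    if trace is None:
        raise ValueError(f"channel {channel!r} not present in recording")
    return trace


def lowpass(trace: ChannelTrace, cutoff: float = 10.0, order: int = 4) -> ChannelTrace:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Forward-backward application preserves event latencies; DC gain is 1.
    """
    nyq = trace.rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    b, a = butter(order, cutoff / nyq)
    values = filtfilt(b, a, trace.values)
    return ChannelTrace(values, rate=trace.rate, channel=trace.channel, t0=trace.t0)


@dataclass
class AnimalZStats:
    """Per-animal Z-score normaliser.

    mean/sd are computed once per animal over the concatenation of all
    analysed dF/F samples from that animal's included sessions, so a single
    Z scale applies across recording days.  The sd uses the population
    convention (divide by n).
    """

    mouse_id: str
    mean: float
    sd: float
    n_samples_used: int
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("AnimalZStats requires sd > 0")


def fit_animal_zstats(
    dff_by_session: Mapping[str, Iterable[np.ndarray]] | Mapping[str, np.ndarray],
    mouse_id: str = "",
) -> AnimalZStats:
    """Fit the per-animal Z statistics from per-session dF/F sample collections.

    Parameters
    ----------
    dff_by_session
        Mapping from session id to an array (or list of arrays) of the
        session's analysed dF/F samples (typically the triggered-trial
        60-s windows).  Non-finite samples are ignored.
    """
    chunks: list[np.ndarray] = []
    provenance: list[str] = []
    for sid, arrs in dff_by_session.items():
        if isinstance(arrs, np.ndarray):
            arrs = [arrs]
        vals = [np.asarray(a, dtype=float).ravel() for a in arrs]
        if vals:
            chunks.append(np.concatenate(vals))
            provenance.append(str(sid))
    if not chunks:
        raise ValueError("no sessions provided for Z statistics")
    x = np.concatenate(chunks)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite samples for Z statistics")
    mean = float(np.mean(x))
    sd = float(np.std(x))  # population convention (ddof=0)
    if sd <= 0:
        raise ValueError(
            f"degenerate recording for mouse {mouse_id!r}: zero variance across "
            f"{x.size} concatenated samples"
        )
    return AnimalZStats(
        mouse_id=mouse_id, mean=mean, sd=sd, n_samples_used=int(x.size), provenance=provenance
    )


def apply_zscore(x: np.ndarray, stats: AnimalZStats) -> np.ndarray:
    """Elementwise (x - mean) / sd in the animal's Z units."""
    return (np.asarray(x, dtype=float) - stats.mean) / stats.sd
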