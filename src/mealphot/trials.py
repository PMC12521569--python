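"""Event alignment: trial tables, cue-locked segmentation, dF/F, inclusion.

Each trial spans a 60-s analysis window beginning 10 s before the tone cue.
A trial is *triggered* when at least one lick falls in the half-open 1-s cue
window [cue, cue + 1); only triggered trials enter meal analyses, and a
session is included only when at least 30 trials were triggered.  Per trial,
F0 is the mean fluorescence over the 10 s pre-cue and dF/F = (F - F0) / F0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .session import SessionMeta, SessionRecording
from .signal import AnimalZStats, ChannelTrace, apply_zscore, demultiplex, fit_animal_zstats, lowpass

logger = logging.getLogger(__name__)

__all__ = [
    "TrialRecord",
    "TrialMatrix",
    "SessionAnalysis",
    "AnalysisParams",
    "build_trial_table",
    "segment",
    "compute_dff",
    "apply_inclusion",
    "analyze_session",
    "attach_zscores",
    "analyze_cohort",
]


@dataclass
class TrialRecord:
    """One trial's behavioral outcome, times relative to the cue."""

    index: int  # 0-based trial number
    cue_time: float  # absolute, seconds
    triggered: bool
    trigger_lick_time: Optional[float] = None  # relative to cue
    lick_times_in_trial: np.ndarray = field(default_factory=lambda: np.empty(0))
    delivery_times: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class TrialMatrix:
    """trials x time matrix on a cue-locked axis (seconds relative to cue)."""

    values: np.ndarray
    time_axis: np.ndarray
    trial_indices: np.ndarray
    units: str = "raw"  # raw | dff | zscore
    f0: Optional[np.ndarray] = None  # per-row baseline, set by compute_dff
    invalid_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def column_mask(self, start: float, end: float) -> np.ndarray:
        return (self.time_axis >= start) & (self.time_axis < end)


@dataclass
class AnalysisParams:
    """Tunable knobs of the per-session analysis path."""

    cue_window: float = 1.0
    pre: float = 10.0
    post: float = 50.0
    lowpass_cutoff: Optional[float] = 10.0  # Hz; None bypasses the filter
    min_triggered: int = 30
    zscore_domain: str = "trial_windows"  # or "full_trace"
    zscore_triggered_only: bool = True


def build_trial_table(
    rec: SessionRecording,
    cue_window: float = 1.0,
    pre: float = 10.0,
    post: float = 50.0,
) -> list[TrialRecord]:
    """Classify every cue as triggered/untriggered and collect its events.

    A trial is triggered iff a lick falls in [cue, cue + cue_window); the
    boundary at exactly cue + cue_window does not trigger.  Licks and
    delivery pulses are assigned to the trial whose [cue - pre, cue + post)
    window contains them.
    """
    cues = np.asarray(rec.cue_times, dtype=float)
    if cues.size == 0:
        raise ValueError("recording has no cue times")
    if cues.size > 1 and np.min(np.diff(cues)) < pre + post - 1e-9:
        raise ValueError(
            f"inter-trial interval {np.min(np.diff(cues)):.3f} s is shorter than "
            f"the {pre + post:.0f}-s trial analysis window"
        )
    licks = np.sort(np.asarray(rec.lick_times, dtype=float))
    deliveries = np.sort(np.asarray(rec.delivery_times, dtype=float))
    out: list[TrialRecord] = []
    for k, cue in enumerate(cues):
        in_win = licks[(licks >= cue - pre) & (licks < cue + post)] - cue
        in_cue = in_win[(in_win >= 0.0) & (in_win < cue_window)]
        dv = deliveries[(deliveries >= cue - pre) & (deliveries < cue + post)] - cue
        triggered = in_cue.size > 0
        out.append(TrialRecord(
            index=k, cue_time=float(cue), triggered=triggered,
            trigger_lick_time=float(in_cue[0]) if triggered else None,
            lick_times_in_trial=in_win, delivery_times=dv,
        ))
    return out


def segment(
    trace: ChannelTrace,
    cue_times: Sequence[float],
    pre: float = 10.0,
    post: float = 50.0,
) -> TrialMatrix:
    """Cut cue-locked windows [cue - pre, cue + post) out of a trace.

    Rows are time-locked: column j is the same latency for every trial.
    Trials whose window falls outside the recording are dropped with a
    warning (their original indices simply do not appear in trial_indices).
    """
    rate = trace.rate
    n_cols = round((pre + post) * rate)
    time_axis = -pre + np.arange(n_cols) / rate
    rows, kept = [], []
    for k, cue in enumerate(np.asarray(cue_times, dtype=float)):
        i0 = round((cue - pre - trace.t0) * rate)
        if i0 < 0 or i0 + n_cols > trace.values.size:
            logger.warning("trial %d window [%0.1f, %0.1f) s out of bounds; excluded",
                           k, cue - pre, cue + post)
            continue
        rows.append(trace.values[i0: i0 + n_cols])
        kept.append(k)
    if not rows:
        raise ValueError("no trial window lies within the recording")
    return TrialMatrix(values=np.array(rows), time_axis=time_axis,
                       trial_indices=np.array(kept, dtype=int), units="raw")


def compute_dff(matrix: TrialMatrix) -> TrialMatrix:
    """Per-row fractional fluorescence change about the pre-cue baseline.

    F0 is the mean over the pre-cue columns (time < 0) of that row only;
    rows with F0 <= 0 are flagged invalid and set to NaN.
    """
    if matrix.units != "raw":
        raise ValueError(f"expected raw-unit matrix, got {matrix.units!r}")
    pre_cols = matrix.time_axis < 0.0
    if not pre_cols.any():
        raise ValueError("matrix has no pre-cue columns for F0")
    f0 = matrix.values[:, pre_cols].mean(axis=1)
    bad = ~(f0 > 0)
    if bad.any():
        logger.warning("%d trial(s) with non-positive F0 flagged invalid", int(bad.sum()))
    safe = np.where(bad, np.nan, f0)
    values = (matrix.values - safe[:, None]) / safe[:, None]
    return TrialMatrix(values=values, time_axis=matrix.time_axis,
                       trial_indices=matrix.trial_indices, units="dff",
                       f0=f0, invalid_rows=np.flatnonzero(bad))


@dataclass
class SessionAnalysis:
    """Per-session analysis product: trial table plus dF/F (and Z) matrices."""

    meta: SessionMeta
    trials: list[TrialRecord]
    dff: TrialMatrix
    z: Optional[TrialMatrix] = None
    included: bool = False
    n_triggered: int = 0
    min_triggered: int = 30

    @property
    def triggered_indices(self) -> np.ndarray:
        return np.array([t.index for t in self.trials if t.triggered], dtype=int)

    def matrix_rows(self, matrix: TrialMatrix, triggered_only: bool = True) -> np.ndarray:
        """Rows of ``matrix`` for (triggered) trials, in trial order."""
        wanted = set(self.triggered_indices.tolist()) if triggered_only else None
        keep = [i for i, k in enumerate(matrix.trial_indices)
                if wanted is None or k in wanted]
        return matrix.values[keep]

    def triggered_records(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.triggered]


def apply_inclusion(session: SessionAnalysis, min_triggered: int = 30) -> SessionAnalysis:
    """Apply the session inclusion rule: >= min_triggered triggered trials."""
    session.n_triggered = int(sum(t.triggered for t in session.trials))
    session.min_triggered = int(min_triggered)
    session.included = session.n_triggered >= min_triggered
    return session


def analyze_session(
    rec: SessionRecording, params: AnalysisParams | None = None
) -> SessionAnalysis:
    """Demultiplex, filter, segment and compute dF/F for one session.

    Z-scoring is deferred to :func:`attach_zscores`, which needs the
    animal-level statistics pooled over that mouse's included sessions.
    """
    params = params or AnalysisParams()
    trace = demultiplex(rec, "465")
    if params.lowpass_cutoff is not None:
        trace = lowpass(trace, params.lowpass_cutoff)
    table = build_trial_table(rec, cue_window=params.cue_window,
                              pre=params.pre, post=params.post)
    raw_m = segment(trace, rec.cue_times, pre=params.pre, post=params.post)
    dff = compute_dff(raw_m)
    sa = SessionAnalysis(meta=rec.meta, trials=table, dff=dff)
    sa._trace465 = trace  # kept for baseline-variability metrics
    sa._speed = (rec.speed_samples, rec.speed_rate)  # for locomotion metrics
    return apply_inclusion(sa, params.min_triggered)


def attach_zscores(
    sessions: Sequence[SessionAnalysis], params: AnalysisParams | None = None
) -> dict[str, AnimalZStats]:
    """Fit per-animal Z statistics and attach Z matrices to every session.

    Statistics are computed over the concatenation of each animal's
    *included* sessions (by default the triggered-trial dF/F windows, the
    analysed samples); the same per-animal scale is then applied to every
    session of that animal, included or not.
    """
    params = params or AnalysisParams()
    by_mouse: dict[str, dict[str, np.ndarray]] = {}
    for sa in sessions:
        if not sa.included:
            continue
        if params.zscore_domain == "full_trace":
            samples = sa._trace465.values
        else:
            samples = sa.matrix_rows(sa.dff, triggered_only=params.zscore_triggered_only)
        by_mouse.setdefault(sa.meta.mouse_id, {})[sa.meta.session_id] = np.asarray(samples)
    stats: dict[str, AnimalZStats] = {}
    for mouse, per_session in by_mouse.items():
        stats[mouse] = fit_animal_zstats(per_session, mouse_id=mouse)
    for sa in sessions:
        st = stats.get(sa.meta.mouse_id)
        if st is None:
            logger.warning("mouse %s has no included session; no Z scale",
                           sa.meta.mouse_id)
            continue
        sa.z = TrialMatrix(values=apply_zscore(sa.dff.values, st),
                           time_axis=sa.dff.time_axis,
                           trial_indices=sa.dff.trial_indices, units="zscore",
                           invalid_rows=sa.dff.invalid_rows)
    return stats


def analyze_cohort(
    recordings: Sequence[SessionRecording], params: AnalysisParams | None = None
) -> tuple[list[SessionAnalysis], dict[str, AnimalZStats]]:
    """Run the per-session path on every recording and attach per-animal Z."""
    params = params or AnalysisParams()
    analyses = [analyze_session(rec, params) for rec in recordings]
    zstats = attach_zscores(analyses, params)
    n_inc = sum(sa.included for sa in analyses)
    logger.info("analyzed %d sessions, %d included (>= %d triggered)",
                len(analyses), n_inc, params.min_triggered)
    return analyses, zstats
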