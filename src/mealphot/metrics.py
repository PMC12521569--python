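"""Per-session and per-animal meal metrics.

All meal metrics operate on the ordered subsequence of *triggered* trials:
the meal size is their count, the early/late phases are the first/last 15,
the across-meal response change is mean(last 5) - mean(first 5) of the
peri-licking window responses, and the mid-meal response averages the 15th
through 29th triggered trials.  Windows are half-open [start, end) in
seconds post cue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trials import SessionAnalysis, TrialMatrix, TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "WINDOWS",
    "MEAL_SIZE_STRATA",
    "HeatmapBundle",
    "CorrelationResult",
    "window_response",
    "phase_means",
    "delta_z",
    "lick_rate",
    "meal_size",
    "stratify",
    "stratum_label",
    "mid_meal_mean",
    "baseline_variability",
    "heatmap_aggregate",
    "metric_correlation",
    "session_metrics",
    "cohort_metrics",
    "aggregate_by_mouse",
    "phase_table",
]


@dataclass(frozen=True)
class WindowSpec:
    name: str
    start: float  # s post cue, inclusive
    end: float  # s post cue, exclusive

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window {self.name!r}: start must be < end")

    @property
    def duration(self) -> float:
        return self.end - self.start


#: Named analysis windows (seconds post cue, half-open).
WINDOWS: dict[str, WindowSpec] = {
    "cue": WindowSpec("cue", 0.0, 1.0),
    "consumption": WindowSpec("consumption", 0.0, 10.0),
    "peri_licking": WindowSpec("peri_licking", 1.0, 10.0),
    "peri_licking_short": WindowSpec("peri_licking_short", 1.0, 9.0),
    "extended": WindowSpec("extended", 0.0, 20.0),
}

#: Meal-size strata (closed bins over the number of triggered trials).
MEAL_SIZE_STRATA: list[tuple[int, int]] = [(15, 29), (30, 44), (45, 59), (60, 74), (75, 90)]


def window_response(matrix: TrialMatrix, w: WindowSpec) -> np.ndarray:
    """Per-trial mean over the window's columns (NaN rows propagate)."""
    cols = matrix.column_mask(w.start, w.end)
    if not cols.any():
        raise ValueError(f"window {w.name!r} contains no samples on this time axis")
    return matrix.values[:, cols].mean(axis=1)


def phase_means(
    responses: Sequence[float], n_phase: int = 15
) -> tuple[float, float, bool]:
    """Early/late meal-phase means over the triggered-trial responses.

    Returns (early, late, overlap): mean of the first and of the last
    ``n_phase`` responses.  With fewer than 2*n_phase responses the two sets
    overlap (flagged); with fewer than n_phase both are NaN.
    """
    r = np.asarray(responses, dtype=float)
    if r.size < n_phase:
        logger.warning("only %d triggered trials (< %d): phase means undefined",
                       r.size, n_phase)
        return float("nan"), float("nan"), False
    overlap = r.size < 2 * n_phase
    return float(np.nanmean(r[:n_phase])), float(np.nanmean(r[-n_phase:])), overlap


def delta_z(responses: Sequence[float], n_tail: int = 5) -> float:
    """mean(last n_tail) - mean(first n_tail) of the triggered responses."""
    r = np.asarray(responses, dtype=float)
    if r.size < n_tail:
        return float("nan")
    return float(np.nanmean(r[-n_tail:]) - np.nanmean(r[:n_tail]))


def lick_rate(trial: TrialRecord, w: WindowSpec) -> float:
    """Licks per second within [start, end) seconds post cue."""
    t = np.asarray(trial.lick_times_in_trial, dtype=float)
    n = int(np.count_nonzero((t >= w.start) & (t < w.end)))
    return n / w.duration


def meal_size(session: SessionAnalysis) -> int:
    """Total number of triggered trials in the session."""
    return int(sum(t.triggered for t in session.trials))


def stratum_label(n_triggered: int) -> Optional[str]:
    """Closed meal-size bin containing ``n_triggered`` (None below 15)."""
    for lo, hi in MEAL_SIZE_STRATA:
        if lo <= n_triggered <= hi:
            return f"{lo}-{hi}"
    return None


def stratify(sessions: Sequence[SessionAnalysis]) -> list[Optional[str]]:
    return [stratum_label(meal_size(s)) for s in sessions]


def mid_meal_mean(responses: Sequence[float], first: int = 15, last: int = 29) -> float:
    """Mean response over triggered-trial ordinals 15..29 (1-based, inclusive)."""
    r = np.asarray(responses, dtype=float)
    if r.size < last:
        return float("nan")
    return float(np.nanmean(r[first - 1: last]))


def baseline_variability(
    x: np.ndarray, rate: float, window: float = 30.0, step: float = 1.0
) -> tuple[float, np.ndarray, bool]:
    """Rolling-SD summary of a pre-first-delivery fluorescence segment.

    Returns (summary, rolling_sds, short_flag): SDs over sliding windows of
    ``window`` s advanced by ``step`` s, summarised by their mean.  A
    segment shorter than one window yields the single whole-segment SD with
    short_flag set.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    n_win = round(window * rate)
    n_step = max(1, round(step * rate))
    if x.size < n_win:
        sd = float(np.std(x))
        return sd, np.array([sd]), True
    starts = np.arange(0, x.size - n_win + 1, n_step)
    sds = np.array([np.std(x[i: i + n_win]) for i in starts])
    return float(sds.mean()), sds, False


@dataclass
class HeatmapBundle:
    """Two-stage trial-average heatmaps: trials -> mouse, then mouse -> group."""

    mouse_ids: list[str]
    per_mouse: np.ndarray  # mice x time
    grand_mean: np.ndarray  # time
    time_axis: np.ndarray
    per_mouse_matrix: dict = field(default_factory=dict)  # mouse -> trials x time mean
    lick_rate_grand: Optional[np.ndarray] = None  # licks/s time course
    speed_grand: Optional[np.ndarray] = None


def heatmap_aggregate(
    sessions: Sequence[SessionAnalysis],
    units: str = "zscore",
    lick_bin: float = 0.5,
) -> HeatmapBundle:
    """Unweighted two-stage mean over triggered trials of included sessions.

    Stage 1 averages all usable triggered trials across a mouse's included
    sessions; stage 2 averages mice with equal weight regardless of their
    trial counts.  Behavioral time courses (cue-locked lick rate) are
    averaged identically.
    """
    per_mouse_rows: dict[str, list[np.ndarray]] = {}
    per_mouse_licks: dict[str, list[np.ndarray]] = {}
    time_axis = None
    for sa in sessions:
        if not sa.included:
            continue
        matrix = sa.z if units == "zscore" else sa.dff
        if matrix is None:
            continue
        time_axis = matrix.time_axis
        rows = sa.matrix_rows(matrix, triggered_only=True)
        per_mouse_rows.setdefault(sa.meta.mouse_id, []).append(rows)
        edges = np.arange(time_axis[0], time_axis[-1] + lick_bin, lick_bin)
        for tr in sa.triggered_records():
            counts, _ = np.histogram(tr.lick_times_in_trial, bins=edges)
            per_mouse_licks.setdefault(sa.meta.mouse_id, []).append(counts / lick_bin)
    if not per_mouse_rows:
        raise ValueError("no included session with the requested matrix units")
    mouse_ids = sorted(per_mouse_rows)
    per_mouse_mean = np.array([
        np.nanmean(np.vstack(per_mouse_rows[m]), axis=0) for m in mouse_ids
    ])
    lick_means = [np.mean(np.vstack(per_mouse_licks[m]), axis=0)
                  for m in mouse_ids if m in per_mouse_licks]
    return HeatmapBundle(
        mouse_ids=mouse_ids,
        per_mouse=per_mouse_mean,
        grand_mean=per_mouse_mean.mean(axis=0),
        time_axis=time_axis,
        per_mouse_matrix={m: np.nanmean(np.vstack(per_mouse_rows[m]), axis=0)
                          for m in mouse_ids},
        lick_rate_grand=(np.mean(lick_means, axis=0) if lick_means else None),
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def metric_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with the least-squares line for plotting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired finite observations, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return CorrelationResult(r=float(r), p=float(p), slope=float(fit.slope),
                             intercept=float(fit.intercept), n=int(x.size))


def _speed_window_mean(sa: SessionAnalysis, w: WindowSpec) -> float:
    """Mean treadmill speed over a cue-locked window, averaged across
    triggered trials."""
    speed, rate = getattr(sa, "_speed", (np.empty(0), 10.0))
    if speed.size == 0:
        return float("nan")
    vals = []
    for t in sa.triggered_records():
        i0 = round((t.cue_time + w.start) * rate)
        i1 = round((t.cue_time + w.end) * rate)
        if 0 <= i0 < i1 <= speed.size:
            vals.append(speed[i0:i1].mean())
    return float(np.mean(vals)) if vals else float("nan")


def _pre_ensure_segment(sa: SessionAnalysis) -> tuple[np.ndarray, float]:
    """Filtered 465 trace before the first delivery pulse, as dF/F about its mean."""
    trace = sa._trace465
    first = min((t.cue_time + t.delivery_times.min() for t in sa.trials
                 if t.delivery_times.size), default=trace.duration)
    n = round((first - trace.t0) * trace.rate)
    seg = trace.values[: max(n, 1)]
    f0 = seg.mean()
    return (seg - f0) / f0 if f0 > 0 else seg, trace.rate


def session_metrics(
    sa: SessionAnalysis,
    window: str = "peri_licking",
    n_phase: int = 15,
    n_tail: int = 5,
    speed_windows: tuple[WindowSpec, WindowSpec] = (
        WindowSpec("pre_cue", -10.0, 0.0), WindowSpec("post_reward", 1.0, 10.0)),
) -> dict:
    """One tidy metrics row for a session (NaN where undefined)."""
    w = WINDOWS[window] if isinstance(window, str) else window
    n_trig = meal_size(sa)
    row = {
        "mouse": sa.meta.mouse_id, "session": sa.meta.session_id,
        "diet": sa.meta.diet, "condition": sa.meta.condition,
        "sex": sa.meta.sex, "body_weight": sa.meta.body_weight,
        "window": w.name, "n_trials": len(sa.trials),
        "n_triggered": n_trig, "meal_size": n_trig,
        "included": sa.included, "stratum": stratum_label(n_trig),
    }
    matrix = sa.z if sa.z is not None else sa.dff
    row["units"] = matrix.units
    resp_all = window_response(matrix, w)
    by_index = dict(zip(matrix.trial_indices.tolist(), resp_all))
    trig_idx = sa.triggered_indices
    responses = np.array([by_index.get(i, np.nan) for i in trig_idx])
    early, late, overlap = phase_means(responses, n_phase)
    row.update(
        early_mean=early, late_mean=late, phase_overlap=overlap,
        delta_z=delta_z(responses, n_tail),
        mid_meal_mean=mid_meal_mean(responses),
    )
    trig_records = sa.triggered_records()
    cue_rates = [lick_rate(t, WINDOWS["cue"]) for t in trig_records]
    rew_rates = [lick_rate(t, w) for t in trig_records]
    row["cue_lick_rate"] = float(np.mean(cue_rates)) if cue_rates else np.nan
    row["reward_lick_rate"] = float(np.mean(rew_rates)) if rew_rates else np.nan
    row["mid_meal_cue_lick_rate"] = mid_meal_mean(cue_rates) if cue_rates else np.nan
    row["pre_cue_speed"] = _speed_window_mean(sa, speed_windows[0])
    row["post_reward_speed"] = _speed_window_mean(sa, speed_windows[1])
    try:
        seg, rate = _pre_ensure_segment(sa)
        row["baseline_rolling_sd"], _, row["baseline_sd_short"] = \
            baseline_variability(seg, rate)
    except (AttributeError, ValueError):
        row["baseline_rolling_sd"], row["baseline_sd_short"] = np.nan, True
    return row


def cohort_metrics(sessions: Sequence[SessionAnalysis], **kwargs) -> pd.DataFrame:
    """Tidy per-session metrics table for a cohort."""
    return pd.DataFrame([session_metrics(sa, **kwargs) for sa in sessions])


def aggregate_by_mouse(metrics: pd.DataFrame, included_only: bool = True) -> pd.DataFrame:
    """Per-mouse aggregate table: unweighted mean over (included) sessions.

    Session-level and mouse-level views of the same cohort are kept as two
    explicit tables; analyses must pick one, never mix them implicitly.
    """
    df = metrics[metrics["included"]] if included_only else metrics
    numeric = ["n_triggered", "early_mean", "late_mean", "delta_z",
               "mid_meal_mean", "cue_lick_rate", "reward_lick_rate",
               "pre_cue_speed", "post_reward_speed",
               "baseline_rolling_sd", "body_weight"]
    numeric = [c for c in numeric if c in df.columns]
    g = df.groupby(["mouse", "diet", "condition", "sex"], as_index=False)
    out = g.agg(n_sessions=("session", "count"),
                **{c: (c, "mean") for c in numeric})
    return out.sort_values("mouse").reset_index(drop=True)


def phase_table(metrics: pd.DataFrame, included_only: bool = True,
                level: str = "session") -> pd.DataFrame:
    """Long-format early/late table for the mixed-effects models.

    One row per unit x meal phase (unit = session by default, or mouse with
    ``level="mouse"``), columns value / MealPhase / Diet / Condition /
    Mouse, suitable for ``Value ~ Diet * MealPhase + (1|Mouse)``.
    """
    if level not in ("session", "mouse"):
        raise ValueError("level must be 'session' or 'mouse'")
    df = metrics[metrics["included"]] if included_only else metrics
    if level == "mouse":
        df = aggregate_by_mouse(metrics, included_only)
        df = df.assign(session=df["mouse"])
    rows = []
    for _, r in df.iterrows():
        for phase, col in (("early", "early_mean"), ("late", "late_mean")):
            rows.append({
                "value": r[col], "MealPhase": phase, "Diet": r["diet"],
                "Condition": r["condition"], "Mouse": r["mouse"],
                "session": r["session"],
            })
    cols = ["value", "MealPhase", "Diet", "Condition", "Mouse", "session"]
    out = pd.DataFrame(rows, columns=cols)
    return out.dropna(subset=["value"]).reset_index(drop=True)
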