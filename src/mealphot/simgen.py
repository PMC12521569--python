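"""Synthetic head-fixed feeding sessions with known ground truth.

Emulates the design of an operant, tone-cued liquid-diet (Ensure)
assay recorded by fiber photometry: a 5-min baseline, then 60 or 90 trials
at a 60-s inter-trial interval.  On each trial a tone sounds at t = 0 and
the animal has 1 s to lick; a lick triggers delivery of 10 x 150 ms liquid
pulses (150 ms gaps) starting at t = 1 s.  Neural responses are modelled as
a calcium-indicator-like transient locked to the delivery pulses whose
amplitude follows a satiation ramp over the *triggered*-trial ordinal, and
licking vigor decays with consumption so that meal termination emerges when
the trigger probability collapses.

Two diet-group presets capture the contrasting phenomenology of lean
(NCD-like: weak early responses that grow across the meal, large meals) and
diet-induced-obese (HFD-like: already-strong early responses with little
growth, premature satiation) cohorts.

Every session records its ground truth (per-trial programmed amplitude,
trigger outcome, lick counts, seed) so downstream estimates can be checked
against the generator's noiseless summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .session import SessionMeta, SessionRecording
from .signal import ChannelTrace, PulseSchedule

__all__ = [
    "GroupParams",
    "SimConfig",
    "SessionGroundTruth",
    "SimCohort",
    "NCD_LIKE",
    "HFD_LIKE",
    "trial_amplitude",
    "response_kernel",
    "delivery_template",
    "multiplex",
    "simulate_session",
    "simulate_cohort",
    "median_sd_factor",
]

# Standard deviation of the median of n iid standard normals, relative to
# the per-sample sd.  Monte-Carlo values for the window sizes of the default
# pulse schedule; other n fall back to the asymptotic sqrt(pi / (2 n)).
_MEDIAN_SD = {1: 1.0, 6: 0.4629, 14: 0.3200}


def median_sd_factor(n: int) -> float:
    """sd of the median of ``n`` iid Gaussian samples / per-sample sd."""
    if n in _MEDIAN_SD:
        return _MEDIAN_SD[n]
    return math.sqrt(math.pi / (2 * n))


@dataclass(frozen=True)
class GroupParams:
    """Diet-group effect structure.

    a_early / a_late are feeding-evoked response amplitudes (dF/F units;
    with the default noise calibration dF/F units coincide with Z units) at
    meal start and at satiety; the amplitude ramps linearly over the
    triggered-trial ordinal and saturates at ``satiation_capacity`` trials.
    Licking vigor decays as vigor0 * exp(-m / vigor_decline_tau) with m the
    number of triggered trials so far, and the per-trial trigger probability
    is max(trigger_floor, 1 - exp(-vigor)).
    """

    a_early: float = 0.1
    a_late: float = 0.9
    satiation_capacity: int = 50  # triggered trials to reach a_late
    vigor0: float = 5.0  # licks/s at meal start
    vigor_decline_tau: float = 40.0  # triggered trials
    trigger_floor: float = 0.05
    run_speed_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.a_early < 0 or self.a_late < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.trigger_floor <= 1:
            raise ValueError("trigger_floor must lie in [0, 1]")
        if self.vigor0 < 0:
            raise ValueError("vigor0 must be >= 0")
        if self.satiation_capacity <= 0:
            raise ValueError("satiation_capacity must be positive")
        if self.vigor_decline_tau <= 0:
            raise ValueError("vigor_decline_tau must be positive")


#: Lean cohort: weak early responses growing to strong late responses,
#: high initial vigor with slow decline (meals ~70 of 90 trials).
NCD_LIKE = GroupParams(a_early=0.1, a_late=0.9, satiation_capacity=50,
                       vigor0=5.0, vigor_decline_tau=40.0, trigger_floor=0.05,
                       run_speed_scale=1.0)

#: Obese cohort: responses already strong at meal start with little growth,
#: lower vigor declining early (meals ~50 of 90 trials), little locomotion.
HFD_LIKE = GroupParams(a_early=0.7, a_late=0.8, satiation_capacity=15,
                       vigor0=4.0, vigor_decline_tau=30.0, trigger_floor=0.05,
                       run_speed_scale=0.2)


@dataclass
class SimConfig:
    """Cohort design and acquisition parameters for the generator."""

    n_mice: int = 7  # per diet group
    sessions_per_mouse: int = 5
    n_trials: int = 90
    iti: float = 60.0
    baseline_duration: float = 300.0
    schedule: PulseSchedule = field(default_factory=PulseSchedule)
    group_params: dict = field(
        default_factory=lambda: {"NCD": NCD_LIKE, "HFD": HFD_LIKE}
    )
    # Raw additive photodetector noise sd (fluorescence units).  The default
    # is calibrated so that after median extraction and the 10 Hz low-pass
    # the per-sample dF/F sd is ~1, i.e. Z units ~ dF/F units:
    # 1 / (0.4629 [median of 6] x 0.6056 [zero-phase butter4 @ 10/25 Hz]
    #      x 1.169 [session-mean 1/bleach, additive noise over a baseline
    #               decaying with tau=20000 s across a 95-min session]).
    noise_sd: float = 3.05
    f0_base: float = 1.0
    f0_405: float = 0.5
    bleach_tau: float = 20000.0  # s; ~25% decline over a 95-min session
    kernel_rise_tau: float = 0.2  # s, indicator-like rise
    kernel_decay_tau: float = 1.5  # s, slow indicator decay
    cue_window: float = 1.0
    n_delivery_pulses: int = 10
    delivery_pulse_period: float = 0.3  # 150 ms on + 150 ms off
    response_window: tuple[float, float] = (1.0, 10.0)  # template unit-mean span
    mouse_effect_sd: float = 0.2  # per-mouse additive amplitude offset sd
    session_vigor_jitter_sd: float = 0.25  # lognormal sd on vigor0 per session
    stray_lick_fraction: float = 0.02  # of vigor, outside cue/reward windows
    level: str = "trace"  # "trace" (50 Hz) or "raw" (full multiplexed stream)
    simulate_isosbestic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.iti < 60.0 - 1e-9:
            raise ValueError("iti must cover the 60-s trial analysis span")
        for name in ("bleach_tau", "kernel_rise_tau", "kernel_decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.level not in ("trace", "raw"):
            raise ValueError("level must be 'trace' or 'raw'")

    @property
    def session_duration(self) -> float:
        return self.baseline_duration + self.n_trials * self.iti

    def cue_times(self) -> np.ndarray:
        return self.baseline_duration + np.arange(self.n_trials) * self.iti


def trial_amplitude(k: int, gp: GroupParams) -> float:
    """Programmed response amplitude at triggered-trial ordinal ``k`` (0-based).

    Linear ramp from a_early to a_late saturating at satiation_capacity.
    """
    if k < 0:
        raise ValueError("trial index must be >= 0")
    frac = min(k / gp.satiation_capacity, 1.0)
    return gp.a_early + (gp.a_late - gp.a_early) * frac


def response_kernel(
    t: np.ndarray | float, rise_tau: float = 0.2, decay_tau: float = 1.5
) -> np.ndarray:
    """Unit-peak consumption-transient kernel (1 - e^{-t/r}) e^{-t/d}, t >= 0."""
    if rise_tau <= 0 or decay_tau <= 0:
        raise ValueError("kernel time constants must be positive")
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / rise_tau))
                 * np.exp(-np.maximum(t, 0) / decay_tau), 0.0)
    # analytic peak location: t* = r ln((r + d) / r)
    t_peak = rise_tau * math.log((rise_tau + decay_tau) / rise_tau)
    peak = (1.0 - math.exp(-t_peak / rise_tau)) * math.exp(-t_peak / decay_tau)
    return k / peak


_template_cache: dict[tuple, np.ndarray] = {}


def delivery_template(config: SimConfig, rate: float = 50.0) -> np.ndarray:
    """Per-trial noiseless response waveform on [0, 50) s after the cue.

    Sum of indicator kernels at each delivery pulse onset, normalised so the
    mean over the response window (default 1-10 s post cue) equals 1; a
    trial with programmed amplitude A then has a noiseless window-mean
    response of exactly A.
    """
    key = (config.cue_window, config.n_delivery_pulses, config.delivery_pulse_period,
           config.kernel_rise_tau, config.kernel_decay_tau,
           config.response_window, rate)
    cached = _template_cache.get(key)
    if cached is not None:
        return cached
    n = round(50.0 * rate)
    t = np.arange(n) / rate
    tpl = np.zeros(n)
    for j in range(config.n_delivery_pulses):
        onset = config.cue_window + j * config.delivery_pulse_period
        tpl += response_kernel(t - onset, config.kernel_rise_tau, config.kernel_decay_tau)
    lo, hi = config.response_window
    cols = (t >= lo) & (t < hi)
    tpl /= tpl[cols].mean()
    _template_cache[key] = tpl
    return tpl


def multiplex(
    trace465: ChannelTrace,
    trace405: ChannelTrace,
    schedule: PulseSchedule,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Interleave two 50 Hz channel traces into a raw photodetector stream.

    Within cycle i the samples of each channel's pulse window take that
    channel's i-th value; iid Gaussian noise of sd ``noise_sd`` is added to
    every raw sample.  demultiplex(multiplex(x)) == x exactly at zero noise.
    """
    v465 = np.asarray(trace465.values, dtype=float)
    v405 = np.asarray(trace405.values, dtype=float)
    if v465.size != v405.size:
        raise ValueError("channel traces must have equal length")
    spc = schedule.samples_per_cycle
    raw = np.zeros((v465.size, spc))
    raw[:, schedule.window_indices("465")] = v465[:, None]
    raw[:, schedule.window_indices("405")] = v405[:, None]
    raw = raw.ravel()
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        raw = raw + noise_sd * rng.standard_normal(raw.size)
    return raw


@dataclass
class SessionGroundTruth:
    """Generator-side truth for one session."""

    session_id: str
    mouse_id: str
    group: str
    seed_key: tuple
    trials: pd.DataFrame  # trial, triggered, amplitude, cue_licks, vigor, p_trigger
    noiseless: dict  # meal_size, early15, late15, delta5

    def recompute_noiseless(self, n_phase: int = 15, n_tail: int = 5) -> dict:
        """Recompute the noiseless summaries from the stored amplitudes."""
        amps = self.trials.loc[self.trials["triggered"], "amplitude"].to_numpy()
        out = {"meal_size": int(amps.size)}
        out["early15"] = float(np.mean(amps[:n_phase])) if amps.size >= n_phase else np.nan
        out["late15"] = float(np.mean(amps[-n_phase:])) if amps.size >= n_phase else np.nan
        if amps.size >= n_tail:
            out["delta5"] = float(np.mean(amps[-n_tail:]) - np.mean(amps[:n_tail]))
        else:
            out["delta5"] = np.nan
        return out


@dataclass
class SimCohort:
    config: SimConfig
    sessions: list  # of SessionRecording
    ground_truth: list  # of SessionGroundTruth, aligned with sessions

    def __iter__(self):
        return iter(zip(self.sessions, self.ground_truth))


def _simulate_behavior(config: SimConfig, gp: GroupParams, rng: np.random.Generator,
                       vigor_scale: float) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Sequential trial loop: triggers, lick times, delivery pulse times.

    The loop is inherently sequential: the vigor on trial k depends on the
    number of triggered (consumed) trials so far.
    """
    cues = config.cue_times()
    lick_times: list[np.ndarray] = []
    delivery_times: list[np.ndarray] = []
    rows = []
    m = 0  # triggered trials so far
    for k in range(config.n_trials):
        cue = cues[k]
        vigor = gp.vigor0 * vigor_scale * math.exp(-m / gp.vigor_decline_tau)
        p = min(1.0, max(gp.trigger_floor, 1.0 - math.exp(-vigor)))
        triggered = bool(rng.random() < p)
        cue_licks = 0
        if triggered:
            first = cue + rng.uniform(0.0, config.cue_window)
            extra = rng.poisson(vigor * config.cue_window)
            licks = [np.array([first]),
                     cue + rng.uniform(0.0, config.cue_window, size=extra)]
            # consummatory licking over the delivery window
            n_rew = rng.poisson(vigor * 9.0)
            licks.append(cue + rng.uniform(1.0, 10.0, size=n_rew))
            lick_times.extend(licks)
            cue_licks = 1 + int(extra)
            delivery_times.append(
                cue + config.cue_window
                + config.delivery_pulse_period * np.arange(config.n_delivery_pulses)
            )
            m += 1
        # sparse exploratory licks away from the cue and reward windows
        n_stray = rng.poisson(config.stray_lick_fraction * vigor * (config.iti - 10.0))
        if n_stray:
            lick_times.append(cue + rng.uniform(10.0, config.iti, size=n_stray))
        rows.append((k, triggered, cue_licks, vigor, p))
    trials = pd.DataFrame(rows, columns=["trial", "triggered", "cue_licks",
                                         "vigor", "p_trigger"])
    licks = (np.sort(np.concatenate(lick_times)) if lick_times else np.empty(0))
    deliveries = (np.concatenate(delivery_times) if delivery_times else np.empty(0))
    return trials, licks, deliveries


def simulate_session(
    config: SimConfig,
    gp: GroupParams,
    meta: SessionMeta,
    rng: np.random.Generator,
    mouse_amp_offset: float = 0.0,
    seed_key: tuple = (),
) -> tuple[SessionRecording, SessionGroundTruth]:
    """Simulate one session for one animal.

    ``mouse_amp_offset`` is an additive per-animal shift of the response
    amplitude (the cohort-level random intercept); the per-session vigor
    jitter is drawn here from ``rng``.
    """
    vigor_scale = float(np.exp(rng.normal(0.0, config.session_vigor_jitter_sd))) \
        if config.session_vigor_jitter_sd > 0 else 1.0
    trials, licks, deliveries = _simulate_behavior(config, gp, rng, vigor_scale)
    triggered = trials["triggered"].to_numpy()

    # programmed amplitude per trial (NaN on untriggered trials): the
    # satiation ramp runs over the triggered-trial ordinal
    amps = np.full(config.n_trials, np.nan)
    trig_idx = np.flatnonzero(triggered)
    ordinals = np.arange(trig_idx.size)
    if trig_idx.size:
        frac = np.minimum(ordinals / gp.satiation_capacity, 1.0)
        amps[trig_idx] = (gp.a_early + (gp.a_late - gp.a_early) * frac
                          + mouse_amp_offset)
    trials["amplitude"] = amps

    rate = config.schedule.output_rate
    n50 = round(config.session_duration * rate)
    dff = np.zeros(n50)
    tpl = delivery_template(config, rate)
    cues = config.cue_times()
    for k in trig_idx:
        i0 = round(cues[k] * rate)
        i1 = min(i0 + tpl.size, n50)
        dff[i0:i1] += amps[k] * tpl[: i1 - i0]

    t50 = np.arange(n50) / rate
    bleach = np.exp(-t50 / config.bleach_tau)
    f465 = config.f0_base * bleach * (1.0 + dff)
    f405 = config.f0_405 * bleach

    speed_rate = 10.0
    n_speed = round(config.session_duration * speed_rate)
    w = np.hanning(21)
    smooth = np.convolve(rng.standard_normal(n_speed + 20), w / w.sum(), mode="valid")
    speed = gp.run_speed_scale * np.abs(smooth[:n_speed])

    sched = config.schedule
    if config.level == "raw":
        raw = multiplex(
            ChannelTrace(f465, rate=rate, channel="465"),
            ChannelTrace(f405, rate=rate, channel="405"),
            sched, noise_sd=config.noise_sd, rng=rng,
        )
        rec = SessionRecording(meta=meta, schedule=sched, raw_samples=raw,
                               cue_times=cues, lick_times=licks,
                               delivery_times=deliveries,
                               speed_samples=speed, speed_rate=speed_rate)
    else:
        # post-demultiplex equivalent of the raw additive noise
        n465 = sched.window_indices("465").size
        f465 = f465 + config.noise_sd * median_sd_factor(n465) \
            * rng.standard_normal(n50)
        tr405 = None
        if config.simulate_isosbestic:
            n405 = sched.window_indices("405").size
            tr405 = ChannelTrace(
                f405 + config.noise_sd * median_sd_factor(n405)
                * rng.standard_normal(n50),
                rate=rate, channel="405")
        rec = SessionRecording(meta=meta, schedule=sched,
                               trace465=ChannelTrace(f465, rate=rate, channel="465"),
                               trace405=tr405,
                               cue_times=cues, lick_times=licks,
                               delivery_times=deliveries,
                               speed_samples=speed, speed_rate=speed_rate)

    gt = SessionGroundTruth(
        session_id=meta.session_id, mouse_id=meta.mouse_id, group=meta.diet,
        seed_key=seed_key,
        trials=trials[["trial", "triggered", "amplitude", "cue_licks",
                       "vigor", "p_trigger"]].copy(),
        noiseless={},
    )
    gt.noiseless = gt.recompute_noiseless()
    return rec, gt


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Simulate all groups x mice x sessions of a cohort.

    Seeding: per-session generators are derived from the master seed with
    fixed spawn keys (group, mouse, session), so any session is reproducible
    in isolation and the cohort is deterministic as a whole.
    """
    sessions: list[SessionRecording] = []
    truths: list[SessionGroundTruth] = []
    for gi, (group, gp) in enumerate(sorted(config.group_params.items())):
        for mi in range(config.n_mice):
            mouse_id = f"{group}_m{mi:02d}"
            mouse_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(gi, mi)))
            offset = (mouse_rng.normal(0.0, config.mouse_effect_sd)
                      if config.mouse_effect_sd > 0 else 0.0)
            # body weight: lean ~25 g; obese-like groups ~30% heavier
            heavy = group.upper().startswith("HFD")
            bw = mouse_rng.normal(32.5 if heavy else 25.0, 2.0 if heavy else 1.5)
            sex = "F" if mi % 2 else "M"
            for si in range(config.sessions_per_mouse):
                key = (gi, mi, si + 1)
                rng = np.random.default_rng(
                    np.random.SeedSequence(config.seed, spawn_key=key))
                meta = SessionMeta(mouse_id=mouse_id,
                                   session_id=f"{mouse_id}_s{si:02d}",
                                   diet=group, condition=group,
                                   body_weight=float(bw), sex=sex)
                rec, gt = simulate_session(config, gp, meta, rng,
                                           mouse_amp_offset=offset, seed_key=key)
                sessions.append(rec)
                truths.append(gt)
    return SimCohort(config=config, sessions=sessions, ground_truth=truths)
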