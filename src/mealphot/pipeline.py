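"""End-to-end orchestration: simulate -> analyze -> metrics -> stats.

A single YAML-serialisable :class:`PipelineConfig` governs every stage; the
run writes session files, the ground-truth sidecar, tidy metrics tables,
statistics reports and a manifest with seeds, parameter values and SHA-256
hashes of every table, so a rerun with the same configuration can be
checked for byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .metrics import aggregate_by_mouse, cohort_metrics, heatmap_aggregate, phase_table
from .simgen import HFD_LIKE, NCD_LIKE, GroupParams, SimConfig, simulate_cohort
from .stats import ModelSpec, fit_lme, t_tests
from .trials import AnalysisParams, analyze_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "mealphot_out"
    seed: int = 0
    n_mice: int = 4
    sessions_per_mouse: int = 3
    n_trials: int = 90
    level: str = "trace"
    window: str = "peri_licking"
    min_triggered: int = 30
    n_phase: int = 15
    n_tail: int = 5
    write_sessions: bool = False  # HDF5 per session (large); tables always written
    make_plots: bool = False
    group_params: dict = field(default_factory=lambda: {"NCD": NCD_LIKE, "HFD": HFD_LIKE})
    sim_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        gp = raw.pop("group_params", None)
        cfg = cls(**raw)
        if gp:
            cfg.group_params = {k: GroupParams(**v) for k, v in gp.items()}
        return cfg

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_mice=self.n_mice, sessions_per_mouse=self.sessions_per_mouse,
            n_trials=self.n_trials, group_params=dict(self.group_params),
            level=self.level, seed=self.seed, **self.sim_overrides,
        )

    def analysis_params(self) -> AnalysisParams:
        return AnalysisParams(min_triggered=self.min_triggered)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Raises :class:`PipelineError` naming the failing stage.  A statistics
    stage with no estimable cells (e.g. every session excluded) raises with
    the documented "insufficient data" status.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": _jsonable(asdict(config)),
                      "stages": {}, "hashes": {}}

    try:
        cohort = simulate_cohort(config.sim_config())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e
    manifest["stages"]["simulate"] = {"n_sessions": len(cohort.sessions)}
    gt_path = mio.write_ground_truth_csv(cohort.ground_truth, out / "ground_truth.csv")
    manifest["hashes"]["ground_truth.csv"] = _sha256(gt_path)
    if config.write_sessions:
        sess_dir = out / "sessions"
        for rec in cohort.sessions:
            mio.write_session_h5(rec, sess_dir / f"{rec.meta.session_id}.h5")

    try:
        analyses, zstats = analyze_cohort(cohort.sessions, config.analysis_params())
    except Exception as e:  # noqa: BLE001
        raise PipelineError("analyze", str(e)) from e
    n_included = sum(sa.included for sa in analyses)
    manifest["stages"]["analyze"] = {
        "n_sessions": len(analyses), "n_included": n_included,
        "n_triggered_total": int(sum(sa.n_triggered for sa in analyses)),
        "z_stats": {m: {"mean": s.mean, "sd": s.sd, "n": s.n_samples_used}
                    for m, s in sorted(zstats.items())},
    }

    try:
        metrics = cohort_metrics(analyses, window=config.window,
                                 n_phase=config.n_phase, n_tail=config.n_tail)
        metrics.insert(0, "seed", config.seed)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("metrics", str(e)) from e
    mpath = _write_csv(metrics, out / "metrics.csv")
    manifest["hashes"]["metrics.csv"] = _sha256(mpath)
    try:
        mouse_df = aggregate_by_mouse(metrics)
        manifest["hashes"]["mouse_metrics.csv"] = _sha256(
            _write_csv(mouse_df, out / "mouse_metrics.csv"))
    except (KeyError, ValueError) as e:
        logger.warning("mouse aggregate skipped: %s", e)
    long = phase_table(metrics)
    lpath = _write_csv(long, out / "phase_table.csv")
    manifest["hashes"]["phase_table.csv"] = _sha256(lpath)

    if long.empty or long["Mouse"].nunique() < 2:
        raise PipelineError(
            "stats", "insufficient data: no estimable cells after inclusion "
            f"({n_included} included sessions)")
    report_lines = [f"# mealphot report (seed {config.seed})", ""]
    stats_rows = []
    try:
        diets = sorted(long["Diet"].unique())
        if len(diets) >= 2:
            res = fit_lme(long, ModelSpec(fixed=("Diet", "MealPhase"),
                                          reference_levels={"Diet": diets[0]}))
            stats_rows.append(_result_rows("lme_diet_x_phase", res))
            report_lines += [f"## LME: {res.formula}",
                             f"converged: {res.converged}, n={res.n_obs}, mice={res.n_groups}",
                             res.summary().to_string(index=False), ""]
        for diet in diets:
            sub = long[long["Diet"] == diet]
            piv = sub.pivot_table(index="session", columns="MealPhase", values="value")
            if {"early", "late"} <= set(piv.columns) and len(piv.dropna()) >= 2:
                piv = piv.dropna()
                res = t_tests(piv["late"], piv["early"], paired=True)
                stats_rows.append(_result_rows(f"paired_t_late_vs_early_{diet}", res))
        manifest["stages"]["stats"] = {"n_models": len(stats_rows)}
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stats", str(e)) from e
    stats_df = pd.concat(stats_rows, ignore_index=True)
    spath = _write_csv(stats_df, out / "stats.csv")
    manifest["hashes"]["stats.csv"] = _sha256(spath)

    try:
        bundle = heatmap_aggregate([sa for sa in analyses if sa.included])
        np.savez(out / "heatmaps.npz",
                 time_axis=bundle.time_axis, per_mouse=bundle.per_mouse,
                 grand_mean=bundle.grand_mean,
                 mouse_ids=np.array(bundle.mouse_ids))
        if config.make_plots:
            _plot_heatmap(bundle, out / "heatmap.png")
    except ValueError as e:
        logger.warning("heatmap stage skipped: %s", e)

    (out / "report.md").write_text("\n".join(report_lines))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d sessions, %d included -> %s",
                len(analyses), n_included, out)
    return out


def _result_rows(name: str, res) -> pd.DataFrame:
    df = res.summary()
    df.insert(0, "model", name)
    df.insert(1, "formula", res.formula)
    df["converged"] = res.converged
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def _plot_heatmap(bundle, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(2, 1, figsize=(6, 6), sharex=True,
                                   height_ratios=[1, 2])
    ax0.plot(bundle.time_axis, bundle.grand_mean, color="k")
    ax0.set_ylabel("mean Z")
    extent = [bundle.time_axis[0], bundle.time_axis[-1], 0, len(bundle.mouse_ids)]
    im = ax1.imshow(bundle.per_mouse, aspect="auto", extent=extent, origin="lower")
    ax1.set_xlabel("time from cue (s)")
    ax1.set_ylabel("mouse")
    fig.colorbar(im, ax=ax1, label="Z")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
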