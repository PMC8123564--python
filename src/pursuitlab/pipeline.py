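"""End-to-end pipeline driver: simulate -> preprocess/QC -> pursuit metrics
-> time-to-contact metrics -> within-subject statistics.

Stage order follows the analysis chain; every stage's outputs are written as
plain CSV/JSON plus a run log carrying the config hash, seed, and per-reason
exclusion counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import pursuit as pm
from . import stats as st
from . import ttc
from .config import RunConfig
from .design import (
    SessionDesign,
    StimulusGeometry,
    TrialCondition,
    VisualCondition,
    build_session,
    contact_time,
    default_conditions,
)
from .io import write_table
from .preprocess import (
    EyeTrace,
    QCResult,
    SaccadeEvent,
    average_traces,
    desaccade,
    detect_blinks,
    detect_saccades,
    differentiate_central,
    fir_lowpass,
    qc_trial,
)
from .simulate import (
    SimDataset,
    SimTrial,
    load_population_defaults,
    make_observers,
    simulate_dataset,
)

logger = logging.getLogger("pursuitlab")

__all__ = ["PreprocessedTrial", "PipelineResult", "preprocess_trial", "run_pipeline"]

PURSUIT_CONDITIONS = (
    VisualCondition.PURSUIT_FIRST_ORDER.value,
    VisualCondition.PURSUIT_SECOND_ORDER.value,
)
ERROR_DVS = ("constant_error_ms", "absolute_error_ms", "variable_error_ms")
PURSUIT_DVS = (
    "latency_ms",
    "initial_acceleration",
    "steady_state_velocity",
    "saccade_rate_hz",
)


@dataclass
class PreprocessedTrial:
    """A trial after differentiation, filtering, event detection and QC."""

    trial: SimTrial
    velocity_filt: np.ndarray
    accel_filt: np.ndarray
    velocity_desacc: np.ndarray
    accel_desacc: np.ndarray
    events: list[SaccadeEvent]
    blink_spans: list[tuple[float, float]]
    qc: QCResult

    @property
    def t(self) -> np.ndarray:
        return self.trial.trace.t


@dataclass
class PipelineResult:
    config: RunConfig
    dataset: SimDataset
    preprocessed: list[PreprocessedTrial]
    qc_table: pd.DataFrame
    events_table: pd.DataFrame
    pursuit_table: pd.DataFrame
    results_table: pd.DataFrame  # tidy per-trial TTC errors
    aggregates: pd.DataFrame
    prev_trial_table: pd.DataFrame
    stats_tables: dict[str, pd.DataFrame]
    notes: list[str] = field(default_factory=list)


def preprocess_trial(
    trial: SimTrial, geometry: StimulusGeometry, cfg: RunConfig
) -> PreprocessedTrial:
    """Differentiate -> filter -> detect saccades/blinks -> desaccade -> QC."""
    pp = cfg.preprocess
    trace = trial.trace
    v_raw = differentiate_central(trace.x, trace.dt_ms)
    v_filt = fir_lowpass(
        v_raw, pp.fir_taps, pp.fir_passband_hz, pp.fs_hz, zero_phase=pp.zero_phase
    )
    a_src = v_filt if pp.accel_from_filtered else v_raw
    a_raw = differentiate_central(a_src, trace.dt_ms)
    a_filt = fir_lowpass(
        a_raw, pp.fir_taps, pp.fir_passband_hz, pp.fs_hz, zero_phase=pp.zero_phase
    )
    events = detect_saccades(
        trace.t,
        v_filt,
        a_filt,
        position=trace.x,
        v_thr=pp.saccade_v_thr,
        a_thr=pp.saccade_a_thr,
        merge_gap_ms=pp.saccade_merge_gap_ms,
    )
    v_desacc = desaccade(trace.t, v_filt, events, pad_ms=pp.saccade_pad_ms)
    a_desacc = desaccade(trace.t, a_filt, events, pad_ms=pp.saccade_pad_ms)
    blinks = detect_blinks(trace, guard_ms=pp.blink_guard_ms)
    if pp.qc_enabled:
        qc = qc_trial(
            trace,
            events,
            blinks,
            trial.condition,
            geometry,
            excursion_limit_deg=pp.excursion_limit_deg,
            capture_radius_deg=pp.capture_radius_deg,
            excursion_mode=pp.excursion_mode,
        )
    else:
        qc = QCResult(keep=True)
    return PreprocessedTrial(
        trial=trial,
        velocity_filt=v_filt,
        accel_filt=a_filt,
        velocity_desacc=v_desacc,
        accel_desacc=a_desacc,
        events=events,
        blink_spans=blinks,
        qc=qc,
    )


def _common_grid_slice(
    trace: EyeTrace, t_lo: float, t_hi: float
) -> np.ndarray | None:
    """Index slice of a trace onto the common grid [t_lo, t_hi] (1-ms)."""
    i0 = int(round(t_lo - trace.t[0]))
    i1 = int(round(t_hi - trace.t[0])) + 1
    if i0 < 0 or i1 > len(trace.t):
        return None
    return np.arange(i0, i1)


def compute_cell_pursuit_metrics(
    trials: list[PreprocessedTrial],
    condition: TrialCondition,
    geometry: StimulusGeometry,
    cfg: RunConfig,
) -> pm.PursuitMetrics:
    """Pursuit metrics of one (observer, condition, velocity) cell.

    Onset is detected on the per-cell averaged desaccaded velocity trace
    (the default) or per trial, governed by ``cfg.metrics.onset_mode``.
    """
    mc = cfg.metrics
    t_lo = float(mc.baseline_window_ms[0]) - 100.0
    t_hi = contact_time(geometry, condition.velocity)
    grid = np.arange(t_lo, t_hi + 1.0)

    v_stack, a_stack = [], []
    n_events_present = 0
    for ptr in trials:
        sl = _common_grid_slice(ptr.trial.trace, t_lo, t_hi)
        if sl is None:
            continue
        v_stack.append(ptr.velocity_desacc[sl])
        a_stack.append(ptr.accel_desacc[sl])
        n_events_present += sum(
            1 for ev in ptr.events if 0 <= ev.onset_ms <= geometry.presentation_ms
        )
    if not v_stack:
        raise ValueError("no usable trials in cell")

    rate = pm.saccade_rate(
        n_events_present, len(v_stack) * geometry.presentation_ms
    )
    direction = condition.motion_direction

    def _one(v: np.ndarray, a: np.ndarray) -> tuple:
        base = pm.pretrial_baseline(grid, v, tuple(mc.baseline_window_ms))
        onset = pm.pursuit_onset(
            grid,
            v,
            base,
            direction=direction,
            sustain_ms=mc.sustain_ms,
            threshold_floor=mc.onset_threshold_floor,
        )
        lat = pm.latency(onset)
        accel = (
            pm.initial_acceleration(grid, a, onset, mc.accel_window_ms) * direction
            if onset is not None
            else None
        )
        ssv = pm.steady_state_velocity(grid, v * direction, tuple(mc.steady_window_ms))
        return base, onset, lat, accel, ssv

    if mc.onset_mode == "per_trial":
        rows = [_one(v, a) for v, a in zip(v_stack, a_stack)]
        lats = [r[2] for r in rows if r[2] is not None]
        accs = [r[3] for r in rows if r[3] is not None]
        ssvs = [r[4] for r in rows if r[4] is not None]
        base_means = [r[0].mean for r in rows]
        base_sds = [r[0].sd for r in rows]
        onset = float(np.mean(lats)) if lats else None
        return pm.PursuitMetrics(
            onset_ms=onset,
            latency_ms=onset,
            initial_acceleration=float(np.mean(accs)) if accs else None,
            steady_state_velocity=float(np.mean(ssvs)) if ssvs else None,
            saccade_rate_hz=rate,
            baseline_mean=float(np.mean(base_means)),
            baseline_sd=float(np.mean(base_sds)),
            n_trials=len(v_stack),
        )

    v_mean, _, _ = average_traces(v_stack, min_count=cfg.metrics.min_trace_count)
    a_mean, _, _ = average_traces(a_stack, min_count=cfg.metrics.min_trace_count)
    base, onset, lat, accel, ssv = _one(v_mean, a_mean)
    return pm.PursuitMetrics(
        onset_ms=onset,
        latency_ms=lat,
        initial_acceleration=accel,
        steady_state_velocity=ssv,
        saccade_rate_hz=rate,
        baseline_mean=base.mean,
        baseline_sd=base.sd,
        n_trials=len(v_stack),
    )


def _safe_rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    cfg: RunConfig,
    notes: list[str],
    label: str,
) -> pd.DataFrame | None:
    sub = data.dropna(subset=[dv])
    try:
        out = st.rm_anova_2way(
            sub, dv, within, subject="observer_id", gg_correction=cfg.stats.gg_correction
        )
    except ValueError as exc:
        notes.append(f"skipped ANOVA [{label}] on {dv}: {exc}")
        return None
    out.insert(0, "dv", dv)
    return out


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Execute the full pipeline on a simulated dataset.

    Deterministic for a fixed config + seed.  Returns all intermediate and
    final tables; use :func:`write_results` to persist them.
    """
    cfg = config or RunConfig()
    notes: list[str] = []
    geometry = StimulusGeometry(
        separation=cfg.geometry.separation_deg,
        eccentricity=cfg.geometry.eccentricity_deg,
        window_sd=cfg.geometry.window_sd_deg,
        dot_density=cfg.geometry.dot_density,
        presentation_ms=cfg.geometry.presentation_ms,
    )

    # --- simulate -----------------------------------------------------------
    pop = load_population_defaults()
    pop.update(cfg.simulator.population_overrides)
    observers = make_observers(
        cfg.simulator.n_observers,
        seed=cfg.seed,
        population=pop,
        jitter=cfg.simulator.jitter_observers,
    )
    conditions = default_conditions(cfg.session.velocities)
    rng = np.random.SeedSequence(cfg.seed)
    design_seeds = rng.generate_state(1)
    design = build_session(
        n_per_cell=cfg.session.n_per_cell,
        n_blocks=cfg.session.n_blocks,
        conditions=conditions,
        seed=int(design_seeds[0]),
        pretrial_range_ms=tuple(cfg.session.pretrial_range_ms),
    )
    dataset = simulate_dataset(observers, design, seed=cfg.seed, geometry=geometry)
    logger.info("simulated %d trials (%d observers)", len(dataset), len(observers))

    # --- preprocess + QC ----------------------------------------------------
    preprocessed = [preprocess_trial(tr, geometry, cfg) for tr in dataset.trials]
    reason_counts: Counter[str] = Counter()
    qc_rows, event_rows = [], []
    for ptr in preprocessed:
        tr = ptr.trial
        reason_counts.update(ptr.qc.reasons)
        qc_rows.append(
            {
                "observer_id": tr.observer_id,
                "trial_id": tr.record.trial_id,
                "keep": ptr.qc.keep,
                "reasons": ";".join(sorted(ptr.qc.reasons)),
            }
        )
        for ev in ptr.events:
            event_rows.append(
                {
                    "observer_id": tr.observer_id,
                    "trial_id": tr.record.trial_id,
                    "onset_ms": ev.onset_ms,
                    "offset_ms": ev.offset_ms,
                    "trigger": ev.trigger.value,
                    "peak_velocity": ev.peak_velocity,
                    "landing_deg": ev.landing_position,
                }
            )
    qc_table = pd.DataFrame(qc_rows)
    events_table = pd.DataFrame(
        event_rows,
        columns=[
            "observer_id",
            "trial_id",
            "onset_ms",
            "offset_ms",
            "trigger",
            "peak_velocity",
            "landing_deg",
        ],
    )
    n_kept = int(qc_table["keep"].sum())
    logger.info(
        "QC: %d/%d trials kept (%.1f%%); exclusions by reason: %s",
        n_kept,
        len(qc_table),
        100.0 * n_kept / len(qc_table),
        dict(reason_counts),
    )

    # --- pursuit metrics ----------------------------------------------------
    kept = [p for p in preprocessed if p.qc.keep]
    pursuit_rows = []
    for obs in sorted({p.trial.observer_id for p in preprocessed}):
        for cond in conditions:
            if not cond.visual_condition.is_pursuit:
                continue
            cell = [
                p
                for p in kept
                if p.trial.observer_id == obs and p.trial.condition == cond
            ]
            if not cell:
                notes.append(f"empty pursuit cell: {obs} {cond.label}")
                continue
            m = compute_cell_pursuit_metrics(cell, cond, geometry, cfg)
            pursuit_rows.append(
                {
                    "observer_id": obs,
                    "visual_condition": cond.visual_condition.value,
                    "velocity": cond.velocity,
                    "latency_ms": m.latency_ms,
                    "initial_acceleration": m.initial_acceleration,
                    "steady_state_velocity": m.steady_state_velocity,
                    "saccade_rate_hz": m.saccade_rate_hz,
                    "baseline_mean": m.baseline_mean,
                    "baseline_sd": m.baseline_sd,
                    "n_trials": m.n_trials,
                }
            )
    pursuit_table = pd.DataFrame(pursuit_rows)

    # --- TTC metrics --------------------------------------------------------
    res_rows = []
    for ptr in preprocessed:
        tr = ptr.trial
        cond = tr.condition
        c_ms = contact_time(geometry, cond.velocity)
        ce = ttc.constant_error(tr.response_ms, c_ms)
        res_rows.append(
            {
                "observer_id": tr.observer_id,
                "visual_condition": cond.visual_condition.value,
                "velocity": cond.velocity,
                "trial_id": tr.record.trial_id,
                "block": tr.record.block,
                "keep": ptr.qc.keep,
                "response_ms": tr.response_ms,
                "contact_ms": c_ms,
                "constant_error_ms": ce,
                "absolute_error_ms": abs(ce),
                "reaction_time_ms": ttc.reaction_time(
                    tr.response_ms, geometry.occlusion_onset_ms
                ),
            }
        )
    results_table = pd.DataFrame(res_rows)
    kept_results = results_table[results_table["keep"]]
    aggregates = ttc.aggregate_errors(kept_results)
    # pooled-over-velocity variable error per condition (secondary variant)
    pooled = ttc.aggregate_errors(
        kept_results, group_cols=("observer_id", "visual_condition")
    ).rename(columns={"variable_error_ms": "variable_error_pooled_ms"})
    prev_table = ttc.previous_trial_table(results_table)
    prev_kept = prev_table[prev_table["keep"]]

    # --- statistics ---------------------------------------------------------
    stats_tables: dict[str, pd.DataFrame] = {}

    cells = aggregates.copy()
    fix_first = cells[
        cells["visual_condition"].isin(
            [VisualCondition.FIXATION.value, VisualCondition.PURSUIT_FIRST_ORDER.value]
        )
    ]
    first_second = cells[cells["visual_condition"].isin(PURSUIT_CONDITIONS)]

    frames = []
    for dv in ERROR_DVS:
        out = _safe_rm_anova(
            fix_first, dv, ("visual_condition", "velocity"), cfg, notes,
            "fixation vs pursuit-first-order",
        )
        if out is not None:
            frames.append(out)
    if frames:
        stats_tables["anova_fixation_vs_pursuit"] = pd.concat(frames, ignore_index=True)

    frames = []
    for dv in ERROR_DVS:
        out = _safe_rm_anova(
            first_second, dv, ("visual_condition", "velocity"), cfg, notes,
            "first vs second order",
        )
        if out is not None:
            frames.append(out)
    for dv in PURSUIT_DVS:
        out = _safe_rm_anova(
            pursuit_table, dv, ("visual_condition", "velocity"), cfg, notes,
            "first vs second order (pursuit)",
        )
        if out is not None:
            frames.append(out)
    if frames:
        stats_tables["anova_first_vs_second"] = pd.concat(frames, ignore_index=True)

    rt_cells = (
        kept_results.groupby(["observer_id", "visual_condition", "velocity"], observed=True)[
            "reaction_time_ms"
        ]
        .mean()
        .reset_index()
    )
    out = _safe_rm_anova(
        rt_cells, "reaction_time_ms", ("visual_condition", "velocity"), cfg, notes,
        "reaction time 3x3",
    )
    if out is not None:
        stats_tables["anova_reaction_time"] = out
        stats_tables["pairwise_rt_velocity"] = st.bonferroni_pairwise(
            rt_cells, "reaction_time_ms", "velocity", subject="observer_id"
        )

    # previous-trial (n-1) two-way ANOVA per condition
    frames = []
    for cond_name, g in prev_kept.groupby("visual_condition", observed=True):
        cell_means = (
            g.groupby(["observer_id", "velocity", "prev_velocity"], observed=True)[
                "constant_error_ms"
            ]
            .mean()
            .reset_index()
        )
        out = _safe_rm_anova(
            cell_means, "constant_error_ms", ("velocity", "prev_velocity"), cfg, notes,
            f"n-1 analysis [{cond_name}]",
        )
        if out is not None:
            out.insert(0, "visual_condition", cond_name)
            frames.append(out)
    if frames:
        stats_tables["anova_prev_trial"] = pd.concat(frames, ignore_index=True)

    # within-subjects correlations: pursuit response vs TTC errors, per velocity
    merged = pursuit_table.merge(
        first_second, on=["observer_id", "visual_condition", "velocity"], how="inner"
    )
    ws_rows = []
    for vel, g in merged.groupby("velocity", observed=True):
        for xvar in PURSUIT_DVS:
            for yvar in ERROR_DVS:
                sub = g.dropna(subset=[xvar, yvar])
                try:
                    res = st.within_subject_corr(
                        sub[xvar], sub[yvar], sub["observer_id"]
                    )
                except ValueError as exc:
                    notes.append(f"skipped ws-corr {xvar}~{yvar}@{vel}: {exc}")
                    continue
                ws_rows.append(
                    {
                        "velocity": vel,
                        "x": xvar,
                        "y": yvar,
                        "r": res.r,
                        "df": res.df,
                        "p": res.p,
                        "n": res.n,
                    }
                )
    if ws_rows:
        stats_tables["within_subject_corr"] = pd.DataFrame(ws_rows)
    stats_tables["aggregates_pooled"] = pooled

    return PipelineResult(
        config=cfg,
        dataset=dataset,
        preprocessed=preprocessed,
        qc_table=qc_table,
        events_table=events_table,
        pursuit_table=pursuit_table,
        results_table=results_table,
        aggregates=aggregates,
        prev_trial_table=prev_table,
        stats_tables=stats_tables,
        notes=notes,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Persist every pipeline table plus config and a plain-text run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(outdir / "config.yaml")
    write_table(result.qc_table, outdir / "qc.csv")
    write_table(result.events_table, outdir / "events.csv")
    write_table(result.pursuit_table, outdir / "metrics.csv")
    write_table(result.results_table, outdir / "results.csv")
    write_table(result.aggregates, outdir / "aggregates.csv")
    write_table(result.prev_trial_table, outdir / "prev_trial.csv")
    for name, df in result.stats_tables.items():
        write_table(df, outdir / f"stats_{name}.csv")
    stats_json = {
        name: df.to_dict(orient="records") for name, df in result.stats_tables.items()
    }
    (outdir / "stats.json").write_text(json.dumps(stats_json, indent=2, default=str))
    if cfg.write_traces:
        from .io import write_dataset

        write_dataset(result.dataset, outdir / "dataset", traces=True)

    n = len(result.qc_table)
    n_kept = int(result.qc_table["keep"].sum())
    reasons = Counter()
    for r in result.qc_table["reasons"]:
        if r:
            reasons.update(r.split(";"))
    lines = [
        f"config_hash: {cfg.config_hash()}",
        f"seed: {cfg.seed}",
        f"trials_total: {n}",
        f"trials_used: {n_kept} ({100.0 * n_kept / n:.1f}%)",
        "exclusions_by_reason: "
        + json.dumps(dict(sorted(reasons.items())), sort_keys=True),
    ]
    lines += [f"note: {note}" for note in result.notes]
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
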