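"""Pursuit metrics: pretrial baseline, onset/latency, initial acceleration,
steady-state velocity, and saccade rate."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import SaccadeEvent

__all__ = [
    "Baseline",
    "PursuitMetrics",
    "pretrial_baseline",
    "pursuit_onset",
    "latency",
    "initial_acceleration",
    "steady_state_velocity",
    "saccade_rate",
]


@dataclass(frozen=True)
class Baseline:
    mean: float  # deg/s
    sd: float  # deg/s

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("baseline sd must be non-negative")


@dataclass(frozen=True)
class PursuitMetrics:
    """Per-cell pursuit summary (None = not measurable)."""

    onset_ms: float | None
    latency_ms: float | None
    initial_acceleration: float | None  # deg/s^2
    steady_state_velocity: float | None  # deg/s
    saccade_rate_hz: float
    baseline_mean: float
    baseline_sd: float
    n_trials: int = 0


def pretrial_baseline(
    t: np.ndarray,
    velocity: np.ndarray,
    window_ms: tuple[float, float] = (-300.0, 0.0),
) -> Baseline:
    """NaN-aware mean and SD of eye velocity in the pretrial window.

    The default [-300, 0] ms window length is an analysis choice, not a
    recorded fact.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(velocity, dtype=float)
    lo, hi = window_ms
    sel = v[(t >= lo) & (t < hi)]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        raise ValueError("baseline window contains no valid samples")
    sd = float(np.std(sel, ddof=1)) if sel.size > 1 else 0.0
    return Baseline(mean=float(np.mean(sel)), sd=sd)


def pursuit_onset(
    t: np.ndarray,
    velocity: np.ndarray,
    baseline: Baseline,
    direction: int = +1,
    sustain_ms: float = 20.0,
    threshold_floor: float = 0.05,
) -> float | None:
    """Earliest t >= 0 where directed velocity exceeds baseline + 3 SD.

    The crossing must hold continuously for ``sustain_ms`` to suppress
    single-sample noise.  Velocity is signed into the motion direction so
    leftward and rightward stimuli share one code path.  A degenerate
    baseline (mean and SD both ~0) is handled by flooring the threshold at
    ``threshold_floor`` deg/s.  Returns None when never satisfied.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(velocity, dtype=float) * direction
    thr = max(baseline.mean * direction + 3.0 * baseline.sd, threshold_floor)
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    need = max(int(round(sustain_ms / dt)), 1)
    post = t >= 0
    tv = t[post]
    with np.errstate(invalid="ignore"):
        above = (v[post] > thr) & np.isfinite(v[post])
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= need:
            return float(tv[i - need + 1])
    return None


def latency(onset_ms: float | None, motion_onset_ms: float = 0.0) -> float | None:
    """Time from motion onset to pursuit onset; None when onset is absent."""
    if onset_ms is None:
        return None
    return float(onset_ms - motion_onset_ms)


def initial_acceleration(
    t: np.ndarray,
    acceleration: np.ndarray,
    onset_ms: float,
    window_ms: float = 100.0,
) -> float | None:
    """NaN-aware mean acceleration over the first ``window_ms`` of pursuit.

    Warns (low confidence) when more than half the window is NaN; returns
    None when the whole window is NaN.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(acceleration, dtype=float)
    sel = a[(t >= onset_ms) & (t < onset_ms + window_ms)]
    if sel.size == 0:
        raise ValueError("acceleration window lies outside the trace")
    n_ok = int(np.sum(np.isfinite(sel)))
    if n_ok == 0:
        return None
    if n_ok < sel.size / 2:
        warnings.warn(
            "initial_acceleration: >50% of the window is NaN (low confidence)",
            stacklevel=2,
        )
    return float(np.nanmean(sel))


def steady_state_velocity(
    t: np.ndarray,
    velocity: np.ndarray,
    window_ms: tuple[float, float] = (300.0, 500.0),
) -> float | None:
    """NaN-aware mean desaccaded velocity over the steady-state window.

    The default [300, 500] ms window is an analysis choice.  Returns None
    when the window is fully NaN.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(velocity, dtype=float)
    lo, hi = window_ms
    sel = v[(t >= lo) & (t <= hi)]
    sel = sel[np.isfinite(sel)]
    if sel.size == 0:
        return None
    return float(np.mean(sel))


def saccade_rate(
    events: Sequence[SaccadeEvent] | int,
    total_duration_ms: float,
    window_ms: tuple[float, float] | None = None,
) -> float:
    """Saccade frequency (events/s) over the summed analysed duration.

    ``events`` may be a pre-filtered count or a list of events; with
    ``window_ms`` only events whose onset falls inside the window (e.g. the
    presentation period) are counted.
    """
    if total_duration_ms <= 0:
        raise ValueError("total duration must be positive")
    if isinstance(events, int):
        n = events
    elif window_ms is not None:
        lo, hi = window_ms
        n = sum(1 for ev in events if lo <= ev.onset_ms <= hi)
    else:
        n = len(events)
    return n / (total_duration_ms / 1000.0)
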