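"""Eye-trace preprocessing: differentiation, FIR filtering, saccade and
blink detection, desaccading, trial quality control, and trace averaging.

Stage order mirrors the analysis chain: differentiate -> filter velocity ->
differentiate again -> filter acceleration -> detect events -> desaccade ->
average.  Position itself is never filtered before differentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .design import StimulusGeometry, TrialCondition

__all__ = [
    "EyeTrace",
    "SaccadeTrigger",
    "SaccadeEvent",
    "QCResult",
    "differentiate_central",
    "fir_lowpass",
    "design_fir",
    "detect_saccades",
    "desaccade",
    "detect_blinks",
    "qc_trial",
    "average_traces",
]


@dataclass
class EyeTrace:
    """A 1-kHz eye-position recording aligned on motion onset (t = 0 ms).

    ``x``/``y`` are NaN wherever ``valid`` is False (tracker signal loss).
    """

    t: np.ndarray  # ms, uniform 1-ms grid
    x: np.ndarray  # deg, horizontal (analysis channel)
    y: np.ndarray  # deg, vertical
    valid: np.ndarray  # bool per sample

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n >= 2:
            dts = np.diff(self.t)
            if not np.allclose(dts, dts[0]):
                raise ValueError("non-uniform sampling grid")
        if np.any(~np.isfinite(self.x[self.valid])):
            raise ValueError("x must be finite wherever valid")

    @property
    def dt_ms(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 1.0

    def index_of(self, t_ms: float) -> int:
        return int(np.searchsorted(self.t, t_ms))


class SaccadeTrigger(str, Enum):
    VELOCITY = "velocity"
    ACCELERATION = "acceleration"
    BOTH = "both"


@dataclass(frozen=True)
class SaccadeEvent:
    """A detected saccadic interval."""

    onset_ms: float
    offset_ms: float
    trigger: SaccadeTrigger
    peak_velocity: float  # deg/s, unsigned
    landing_position: float  # deg, x at offset (NaN if unknown)

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")


@dataclass(frozen=True)
class QCResult:
    """Trial inclusion decision; ``keep`` iff no exclusion reasons."""

    keep: bool
    reasons: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.keep != (len(self.reasons) == 0):
            raise ValueError("keep must be equivalent to empty reasons")


def differentiate_central(series: np.ndarray, dt_ms: float = 1.0) -> np.ndarray:
    """Central-difference derivative, converting deg/ms to deg/s.

    Interior samples use ``(x[i+1] - x[i-1]) / (2 dt)``; endpoints fall back
    to one-sided differences.  NaN inputs propagate to NaN outputs.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series, dt_ms / 1000.0)


def design_fir(
    n_taps: int = 80, passband_hz: float = 30.0, fs_hz: float = 1000.0
) -> np.ndarray:
    """Linear-phase FIR low-pass taps (unit DC gain)."""
    return signal.firwin(n_taps, passband_hz, fs=fs_hz)


def _valid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) half-open index runs where mask is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def fir_lowpass(
    series: np.ndarray,
    n_taps: int = 80,
    passband_hz: float = 30.0,
    fs_hz: float = 1000.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Apply the FIR low-pass to each finite run of ``series``.

    NaN spans are left untouched and never leak into filtering windows: each
    contiguous finite segment is filtered independently.  With
    ``zero_phase`` (default) the filter runs forward-backward so event times
    are not lag-shifted; otherwise a single symmetric-window pass is used.
    Segments shorter than the filter length are passed through unfiltered.
    """
    series = np.asarray(series, dtype=float)
    if series.size <= n_taps:
        raise ValueError(f"series must be longer than {n_taps} samples")
    taps = design_fir(n_taps, passband_hz, fs_hz)
    out = series.copy()
    for start, stop in _valid_runs(np.isfinite(series)):
        seg = series[start:stop]
        if len(seg) <= n_taps:
            continue
        if zero_phase:
            padlen = min(3 * n_taps, len(seg) - 1)
            out[start:stop] = signal.filtfilt(taps, [1.0], seg, padlen=padlen)
        else:
            # symmetric 'same' convolution with edge padding; the even tap
            # count leaves a half-sample delay that zero_phase mode avoids
            padded = np.pad(seg, n_taps, mode="edge")
            full = np.convolve(padded, taps, mode="same")
            out[start:stop] = full[n_taps : n_taps + len(seg)]
    return out


def detect_saccades(
    t: np.ndarray,
    velocity: np.ndarray,
    acceleration: np.ndarray,
    position: np.ndarray | None = None,
    v_thr: float = 30.0,
    a_thr: float = 1000.0,
    merge_gap_ms: float = 20.0,
) -> list[SaccadeEvent]:
    """Threshold saccade detector.

    An event is a maximal run of samples where ``|v| >= v_thr`` OR
    ``|a| >= a_thr``; runs separated by less than ``merge_gap_ms`` are fused.
    NaN samples never trigger.  ``landing_position`` is the position at event
    offset when ``position`` is supplied.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(acceleration, dtype=float)
    with np.errstate(invalid="ignore"):
        over_v = np.abs(v) >= v_thr
        over_a = np.abs(a) >= a_thr
    mask = over_v | over_a
    runs = _valid_runs(mask)
    if not runs:
        return []
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if (start - merged[-1][1]) * dt < merge_gap_ms:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    events = []
    for start, stop in merged:
        sl = slice(start, stop)
        has_v = bool(np.any(over_v[sl]))
        has_a = bool(np.any(over_a[sl]))
        if has_v and has_a:
            trigger = SaccadeTrigger.BOTH
        elif has_v:
            trigger = SaccadeTrigger.VELOCITY
        else:
            trigger = SaccadeTrigger.ACCELERATION
        peak = float(np.nanmax(np.abs(v[sl]))) if np.any(np.isfinite(v[sl])) else 0.0
        landing = float(position[stop - 1]) if position is not None else float("nan")
        # offset is exclusive: the first sample after the event
        events.append(
            SaccadeEvent(
                onset_ms=float(t[start]),
                offset_ms=float(t[start]) + (stop - start) * dt,
                trigger=trigger,
                peak_velocity=peak,
                landing_position=landing,
            )
        )
    return events


def desaccade(
    t: np.ndarray,
    series: np.ndarray,
    events: Iterable[SaccadeEvent],
    pad_ms: float = 10.0,
) -> np.ndarray:
    """Replace samples inside padded event spans with NaN.

    Samples with ``onset - pad <= t <= offset + pad`` become NaN; everything
    else is returned unchanged.
    """
    t = np.asarray(t, dtype=float)
    out = np.asarray(series, dtype=float).copy()
    for ev in events:
        out[(t >= ev.onset_ms - pad_ms) & (t <= ev.offset_ms + pad_ms)] = np.nan
    return out


def detect_blinks(
    trace: EyeTrace, guard_ms: float = 20.0
) -> list[tuple[float, float]]:
    """Spans (ms) where the validity mask is False, dilated by ``guard_ms``.

    Spans whose guard margins touch are merged.
    """
    invalid = ~trace.valid
    spans = []
    for start, stop in _valid_runs(invalid):
        lo = float(trace.t[start]) - guard_ms
        hi = float(trace.t[stop - 1]) + guard_ms
        if spans and lo <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], hi))
        else:
            spans.append((lo, hi))
    return spans


def qc_trial(
    trace: EyeTrace,
    events: Sequence[SaccadeEvent],
    blink_spans: Sequence[tuple[float, float]],
    condition: TrialCondition,
    geometry: StimulusGeometry | None = None,
    excursion_limit_deg: float = 2.0,
    capture_radius_deg: float = 1.5,
    excursion_mode: str = "x",
) -> QCResult:
    """Apply the trial-exclusion rules over the presentation period.

    * fixation trials: excluded if the eye strays more than
      ``excursion_limit_deg`` from the gazed object;
    * pursuit trials: excluded if a saccade starting in the presentation
      period lands within ``capture_radius_deg`` of the stationary object
      while moving toward it;
    * any condition: excluded if a blink span intersects the presentation.

    ``excursion_mode``: ``"x"`` checks the horizontal channel only,
    ``"euclidean"`` uses the 2-D distance from the gazed object.
    """
    geometry = geometry or StimulusGeometry()
    reasons: set[str] = set()
    present = (trace.t >= 0) & (trace.t <= geometry.presentation_ms)
    gazed = -geometry.eccentricity

    if condition.visual_condition.is_pursuit:
        stationary = +geometry.eccentricity
        for ev in events:
            if not 0 <= ev.onset_ms <= geometry.presentation_ms:
                continue
            if not np.isfinite(ev.landing_position):
                continue
            onset_idx = trace.index_of(ev.onset_ms)
            start_pos = trace.x[min(onset_idx, len(trace.x) - 1)]
            toward = (ev.landing_position - start_pos) * (stationary - start_pos) > 0
            if abs(ev.landing_position - stationary) <= capture_radius_deg and toward:
                reasons.add("saccade_to_target")
    else:
        dx = trace.x[present] - gazed
        if excursion_mode == "euclidean":
            exc = np.hypot(dx, trace.y[present])
        else:
            exc = np.abs(dx)
        if np.any(exc[np.isfinite(exc)] > excursion_limit_deg):
            reasons.add("fixation_excursion")

    for lo, hi in blink_spans:
        if lo <= geometry.presentation_ms and hi >= 0:
            reasons.add("blink")
            break

    return QCResult(keep=not reasons, reasons=frozenset(reasons))


def average_traces(
    traces: Sequence[np.ndarray], min_count: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample NaN-aware mean, SD (ddof=1) and contributing count.

    Traces must share one grid aligned at motion onset.  Samples with fewer
    than ``min_count`` contributing trials are NaN in the mean and SD.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    stack = np.vstack([np.asarray(tr, dtype=float) for tr in traces])
    count = np.sum(np.isfinite(stack), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    mean[count < min_count] = np.nan
    sd[count < max(min_count, 2)] = np.nan
    return mean, sd, count
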