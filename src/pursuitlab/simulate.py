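"""Ground-truth-annotated synthetic eye traces and button responses.

Every downstream stage (preprocessing, pursuit metrics, time-to-contact
metrics, statistics) is testable against the generating parameters stored in
each trial's ``truth`` record.

Behavioural model per pursuit trial:

* pretrial: low-amplitude smooth positional noise around the gazed object;
* pursuit onset after a Gaussian latency draw, then constant acceleration up
  to ``gain * target_velocity``, held through the presentation and decaying
  exponentially after occlusion;
* catch-up saccades at Poisson times, injected as 30-ms minimum-jerk
  position steps toward the instantaneous tracking error;
* blinks as NaN spans of 100-300 ms.

The button response follows a perceived-speed extrapolation with
multiplicative (scalar) timing noise and additive motor noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .design import (
    SessionDesign,
    StimulusGeometry,
    TrialCondition,
    TrialRecord,
    VisualCondition,
    contact_time,
)
from .preprocess import EyeTrace

__all__ = [
    "SimObserver",
    "SimTrial",
    "SimDataset",
    "load_population_defaults",
    "make_observers",
    "simulate_eye_trace",
    "simulate_response",
    "simulate_dataset",
    "expected_response_ms",
]

SACCADE_DURATION_MS = 30
POST_CONTACT_PAD_MS = 300.0  # trace continues this long past contact time


@dataclass(frozen=True)
class SimObserver:
    """Generating parameters for one simulated observer.

    Per-condition parameters are keyed by :class:`VisualCondition` value
    strings; per-(condition, velocity) parameters by nested float keys.
    """

    observer_id: str
    latency_mean_ms: Mapping[str, float]
    latency_sd_ms: Mapping[str, float]
    accel_mean: Mapping[str, float]
    pursuit_gain: Mapping[str, Mapping[float, float]]
    saccade_rate_hz: Mapping[str, float]
    blink_prob: float
    fixation_noise_sd_deg: float
    perceptual_gain: Mapping[str, Mapping[float, float]]
    timing_cv: float
    motor_sd_ms: float
    decay_tau_ms: float = 200.0
    noise_cutoff_hz: float = 8.0
    min_saccade_amp_deg: float = 0.8

    def __post_init__(self) -> None:
        if self.timing_cv < 0 or self.motor_sd_ms < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.blink_prob < 0 or self.blink_prob > 1:
            raise ValueError("blink_prob must be a probability")
        for cond, gains in self.pursuit_gain.items():
            for v, g in gains.items():
                if not 0 < g <= 1.2:
                    raise ValueError(f"pursuit_gain[{cond}][{v}]={g} out of (0, 1.2]")
        for cond, gains in self.perceptual_gain.items():
            for v, g in gains.items():
                if g <= 0:
                    raise ValueError("perceptual gain must be positive")

    def gain(self, condition: TrialCondition) -> float:
        return float(
            self.pursuit_gain[condition.visual_condition.value][condition.velocity]
        )

    def gamma(self, condition: TrialCondition) -> float:
        return float(
            self.perceptual_gain[condition.visual_condition.value][condition.velocity]
        )


@dataclass
class SimTrial:
    """One simulated trial: schedule, trace, response and ground truth."""

    observer_id: str
    record: TrialRecord
    trace: EyeTrace
    response_ms: float
    truth: dict

    @property
    def condition(self) -> TrialCondition:
        return self.record.condition


@dataclass
class SimDataset:
    """A collection of simulated trials with its generating design."""

    trials: list[SimTrial]
    geometry: StimulusGeometry
    observers: list[SimObserver]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def by_observer(self) -> dict[str, list[SimTrial]]:
        out: dict[str, list[SimTrial]] = {}
        for tr in self.trials:
            out.setdefault(tr.observer_id, []).append(tr)
        return out


def _float_keys(d: Mapping) -> dict:
    return {float(k): float(v) for k, v in d.items()}


def load_population_defaults() -> dict:
    """Load the versioned default parameter file shipped with the package."""
    text = (
        importlib.resources.files("pursuitlab")
        .joinpath("data/observer_defaults.yaml")
        .read_text()
    )
    cfg = yaml.safe_load(text)
    for key in ("pursuit_gain", "perceptual_gain"):
        cfg[key] = {c: _float_keys(g) for c, g in cfg[key].items()}
    return cfg


def make_observers(
    n: int = 12,
    seed: int | None = None,
    population: dict | None = None,
    jitter: bool = True,
) -> list[SimObserver]:
    """Build ``n`` observers around the population defaults.

    With ``jitter`` each observer's latency means, acceleration, pursuit
    gains, perceptual gains and timing CV are perturbed by the
    ``between_subject`` SDs, giving realistic between-subject variance for
    the within-subject statistics.
    """
    pop = population or load_population_defaults()
    rng = np.random.default_rng(seed)
    bs = pop.get("between_subject", {})
    observers = []
    for i in range(n):
        def j(x: float, key: str) -> float:
            return float(x + rng.normal(0.0, bs.get(key, 0.0))) if jitter else float(x)

        latency = {c: j(v, "latency_mean_ms") for c, v in pop["latency_mean_ms"].items()}
        accel = {c: max(j(v, "accel_mean"), 5.0) for c, v in pop["accel_mean"].items()}
        pgain = {
            c: {vel: float(np.clip(j(g, "pursuit_gain"), 0.3, 1.2)) for vel, g in gains.items()}
            for c, gains in pop["pursuit_gain"].items()
        }
        ggain = {
            c: {vel: max(j(g, "perceptual_gain"), 0.2) for vel, g in gains.items()}
            for c, gains in pop["perceptual_gain"].items()
        }
        observers.append(
            SimObserver(
                observer_id=f"obs{i + 1:02d}",
                latency_mean_ms={c: max(v, 60.0) for c, v in latency.items()},
                latency_sd_ms=dict(pop["latency_sd_ms"]),
                accel_mean=accel,
                pursuit_gain=pgain,
                saccade_rate_hz=dict(pop["saccade_rate_hz"]),
                blink_prob=float(pop["blink_prob"]),
                fixation_noise_sd_deg=float(pop["fixation_noise_sd_deg"]),
                perceptual_gain=ggain,
                timing_cv=max(j(pop["timing_cv"], "timing_cv"), 0.0),
                motor_sd_ms=float(pop["motor_sd_ms"]),
                decay_tau_ms=float(pop.get("decay_tau_ms", 200.0)),
                noise_cutoff_hz=float(pop.get("noise_cutoff_hz", 8.0)),
                min_saccade_amp_deg=float(pop.get("min_saccade_amp_deg", 0.8)),
            )
        )
    return observers


def _minimum_jerk(n: int) -> np.ndarray:
    """Unit minimum-jerk displacement profile over n samples (0 -> 1)."""
    tau = np.linspace(0.0, 1.0, n)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _smooth_noise(
    rng: np.random.Generator, n: int, sd: float, cutoff_hz: float, fs: float = 1000.0
) -> np.ndarray:
    """Band-limited Gaussian positional noise with the requested sample SD."""
    if sd <= 0 or n < 30:
        return np.zeros(n)
    from scipy import signal as sps

    white = rng.standard_normal(n + 400)
    b, a = sps.butter(2, cutoff_hz, fs=fs)
    smooth = sps.filtfilt(b, a, white)[200:-200]
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def _target_position_x(
    t_ms: np.ndarray, condition: TrialCondition, geometry: StimulusGeometry
) -> np.ndarray:
    """Screen x of the moving object (valid for t in the presentation)."""
    d = condition.motion_direction
    start = -geometry.eccentricity if d > 0 else +geometry.eccentricity
    step = condition.velocity * 0.1
    return start + d * (condition.velocity * t_ms / 1000.0 - step)


def simulate_eye_trace(
    condition: TrialCondition,
    observer: SimObserver,
    seed: int | np.random.Generator | None = None,
    geometry: StimulusGeometry | None = None,
    pretrial_ms: float = 1250.0,
) -> tuple[EyeTrace, dict]:
    """Simulate one 1-kHz trial trace with ground-truth annotations.

    Returns the trace and a ``truth`` dict with keys ``onset_ms`` (None for
    fixation trials), ``steady_velocity``, ``saccades`` (list of
    ``{onset_ms, amplitude_deg}``), and ``blink_spans``.
    """
    geometry = geometry or StimulusGeometry()
    geometry.check_velocity(condition.velocity)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cond_key = condition.visual_condition.value
    v_target = condition.velocity
    occl = geometry.presentation_ms
    t_end = contact_time(geometry, v_target) + POST_CONTACT_PAD_MS
    t = np.arange(-round(pretrial_ms), round(t_end) + 1, dtype=float)
    n = len(t)
    gazed = -geometry.eccentricity

    truth: dict = {
        "condition": cond_key,
        "velocity": v_target,
        "onset_ms": None,
        "steady_velocity": 0.0,
        "saccades": [],
        "blink_spans": [],
    }

    if condition.visual_condition.is_pursuit:
        latency = float(
            max(
                rng.normal(
                    observer.latency_mean_ms[cond_key],
                    observer.latency_sd_ms[cond_key],
                ),
                40.0,
            )
        )
        accel = observer.accel_mean[cond_key]
        v_ss = observer.gain(condition) * v_target
        ve = np.zeros(n)
        ramp = (t >= latency) & (t <= occl)
        ve[ramp] = np.minimum(accel * (t[ramp] - latency) / 1000.0, v_ss)
        post = t > occl
        v_at_occl = min(accel * max(occl - latency, 0.0) / 1000.0, v_ss)
        ve[post] = v_at_occl * np.exp(-(t[post] - occl) / observer.decay_tau_ms)
        x = gazed + np.cumsum(ve) / 1000.0
        truth["onset_ms"] = latency
        truth["steady_velocity"] = v_ss

        # catch-up saccades: Poisson times within [latency, occlusion]
        lam = observer.saccade_rate_hz[cond_key]
        window_s = max(occl - SACCADE_DURATION_MS - latency, 0.0) / 1000.0
        n_sacc = rng.poisson(lam * window_s) if lam > 0 and window_s > 0 else 0
        if n_sacc:
            times = np.sort(
                rng.uniform(latency, occl - SACCADE_DURATION_MS, size=n_sacc)
            )
            profile = _minimum_jerk(SACCADE_DURATION_MS + 1)
            for ts in times:
                i0 = int(ts - t[0])
                err = _target_position_x(np.array([ts]), condition, geometry)[0] - x[i0]
                amp = err
                if abs(amp) < observer.min_saccade_amp_deg:
                    sign = np.sign(amp) if amp != 0 else condition.motion_direction
                    amp = sign * observer.min_saccade_amp_deg
                m = min(len(profile), n - i0)
                x[i0 : i0 + m] += amp * profile[:m]
                x[i0 + m :] += amp
                truth["saccades"].append(
                    {"onset_ms": float(ts), "amplitude_deg": float(amp)}
                )
    else:
        x = np.full(n, gazed)

    x = x + _smooth_noise(
        rng, n, observer.fixation_noise_sd_deg, observer.noise_cutoff_hz
    )
    y = _smooth_noise(rng, n, observer.fixation_noise_sd_deg, observer.noise_cutoff_hz)

    valid = np.ones(n, dtype=bool)
    if observer.blink_prob > 0 and rng.random() < observer.blink_prob:
        dur = float(rng.uniform(100.0, 300.0))
        onset = float(rng.uniform(t[0] + 100.0, t_end - dur - 100.0))
        span = (t >= onset) & (t <= onset + dur)
        valid[span] = False
        x[span] = np.nan
        y[span] = np.nan
        truth["blink_spans"].append((onset, onset + dur))

    return EyeTrace(t=t, x=x, y=y, valid=valid), truth


def expected_response_ms(
    condition: TrialCondition,
    gamma: float,
    geometry: StimulusGeometry | None = None,
) -> float:
    """Noise-free response time of the extrapolation model (ms).

    ``occlusion + remaining_distance / (gamma * velocity)`` with
    ``remaining_distance = separation - velocity * presentation``.
    """
    geometry = geometry or StimulusGeometry()
    if gamma <= 0:
        raise ValueError("perceptual gain must be positive")
    v = condition.velocity
    remaining = geometry.separation - v * geometry.presentation_ms / 1000.0
    return geometry.presentation_ms + remaining / (gamma * v) * 1000.0


def simulate_response(
    condition: TrialCondition,
    observer: SimObserver,
    seed: int | np.random.Generator | None = None,
    geometry: StimulusGeometry | None = None,
) -> float:
    """Draw one button-press time (ms from motion onset).

    The occlusion-to-response interval is scaled by multiplicative Gaussian
    timing noise (CV = ``timing_cv``) and shifted by Gaussian motor noise.
    """
    geometry = geometry or StimulusGeometry()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    gamma = observer.gamma(condition)
    base = expected_response_ms(condition, gamma, geometry)
    interval = base - geometry.presentation_ms
    noisy = interval * (1.0 + observer.timing_cv * rng.standard_normal())
    noisy += observer.motor_sd_ms * rng.standard_normal()
    return float(geometry.presentation_ms + noisy)


def simulate_dataset(
    observers: Sequence[SimObserver],
    design: SessionDesign,
    seed: int | None = None,
    geometry: StimulusGeometry | None = None,
) -> SimDataset:
    """One :class:`SimTrial` per (observer, design trial).

    Per-trial RNG streams are spawned deterministically from the master
    seed, so the full dataset is reproducible bit-for-bit.
    """
    if len(observers) == 0:
        raise ValueError("need at least one observer")
    geometry = geometry or StimulusGeometry()
    root = np.random.SeedSequence(seed)
    obs_seqs = root.spawn(len(observers))
    trials: list[SimTrial] = []
    for observer, obs_seq in zip(observers, obs_seqs):
        trial_seqs = obs_seq.spawn(len(design.trials))
        for rec, sub in zip(design.trials, trial_seqs):
            rng = np.random.default_rng(sub)
            trace, truth = simulate_eye_trace(
                rec.condition,
                observer,
                seed=rng,
                geometry=geometry,
                pretrial_ms=rec.pretrial_ms,
            )
            response = simulate_response(rec.condition, observer, seed=rng, geometry=geometry)
            trials.append(
                SimTrial(
                    observer_id=observer.observer_id,
                    record=rec,
                    trace=trace,
                    response_ms=response,
                    truth=truth,
                )
            )
    return SimDataset(trials=trials, geometry=geometry, observers=list(observers), seed=seed)
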