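"""Paradigm geometry, trial timing, step-ramp motion model, and factorial
session structure.

Conventions used throughout the package:

* time is in milliseconds with ``t = 0`` at motion onset;
* positions are in degrees of visual angle, rightward positive, origin at
  screen centre;
* trajectory helpers (:func:`step_ramp_trajectory`,
  :func:`motion_stimulus_descriptor`) work on the *motion axis*: displacement
  from the moving object's initial position, positive in the direction of
  motion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "VisualCondition",
    "StimulusGeometry",
    "TrialCondition",
    "TrialTimeline",
    "TrialRecord",
    "SessionDesign",
    "DEFAULT_VELOCITIES",
    "contact_time",
    "step_ramp_trajectory",
    "motion_stimulus_descriptor",
    "build_session",
    "default_conditions",
]

DEFAULT_VELOCITIES: tuple[float, ...] = (3.0, 4.0, 5.0)

#: duration of the initial backward step of the step-ramp, in seconds
STEP_RECROSS_S = 0.1


class VisualCondition(str, Enum):
    """The three viewing conditions of the task."""

    FIXATION = "fixation"
    PURSUIT_FIRST_ORDER = "pursuit_first_order"
    PURSUIT_SECOND_ORDER = "pursuit_second_order"

    @property
    def is_pursuit(self) -> bool:
        return self is not VisualCondition.FIXATION

    @property
    def motion_direction(self) -> int:
        """Screen-axis sign of object motion: +1 rightward, -1 leftward.

        Under fixation the gazed (left) object is stationary and the right
        object moves leftward; under pursuit the left object moves rightward.
        """
        return -1 if self is VisualCondition.FIXATION else +1

    @property
    def is_second_order(self) -> bool:
        return self is VisualCondition.PURSUIT_SECOND_ORDER


@dataclass(frozen=True)
class StimulusGeometry:
    """Spatial and temporal layout of the two-object display.

    Parameters
    ----------
    separation
        Distance between moving and stationary object centres (deg).
    eccentricity
        Distance of each object from screen centre (deg); the gazed object
        sits at ``-eccentricity``, the other at ``+eccentricity``.
    window_sd
        SD of the Gaussian contrast window defining each object (deg).
    dot_density
        Fraction of texture dots that are bright.
    presentation_ms
        Time from motion onset to simultaneous disappearance (ms).
    """

    separation: float = 6.0
    eccentricity: float = 3.0
    window_sd: float = 0.4
    dot_density: float = 0.5
    presentation_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if self.presentation_ms <= 0:
            raise ValueError("presentation_ms must be positive")
        if not 0 < self.dot_density <= 1:
            raise ValueError("dot_density must be in (0, 1]")

    @property
    def occlusion_onset_ms(self) -> float:
        """Occlusion starts when presentation ends (motion-onset clock)."""
        return self.presentation_ms

    def check_velocity(self, velocity: float) -> None:
        """Objects must disappear before they could touch."""
        if velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.presentation_ms >= contact_time(self, velocity):
            raise ValueError(
                f"presentation ({self.presentation_ms} ms) outlasts contact "
                f"at {velocity} deg/s"
            )


@dataclass(frozen=True)
class TrialCondition:
    """A single cell of the factorial design."""

    visual_condition: VisualCondition
    velocity: float  # deg/s

    def __post_init__(self) -> None:
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")

    @property
    def motion_direction(self) -> int:
        return self.visual_condition.motion_direction

    @property
    def label(self) -> str:
        return f"{self.visual_condition.value}@{self.velocity:g}"


@dataclass(frozen=True)
class TrialTimeline:
    """Event timing of one trial relative to motion onset (t = 0 ms)."""

    cue_ms: float = 2500.0
    pretrial_ms: float = 1250.0
    presentation_ms: float = 500.0
    intertrial_ms: float = 5000.0

    def __post_init__(self) -> None:
        if not 1000.0 <= self.pretrial_ms <= 1500.0:
            raise ValueError("pretrial_ms must lie in [1000, 1500]")

    @property
    def motion_onset_ms(self) -> float:
        return 0.0

    @property
    def occlusion_onset_ms(self) -> float:
        return self.presentation_ms


@dataclass(frozen=True)
class TrialRecord:
    """One scheduled trial of a session."""

    trial_id: int
    block: int
    condition: TrialCondition
    pretrial_ms: float


@dataclass
class SessionDesign:
    """A randomly interleaved factorial session split into equal blocks."""

    trials: list[TrialRecord]
    n_blocks: int
    n_per_cell: int
    seed: int | None = None
    conditions: tuple[TrialCondition, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_cells(self) -> int:
        return len(self.conditions)

    def cell_counts(self) -> dict[TrialCondition, int]:
        counts: dict[TrialCondition, int] = {c: 0 for c in self.conditions}
        for rec in self.trials:
            counts[rec.condition] += 1
        return counts

    def to_records(self) -> list[dict]:
        """Plain-dict manifest rows (one per trial), serialisation-ready."""
        return [
            {
                "trial_id": rec.trial_id,
                "block": rec.block,
                "visual_condition": rec.condition.visual_condition.value,
                "velocity": rec.condition.velocity,
                "pretrial_ms": rec.pretrial_ms,
            }
            for rec in self.trials
        ]


def default_conditions(
    velocities: Sequence[float] = DEFAULT_VELOCITIES,
) -> tuple[TrialCondition, ...]:
    """The 3 visual conditions x len(velocities) factorial cells."""
    return tuple(
        TrialCondition(vc, float(v))
        for vc, v in itertools.product(VisualCondition, velocities)
    )


def contact_time(geometry: StimulusGeometry, velocity: float) -> float:
    """Time (ms from motion onset) at which the moving object would
    coincide with the stationary one: separation / velocity."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    return geometry.separation / velocity * 1000.0


def step_ramp_trajectory(
    velocity: float, duration_ms: float, dt_ms: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Step-ramp target displacement on the motion axis.

    The target steps *backward* (opposite to motion) by ``velocity * 0.1 s``
    at t = 0 and then ramps forward at constant ``velocity``, recrossing its
    initial position at exactly 100 ms.

    Returns
    -------
    t : ndarray
        Sample times in ms, ``0 .. duration_ms`` inclusive.
    pos : ndarray
        Displacement from the initial presented position (deg, motion
        direction positive).
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    n_steps = duration_ms / dt_ms
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("dt_ms must divide duration_ms")
    t = np.arange(round(n_steps) + 1, dtype=float) * dt_ms
    # algebraically v*t/1000 - step, but exact (not just close) at the
    # 100-ms recross
    pos = velocity * (t - STEP_RECROSS_S * 1000.0) / 1000.0
    return t, pos


def motion_stimulus_descriptor(
    condition: TrialCondition,
    t_ms: float,
    geometry: StimulusGeometry | None = None,
) -> dict[str, float]:
    """Window-centre and texture-phase displacement of the moving object.

    Both values are displacements on the motion axis from the object's
    initial presented position.  First-order motion: the texture rides the
    window (equal displacement).  Second-order motion: the window moves over
    a static carrier, so the texture phase stays at 0.  The fixation
    condition's leftward-moving object is a first-order stimulus.
    """
    geometry = geometry or StimulusGeometry()
    if not 0 <= t_ms <= geometry.presentation_ms:
        raise ValueError(
            f"t={t_ms} ms outside presentation [0, {geometry.presentation_ms}]"
        )
    step = condition.velocity * STEP_RECROSS_S
    window_center = condition.velocity * t_ms / 1000.0 - step
    if condition.visual_condition.is_second_order:
        texture_phase = 0.0
    else:
        texture_phase = window_center
    return {"window_center": window_center, "texture_phase": texture_phase}


def build_session(
    n_per_cell: int = 20,
    n_blocks: int = 5,
    conditions: Sequence[TrialCondition] | None = None,
    seed: int | None = None,
    pretrial_range_ms: tuple[float, float] = (1000.0, 1500.0),
) -> SessionDesign:
    """Build a seeded, randomly interleaved session.

    All ``n_per_cell * len(conditions)`` trials are globally shuffled and
    then cut into ``n_blocks`` equal blocks.  Pretrial fixation durations are
    drawn uniformly from ``pretrial_range_ms`` (jitter distribution assumed
    uniform).  Deterministic for a fixed seed.
    """
    if conditions is None:
        conditions = default_conditions()
    conditions = tuple(conditions)
    if n_per_cell < 1 or n_blocks < 1:
        raise ValueError("n_per_cell and n_blocks must be >= 1")
    n_trials = n_per_cell * len(conditions)
    if n_trials % n_blocks != 0:
        raise ValueError(
            f"{n_trials} trials cannot be split into {n_blocks} equal blocks"
        )
    rng = np.random.default_rng(seed)
    pool = [c for c in conditions for _ in range(n_per_cell)]
    order = rng.permutation(n_trials)
    per_block = n_trials // n_blocks
    lo, hi = pretrial_range_ms
    trials = []
    for i, k in enumerate(order):
        trials.append(
            TrialRecord(
                trial_id=i,
                block=i // per_block,
                condition=pool[k],
                pretrial_ms=float(rng.uniform(lo, hi)),
            )
        )
    return SessionDesign(
        trials=trials,
        n_blocks=n_blocks,
        n_per_cell=n_per_cell,
        seed=seed,
        conditions=conditions,
    )
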