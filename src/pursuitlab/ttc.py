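"""Time-to-contact performance measures.

All times are on the motion-onset clock (ms).  The sign convention is:
negative constant error = response earlier than the correct contact time.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "constant_error",
    "variable_error",
    "reaction_time",
    "aggregate_errors",
    "previous_trial_table",
]


def constant_error(response_ms: float, contact_ms: float) -> float:
    """Signed timing error: response - correct contact time (ms)."""
    if not np.isfinite(response_ms):
        raise ValueError("missing response")
    return float(response_ms - contact_ms)


def variable_error(constant_errors: Sequence[float]) -> float | None:
    """Sample SD of a cell's constant errors; None with fewer than 2 trials."""
    ce = np.asarray(list(constant_errors), dtype=float)
    ce = ce[np.isfinite(ce)]
    if ce.size < 2:
        return None
    return float(np.std(ce, ddof=1))


def reaction_time(response_ms: float, occlusion_ms: float) -> float:
    """Response latency from occlusion onset (ms).

    Anticipatory responses (at or before occlusion onset) are still
    returned, but callers should treat non-positive values as flagged.
    """
    return float(response_ms - occlusion_ms)


def aggregate_errors(
    trials: pd.DataFrame,
    group_cols: Sequence[str] = ("observer_id", "visual_condition", "velocity"),
) -> pd.DataFrame:
    """Per-cell mean constant/absolute error, variable error and count.

    ``trials`` must carry ``constant_error_ms`` (QC-passing trials only).
    Cells with a single trial get NaN variable error.
    """
    if trials.empty:
        raise ValueError("no trials to aggregate")

    def _agg(g: pd.DataFrame) -> pd.Series:
        ce = g["constant_error_ms"].to_numpy(dtype=float)
        ve = variable_error(ce)
        return pd.Series(
            {
                "constant_error_ms": float(np.mean(ce)),
                "absolute_error_ms": float(np.mean(np.abs(ce))),
                "variable_error_ms": np.nan if ve is None else ve,
                "n_trials": len(ce),
            }
        )

    out = (
        trials.groupby(list(group_cols), observed=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n_trials"] = out["n_trials"].astype(int)
    return out


def previous_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Constant errors keyed by current and previous object velocity.

    ``trials`` must carry session order (``trial_id``), ``block``,
    ``velocity`` and ``constant_error_ms`` for one observer-session (or a
    frame grouped by ``observer_id``).  The previous velocity is the
    *presented* velocity of the preceding trial regardless of its QC fate;
    block-initial trials have no valid predecessor and are dropped.

    Returns a long frame with a ``prev_velocity`` column, ready for a
    (velocity x prev_velocity) comparison.
    """
    required = {"trial_id", "block", "velocity"}
    if not required <= set(trials.columns):
        raise ValueError(f"trials must have columns {sorted(required)}")
    frames = []
    group_cols = ["observer_id"] if "observer_id" in trials.columns else []
    grouped = trials.groupby(group_cols, observed=True) if group_cols else [((), trials)]
    for _, g in grouped:
        g = g.sort_values("trial_id").copy()
        g["prev_velocity"] = g["velocity"].shift(1)
        g.loc[g["block"] != g["block"].shift(1), "prev_velocity"] = np.nan
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    return out[out["prev_velocity"].notna()].reset_index(drop=True)
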