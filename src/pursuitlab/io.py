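"""Plain-text dataset formats: trace CSV, session manifest, ground-truth
sidecar, and result tables.

A dataset directory contains::

    manifest.yaml   one record per trial (ids, condition, timing, response)
    traces.csv      long-format samples: observer_id, trial_id, t_ms,
                    x_deg, y_deg, valid
    truth.json      optional per-trial ground-truth annotations
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (
    SessionDesign,
    StimulusGeometry,
    TrialCondition,
    TrialRecord,
    VisualCondition,
)
from .preprocess import EyeTrace
from .simulate import SimDataset, SimTrial

__all__ = ["SchemaError", "write_dataset", "read_dataset", "write_table", "read_table"]

TRACE_COLUMNS = ["observer_id", "trial_id", "t_ms", "x_deg", "y_deg", "valid"]


class SchemaError(ValueError):
    """A dataset file violates the expected schema."""


def write_dataset(dataset: SimDataset, path: str | Path, traces: bool = True) -> None:
    """Write a dataset directory (manifest + optional traces + truth)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = []
    for tr in dataset.trials:
        rec = tr.record
        records.append(
            {
                "observer_id": tr.observer_id,
                "trial_id": rec.trial_id,
                "block": rec.block,
                "visual_condition": rec.condition.visual_condition.value,
                "velocity": rec.condition.velocity,
                "pretrial_ms": rec.pretrial_ms,
                "response_ms": float(tr.response_ms),
            }
        )
    manifest = {
        "seed": dataset.seed,
        "geometry": {
            "separation_deg": dataset.geometry.separation,
            "eccentricity_deg": dataset.geometry.eccentricity,
            "window_sd_deg": dataset.geometry.window_sd,
            "dot_density": dataset.geometry.dot_density,
            "presentation_ms": dataset.geometry.presentation_ms,
        },
        "trials": records,
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    truth = {
        f"{tr.observer_id}/{tr.record.trial_id}": tr.truth for tr in dataset.trials
    }
    (path / "truth.json").write_text(json.dumps(truth))

    if traces:
        frames = []
        for tr in dataset.trials:
            frames.append(
                pd.DataFrame(
                    {
                        "observer_id": tr.observer_id,
                        "trial_id": tr.record.trial_id,
                        "t_ms": tr.trace.t.astype(int),
                        "x_deg": tr.trace.x,
                        "y_deg": tr.trace.y,
                        "valid": tr.trace.valid.astype(int),
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path / "traces.csv", index=False)


def read_dataset(path: str | Path) -> SimDataset:
    """Read a dataset directory back into a :class:`SimDataset`.

    Validates the trace schema: required columns, every manifest trial
    present, and a uniform 1-ms grid per trial (violations are reported with
    the trial id and the offending CSV row number).
    """
    path = Path(path)
    man_file = path / "manifest.yaml"
    if not man_file.exists():
        raise SchemaError(f"missing manifest: {man_file}")
    manifest = yaml.safe_load(man_file.read_text())
    g = manifest.get("geometry", {})
    geometry = StimulusGeometry(
        separation=g.get("separation_deg", 6.0),
        eccentricity=g.get("eccentricity_deg", 3.0),
        window_sd=g.get("window_sd_deg", 0.4),
        dot_density=g.get("dot_density", 0.5),
        presentation_ms=g.get("presentation_ms", 500.0),
    )

    trace_file = path / "traces.csv"
    if not trace_file.exists():
        raise SchemaError(f"missing traces file: {trace_file}")
    df = pd.read_csv(trace_file, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"traces.csv missing columns: {missing}")
    df["_row"] = np.arange(2, len(df) + 2)  # 1-based, after header

    truth_file = path / "truth.json"
    truth_map = json.loads(truth_file.read_text()) if truth_file.exists() else {}

    grouped = {k: v for k, v in df.groupby(["observer_id", "trial_id"], sort=False)}
    trials = []
    for rec in manifest["trials"]:
        key = (rec["observer_id"], rec["trial_id"])
        if key not in grouped:
            raise SchemaError(
                f"manifest references trial {rec['observer_id']}/{rec['trial_id']} "
                "with no samples in traces.csv"
            )
        g_df = grouped[key].sort_values("t_ms")
        dts = np.diff(g_df["t_ms"].to_numpy())
        bad = np.flatnonzero(dts != 1)
        if bad.size:
            row = int(g_df["_row"].iloc[bad[0] + 1])
            raise SchemaError(
                f"non-uniform sampling in trial {rec['observer_id']}/"
                f"{rec['trial_id']} near traces.csv row {row} "
                f"(dt={dts[bad[0]]} ms)"
            )
        trace = EyeTrace(
            t=g_df["t_ms"].to_numpy(dtype=float),
            x=g_df["x_deg"].to_numpy(dtype=float),
            y=g_df["y_deg"].to_numpy(dtype=float),
            valid=g_df["valid"].to_numpy(dtype=bool),
        )
        condition = TrialCondition(
            VisualCondition(rec["visual_condition"]), float(rec["velocity"])
        )
        trials.append(
            SimTrial(
                observer_id=rec["observer_id"],
                record=TrialRecord(
                    trial_id=rec["trial_id"],
                    block=rec["block"],
                    condition=condition,
                    pretrial_ms=rec["pretrial_ms"],
                ),
                trace=trace,
                response_ms=float(rec["response_ms"]),
                truth=truth_map.get(f"{rec['observer_id']}/{rec['trial_id']}", {}),
            )
        )
    return SimDataset(
        trials=trials, geometry=geometry, observers=[], seed=manifest.get("seed")
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
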