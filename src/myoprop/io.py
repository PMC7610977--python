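"""Configuration files and trial-record serialization.

The experiment configuration is a YAML document with sections for the
workspace geometry, the control law, the manipulandum plant and the
synthetic-cohort generator.  Trial records are written as JSON Lines (one
object per trial, trajectories as nested arrays) next to a flat CSV
summary (one row per trial).
"""

from __future__ import annotations

import dataclasses
import json

import pandas as pd
import yaml

from .geometry import DoAConfig, WorkspaceGeometry
from .manipulandum import PlantParams
from .task import TrialRecord

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "geometry_from_config",
    "doa_from_config",
    "plant_from_config",
    "write_records_jsonl",
    "read_records_jsonl",
    "write_summary_csv",
    "read_summary_csv",
]


def default_config() -> dict:
    """The default experiment configuration as a plain dictionary."""
    g = WorkspaceGeometry()
    d = DoAConfig()
    p = PlantParams()
    return {
        "workspace": {
            "start_zone_diameter_cm": 2 * g.start_zone_radius,
            "cursor_diameter_cm": 2 * g.cursor_radius,
            "target_diameter_cm": 2 * g.target_radius,
            "ring_radius_cm": g.ring_radius,
            "target_angles_deg": list(g.target_angles_deg),
            "display_rate_hz": g.display_rate,
        },
        "control": {
            "doa_angles_deg": list(d.angles_deg),
            "gain_length_cm": d.gain_length,
        },
        "manipulandum": dataclasses.asdict(p),
        "cohort": {
            "n_subjects": {1: 21, 2: 19, 3: 19},
            "fraction_non_learners": 0.1,
        },
    }


def geometry_from_config(config: dict) -> WorkspaceGeometry:
    w = config["workspace"]
    return WorkspaceGeometry(
        start_zone_radius=w["start_zone_diameter_cm"] / 2.0,
        cursor_radius=w["cursor_diameter_cm"] / 2.0,
        target_radius=w["target_diameter_cm"] / 2.0,
        ring_radius=w["ring_radius_cm"],
        target_angles_deg=tuple(w["target_angles_deg"]),
        display_rate=w["display_rate_hz"],
    )


def doa_from_config(config: dict) -> DoAConfig:
    c = config["control"]
    return DoAConfig(
        angles_deg=tuple(c["doa_angles_deg"]),
        gain_length=c["gain_length_cm"],
    )


def plant_from_config(config: dict) -> PlantParams:
    return PlantParams(**config["manipulandum"])


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


# ----------------------------------------------------------------------
# trial records
# ----------------------------------------------------------------------

def _record_to_dict(record: TrialRecord) -> dict:
    m = record.metrics
    return {
        "spec": dataclasses.asdict(record.spec),
        "frame_times": record.frame_times.tolist(),
        "phase_labels": list(record.phase_labels),
        "cursor": record.cursor.tolist(),
        "activations": record.activations.tolist(),
        "handle": None if record.handle is None else record.handle.tolist(),
        "events": [list(e) for e in record.events],
        "score": record.score,
        "valid": record.valid,
        "metrics": {
            "mismatch": m.mismatch,
            "radial_window_means": list(m.radial_window_means),
            "angular_window_means": (
                None
                if m.angular_window_means is None
                else list(m.angular_window_means)
            ),
        },
    }


def write_records_jsonl(records, path) -> None:
    """One JSON object per line per trial (full trajectories included)."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(_record_to_dict(record)) + "\n")


def read_records_jsonl(path) -> list[dict]:
    """Read trial records back as plain dictionaries (arrays as lists)."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


def read_summary_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
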