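"""Session container and on-disk format.

A session is a directory of plain-text tables plus a JSON metadata file:

* ``metadata.json`` — rates, channel roles/units, seed, autofluorescence,
  config hash;
* ``timeseries.csv`` — ``time_s, velocity_cmps`` and one column per
  population fluorescence channel (raw units, raw rate);
* ``cells.csv`` / ``cell_traces.csv`` — ROI centroids (µm, origin at the
  field corner) and per-cell raw fluorescence at the ROI frame rate;
* ``events_*.csv`` — reward/lick streams and the generator's ground-truth
  event table, when present.

All time axes are seconds from session start; intervals are half-open
[start, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .synth.config import GroundTruth, PopulationEvent

__all__ = ["Session", "SchemaError", "read_session", "write_session"]

_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """The on-disk session does not match the declared schema."""


@dataclass
class Session:
    raw_rate_hz: float
    velocity: np.ndarray  # cm/s at raw rate
    channels: Dict[str, np.ndarray] = field(default_factory=dict)
    autofluorescence: float = 0.0
    cell_rate_hz: float = 30.0
    cell_traces: Optional[np.ndarray] = None  # n_cells × n_frames, raw units
    cell_positions: Optional[np.ndarray] = None  # n_cells × 2, µm
    rewards: Optional[np.ndarray] = None
    licks: Optional[np.ndarray] = None
    ground_truth: Optional[GroundTruth] = None
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.velocity.size / self.raw_rate_hz

    @property
    def n_cells(self) -> int:
        return 0 if self.cell_traces is None else self.cell_traces.shape[0]


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": _FORMAT_VERSION,
        "raw_rate_hz": session.raw_rate_hz,
        "cell_rate_hz": session.cell_rate_hz,
        "autofluorescence": session.autofluorescence,
        "channels": {role: {"units": "raw_fluorescence"}
                     for role in session.channels},
        "velocity_units": "cm/s",
        "n_cells": session.n_cells,
        **session.meta,
    }
    t = np.arange(session.velocity.size) / session.raw_rate_hz
    ts = pd.DataFrame({"time_s": t, "velocity_cmps": session.velocity})
    for role, x in session.channels.items():
        ts[role] = x
    ts.to_csv(path / "timeseries.csv", index=False, float_format="%.6g")

    if session.cell_traces is not None and session.n_cells:
        pd.DataFrame({
            "cell_id": np.arange(session.n_cells),
            "x_um": session.cell_positions[:, 0],
            "y_um": session.cell_positions[:, 1],
        }).to_csv(path / "cells.csv", index=False, float_format="%.4f")
        tc = np.arange(session.cell_traces.shape[1]) / session.cell_rate_hz
        df = pd.DataFrame(session.cell_traces.T,
                          columns=[f"cell_{i}" for i in range(session.n_cells)])
        df.insert(0, "time_s", tc)
        df.to_csv(path / "cell_traces.csv", index=False, float_format="%.6g")

    for name, arr in (("rewards", session.rewards), ("licks", session.licks)):
        if arr is not None:
            pd.DataFrame({"time_s": arr}).to_csv(
                path / f"events_{name}.csv", index=False, float_format="%.4f")

    gt = session.ground_truth
    if gt is not None:
        pd.DataFrame(gt.movement_events, columns=["time_s", "type"]).to_csv(
            path / "events_ground_truth.csv", index=False, float_format="%.4f")
        extras = {
            "bouts": gt.bouts,
            "da_lag_s": gt.da_lag_s,
            "participation": gt.participation,
            "population_events": [
                {"time_s": e.time_s, "kind": e.kind,
                 "chi_amp": e.chi_amp, "da_amp": e.da_amp}
                for e in gt.population_events],
            "cell_transients": gt.cell_transients,
            "reward_truth": gt.reward_truth,
            "duration_s": gt.duration_s,
        }
        (path / "ground_truth.json").write_text(json.dumps(extras))

    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path: str | Path) -> Session:
    """Read a session directory, validating the schema."""
    path = Path(path)
    meta_file = path / "metadata.json"
    if not meta_file.exists():
        raise SchemaError(f"missing metadata.json in {path}")
    meta = json.loads(meta_file.read_text())
    for key in ("raw_rate_hz", "channels"):
        if key not in meta:
            raise SchemaError(f"metadata lacks required key {key!r}")
    ts = pd.read_csv(path / "timeseries.csv")
    if "velocity_cmps" not in ts.columns:
        raise SchemaError("timeseries.csv lacks column 'velocity_cmps'")
    channels = {}
    for role in meta["channels"]:
        if role not in ts.columns:
            raise SchemaError(f"timeseries.csv lacks declared channel {role!r}")
        channels[role] = ts[role].to_numpy(dtype=float)
    # declared rate must match the time axis
    if ts.shape[0] > 1:
        dt = float(ts["time_s"].iloc[1] - ts["time_s"].iloc[0])
        if abs(dt - 1.0 / meta["raw_rate_hz"]) > 1e-6:
            raise SchemaError("time axis does not match declared raw_rate_hz")

    cell_traces = cell_positions = None
    if (path / "cell_traces.csv").exists():
        cm = pd.read_csv(path / "cells.csv")
        cell_positions = cm[["x_um", "y_um"]].to_numpy(dtype=float)
        ct = pd.read_csv(path / "cell_traces.csv")
        cols = [c for c in ct.columns if c.startswith("cell_")]
        cell_traces = ct[cols].to_numpy(dtype=float).T

    def _events(name: str) -> Optional[np.ndarray]:
        f = path / f"events_{name}.csv"
        return pd.read_csv(f)["time_s"].to_numpy(dtype=float) if f.exists() else None

    gt = None
    if (path / "ground_truth.json").exists():
        d = json.loads((path / "ground_truth.json").read_text())
        ev = pd.read_csv(path / "events_ground_truth.csv")
        gt = GroundTruth(
            movement_events=[(float(t), str(k))
                             for t, k in zip(ev["time_s"], ev["type"])],
            bouts=[tuple(b) for b in d["bouts"]],
            population_events=[PopulationEvent(**e)
                               for e in d["population_events"]],
            cell_transients=d["cell_transients"],
            da_lag_s=d["da_lag_s"],
            participation=d["participation"],
            reward_truth=d["reward_truth"],
            duration_s=d["duration_s"],
        )

    known = {"format_version", "raw_rate_hz", "cell_rate_hz",
             "autofluorescence", "channels", "velocity_units", "n_cells"}
    return Session(
        raw_rate_hz=float(meta["raw_rate_hz"]),
        velocity=ts["velocity_cmps"].to_numpy(dtype=float),
        channels=channels,
        autofluorescence=float(meta.get("autofluorescence", 0.0)),
        cell_rate_hz=float(meta.get("cell_rate_hz", 30.0)),
        cell_traces=cell_traces,
        cell_positions=cell_positions,
        rewards=_events("rewards"),
        licks=_events("licks"),
        ground_truth=gt,
        meta={k: v for k, v in meta.items() if k not in known},
    )
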