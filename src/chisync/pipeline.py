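"""End-to-end pipeline: preprocess → classify → detect → align → correlate.

Duration thresholds for transient significance are calibrated across all
provided recordings, then applied to each session individually; every
output table carries the config hash for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import alignment, coupling, synchrony, transients
from .behavior import BehaviorAnnotation, annotate
from .config import AnalysisConfig
from .preprocessing import (
    DffTrace,
    Kinematics,
    RawTrace,
    bin_trace,
    compute_dff,
    compute_kinematics,
    zscore_to_rest,
)
from .session import Session

logger = logging.getLogger(__name__)

__all__ = ["ProcessedSession", "preprocess_session", "run_pipeline",
            "save_results", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and session id."""

    def __init__(self, stage: str, session_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for session {session_id!r}: {cause}")
        self.stage = stage
        self.session_id = session_id


@dataclass
class ProcessedSession:
    """Binned ΔF/F channels, kinematics and behavioral annotation."""

    kin: Kinematics
    dff: Dict[str, DffTrace]
    cell_dff: List[DffTrace]
    annotation: BehaviorAnnotation
    session: Session

    def zscored(self, role: str) -> np.ndarray:
        return zscore_to_rest(self.dff[role], self.annotation.mask("rest"))


def preprocess_session(session: Session, config: AnalysisConfig) -> ProcessedSession:
    """Bin raw channels to the analysis rate, compute ΔF/F and kinematics,
    and annotate behavior.  Per-cell ROI traces are processed at their
    native frame rate."""
    v_binned = bin_trace(
        RawTrace(session.velocity, session.raw_rate_hz, "velocity"), config.bin_s)
    kin = compute_kinematics(v_binned, config)
    annotation = annotate(kin, config)
    dff = {}
    for role, raw in session.channels.items():
        binned = bin_trace(RawTrace(raw, session.raw_rate_hz, role), config.bin_s)
        dff[role] = compute_dff(binned, config, session.autofluorescence)
    cell_dff = []
    if session.cell_traces is not None:
        cell_bin = 1.0 / session.cell_rate_hz
        for i in range(session.n_cells):
            cell_dff.append(compute_dff(session.cell_traces[i], config,
                                        autofluorescence=0.0, bin_s=cell_bin))
    return ProcessedSession(kin=kin, dff=dff, cell_dff=cell_dff,
                            annotation=annotation, session=session)


def run_pipeline(
    session: Session,
    config: Optional[AnalysisConfig] = None,
    thresholds: Optional[transients.DurationThresholds] = None,
    session_id: str = "session",
) -> Dict[str, object]:
    """Run the full analysis chain on one session.

    ``thresholds`` should come from :func:`transients.
    calibrate_duration_thresholds` over *all* recordings of a study; when
    omitted they are calibrated from this session alone.  Deterministic
    given session + config.  Returns a results bundle of data frames and
    result objects keyed by stage.
    """
    config = config or AnalysisConfig()
    results: Dict[str, object] = {"config_hash": config.hash(),
                                  "exclusions": []}
    stage = "preprocess"
    try:
        proc = preprocess_session(session, config)
        results["processed"] = proc

        stage = "classify"
        ann = proc.annotation
        results["behavior_events"] = pd.DataFrame(
            ann.events, columns=["time_s", "type"])
        results["bouts"] = pd.DataFrame(ann.bouts, columns=["start_s", "end_s"])
        results["labels"] = pd.DataFrame({
            "time_s": proc.kin.times, "label": ann.labels})

        stage = "detect"
        # thresholds are calibrated per channel role (pooled across a
        # study's recordings of that role when supplied by the caller):
        # ChI and DA channels have different event statistics, and pooling
        # them lets one role's long excursions dominate the other's rule
        if thresholds is None:
            thresholds = {
                role: transients.calibrate_duration_thresholds([tr], config)
                for role, tr in proc.dff.items()}
            if proc.cell_dff:
                thresholds["cells"] = transients.calibrate_duration_thresholds(
                    proc.cell_dff, config)
        elif isinstance(thresholds, transients.DurationThresholds):
            th = thresholds
            thresholds = {role: th for role in proc.dff}
            thresholds["cells"] = th
        results["thresholds"] = thresholds
        events_rows = []
        results["transients"] = {}
        for role, tr in proc.dff.items():
            evs = transients.detect_transients(tr, thresholds[role], config,
                                               source=role)
            results["transients"][role] = evs
            results[f"state_metrics_{role}"] = transients.transient_state_metrics(
                evs, tr, ann, config)
            events_rows += [
                {"source": role, "onset_s": e.onset_s, "offset_s": e.offset_s,
                 "peak_dff": e.peak_dff, "sd_level": e.sd_level} for e in evs]
        cell_events = []
        for i, tr in enumerate(proc.cell_dff):
            evs = transients.detect_transients(tr, thresholds["cells"], config,
                                               source=f"cell_{i}")
            cell_events.append(evs)
            events_rows += [
                {"source": f"cell_{i}", "onset_s": e.onset_s,
                 "offset_s": e.offset_s, "peak_dff": e.peak_dff,
                 "sd_level": e.sd_level} for e in evs]
        results["cell_transients"] = cell_events
        results["transient_table"] = pd.DataFrame(events_rows)

        stage = "align"
        rest_mask = ann.mask("rest")
        results["triggered"] = {}
        for role, tr in proc.dff.items():
            rest_vals = tr.dff[rest_mask]
            for kind in ("jerk", "initiation"):
                times = ann.event_times(kind)
                if times.size == 0:
                    continue
                results["triggered"][(role, kind)] = alignment.triggered_average(
                    tr.dff, times, config.triggered_window_s, rest_vals,
                    config.bin_s, tr.t0, config.triggered_alpha,
                    config.triggered_fdr)

        stage = "synchrony"
        if len(proc.cell_dff) >= 2:
            results["pair_correlations"] = {}
            for epoch in ("rest", "onset", "locomotion"):
                try:
                    pairs = synchrony.pairwise_xcorr_by_state(
                        proc.cell_dff, ann, epoch, config,
                        positions_um=session.cell_positions)
                    results["pair_correlations"][epoch] = pairs
                except synchrony.SessionExcluded as e:
                    results["exclusions"].append(str(e))
                    logger.info("synchrony: %s", e)
            results["coactivation"] = synchrony.coactivation_fraction(
                cell_events, ann, config)

        stage = "couple"
        if {"chi_pop", "da_pop"} <= set(proc.dff):
            a = proc.dff["chi_pop"].dff
            b = proc.dff["da_pop"].dff
            results["coupling_all"] = coupling.population_xcorr(
                a, b, None, config, config.bin_s, "all")
            bout_mask = ann.bout_mask()
            if bout_mask.sum() * config.bin_s >= config.min_epoch_s:
                results["coupling_locomotion"] = coupling.population_xcorr(
                    a, b, bout_mask, config, config.bin_s, "locomotion")
            results["velocity_xcorr"] = {
                role: coupling.kinematic_xcorr(
                    proc.dff[role].dff, proc.kin.velocity, None, config,
                    config.bin_s)
                for role in ("chi_pop", "da_pop")}
    except (synchrony.SessionExcluded,) as e:
        results["exclusions"].append(str(e))
    except Exception as e:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineError(stage, session_id, e) from e
    return results


def save_results(results: Dict[str, object], outdir: str | Path) -> None:
    """Write the exportable tables of a results bundle as delimited text,
    each stamped with the config hash."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = results.get("config_hash", "")

    def _write(df: pd.DataFrame, name: str) -> None:
        df = df.copy()
        df["config_hash"] = stamp
        df.to_csv(outdir / name, index=False)

    for key in ("behavior_events", "bouts", "labels", "transient_table"):
        if key in results:
            _write(results[key], f"{key}.csv")
    if "thresholds" in results:
        rows = []
        for role, th in results["thresholds"].items():
            rows += [{
                "role": role, "sd_level": k, "min_duration_s": d,
                "n_pos": th.n_pos.get(k, 0), "n_neg": th.n_neg.get(k, 0),
            } for k, d in th.durations_s.items()]
        _write(pd.DataFrame(rows), "duration_thresholds.csv")
    for key in ("coupling_all", "coupling_locomotion"):
        if key in results:
            c = results[key]
            _write(pd.DataFrame({"lag_s": c.lags_s, "r": c.correlogram}),
                   f"{key}_correlogram.csv")
            _write(pd.DataFrame([{
                "peak_r": c.peak_r, "peak_lag_s": c.peak_lag_s,
                "trough_r": c.trough_r, "trough_lag_s": c.trough_lag_s,
                "epoch": c.epoch, "convention": c.convention,
            }]), f"{key}_summary.csv")
    if "pair_correlations" in results:
        rows = []
        for epoch, pairs in results["pair_correlations"].items():
            rows += [{
                "cell_a": p.cell_a, "cell_b": p.cell_b,
                "distance_um": p.distance_um, "epoch": epoch,
                "peak_r": p.peak_r, "peak_lag_s": p.peak_lag_s,
                "zero_lag_r": p.zero_lag_r,
            } for p in pairs]
        if rows:
            _write(pd.DataFrame(rows), "pair_correlations.csv")
    if "exclusions" in results and results["exclusions"]:
        _write(pd.DataFrame({"reason": results["exclusions"]}), "exclusions.csv")
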