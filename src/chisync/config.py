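"""Analysis configuration.

Every numeric threshold used by the pipeline lives here, so that a single
serialized config file fully determines an analysis run.  Defaults follow
the conventions of head-fixed treadmill photometry work in dorsal striatum:
10 ms analysis bins, an 8th-percentile / 16 s sliding-window ΔF/F baseline,
velocity thresholds of 0.2 / 1.0 / 2.2 / 4.5 cm/s and an acceleration
threshold of 40 cm/s² for behavioral state segmentation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class AnalysisConfig:
    # -- binning & ΔF/F baseline -------------------------------------------
    #: analysis bin width, s (raw 1000 Hz channels are averaged into 10 ms bins)
    bin_s: float = 0.01
    #: sliding window for the percentile baseline, s
    baseline_window_s: float = 16.0
    #: percentile used for the baseline (8th percentile of the window)
    baseline_percentile: float = 8.0
    #: pass-2 exclusion: drop bins whose provisional ΔF/F exceeds this many
    #: robust SD (1.4826 × MAD) before recomputing the percentile
    baseline_exclude_nsd: float = 2.0
    #: which baseline the ΔF/F numerator subtracts: "uncorrected" subtracts
    #: the raw percentile baseline, "corrected" the autofluorescence-corrected
    #: one; the denominator is always the corrected baseline
    dff_numerator: str = "uncorrected"

    # -- kinematics ---------------------------------------------------------
    #: centered moving-average window applied to velocity before
    #: differentiating, s
    smooth_velocity_s: float = 0.05
    #: additional smoothing used only for locomotion-bout detection and
    #: within-bout velocity extrema, s (bridges stride-cycle dips)
    smooth_bout_s: float = 0.25

    # -- behavioral state / event thresholds (cm/s, cm/s², s) ---------------
    rest_velocity_cmps: float = 0.2
    onset_min_peak_cmps: float = 1.0
    movement_velocity_cmps: float = 2.2
    movement_accel_cmps2: float = 40.0
    bout_velocity_cmps: float = 4.5
    #: ± window (s) for the movement/rest state rules
    state_window_s: float = 1.0
    #: required quiescence before a clean movement onset, s
    pre_quiet_s: float = 0.5
    #: peak-velocity check window after a 0.2 cm/s crossing, s
    onset_peak_window_s: float = 1.0
    #: jerk rule: max velocity in this window post-crossing must stay
    #: below ``movement_velocity_cmps``
    jerk_window_s: Tuple[float, float] = (1.0, 2.0)
    #: initiation rule: mean velocity in this window must exceed
    #: ``bout_velocity_cmps``
    initiation_window_s: Tuple[float, float] = (0.5, 2.0)
    #: minimum continuous-locomotion bout duration, s (strictly greater)
    bout_min_s: float = 3.0
    #: a termination must hold velocity below ``movement_velocity_cmps``
    #: for this long, s
    termination_hold_s: float = 1.0
    #: prominence for within-bout velocity peaks/troughs, cm/s
    extrema_prominence_cmps: float = 1.0

    # -- transient significance calibration ---------------------------------
    #: SD levels (k: threshold = mean + k·SD) to calibrate
    sd_levels: Tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    #: required fraction of positive among positive+negative events
    event_ratio: float = 0.99
    #: "fraction_of_total": N+/(N+ + N−) ≥ event_ratio (default);
    #: "pos_over_neg": N+/N− ≥ event_ratio (literal ratio variant)
    ratio_mode: str = "fraction_of_total"
    #: statistics (mean, SD) for thresholds: "all" bins or "rest" bins only
    calibration_scope: str = "all"

    # -- epoch / alignment windows ------------------------------------------
    #: window around a movement onset treated as the "onset" epoch, s
    onset_epoch_window_s: Tuple[float, float] = (-0.1, 2.0)
    #: sessions with less total time than this in a required epoch are
    #: excluded from that epoch's analysis, s
    min_epoch_s: float = 5.0
    #: default event-triggered-average window, s
    triggered_window_s: Tuple[float, float] = (-2.0, 4.0)
    #: binwise significance level for triggered averages (rank-sum vs rest)
    triggered_alpha: float = 0.01
    #: apply Benjamini–Hochberg across lags (off by default, matching the
    #: figure convention of uncorrected binwise tests)
    triggered_fdr: bool = False
    #: trialwise response window after a reward/trigger, s
    response_window_s: Tuple[float, float] = (0.0, 1.0)
    #: velocity-change baseline window before the trigger, s
    dv_pre_window_s: Tuple[float, float] = (-1.0, 0.0)

    # -- pairwise synchrony --------------------------------------------------
    #: maximum cross-correlogram lag, s
    max_lag_s: float = 1.0
    #: minimum pairs for a per-field distance regression
    min_pairs_per_field: int = 10
    #: single-linkage window for clustering transient onsets across cells
    #: into population co-activation events, s
    coactivation_window_s: float = 0.2
    #: minimum distinct cells for a cluster to count as a population event
    coactivation_min_cells: int = 2

    # -- dual-population coupling -------------------------------------------
    #: companion-amplitude window around a primary transient onset, s
    companion_window_s: Tuple[float, float] = (-0.1, 0.5)
    #: post-transient velocity-outcome window, s
    outcome_post_window_s: Tuple[float, float] = (0.0, 1.0)
    #: pre-transient velocity baseline window, s
    outcome_pre_window_s: Tuple[float, float] = (-0.5, 0.0)
    #: joint z×z map grid: (low edge, high edge, width) in z units
    map_z_low: float = -2.0
    map_z_high: float = 4.0
    map_z_width: float = 0.5
    #: minimum samples per map cell; sparser cells are masked
    map_min_count: int = 10

    def __post_init__(self) -> None:
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if not 0 < self.event_ratio <= 1 and self.ratio_mode == "fraction_of_total":
            raise ValueError("event_ratio must lie in (0, 1]")
        if self.dff_numerator not in ("uncorrected", "corrected"):
            raise ValueError("dff_numerator must be 'uncorrected' or 'corrected'")
        if self.ratio_mode not in ("fraction_of_total", "pos_over_neg"):
            raise ValueError("unknown ratio_mode")
        if self.calibration_scope not in ("all", "rest"):
            raise ValueError("unknown calibration_scope")

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Short content hash stamped into every output for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
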