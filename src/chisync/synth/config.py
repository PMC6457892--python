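"""Synthetic-session configuration and ground truth.

The generator emulates a head-fixed mouse on a cylindrical treadmill
(3–6 min sessions, velocity sampled at 1 kHz) with GCaMP6f-like tonic-plus-
burst fluorescence: rest, micro-movements, jerks, locomotion initiations,
continuous bouts with stride-cycle and slow velocity fluctuations, and
terminations, all constructed to satisfy the behavioral classifier's
printed thresholds with margin.  Population synchrony is controlled by
per-state participation probabilities rather than single-cell rates, and a
DA-like population channel can respond with a configurable lag and a
state-dependent sign relative to the ChI drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["SynthConfig", "GroundTruth", "PopulationEvent", "PlacementError"]

#: named RNG substreams: every component draws from
#: default_rng([seed, STREAMS[name]]) so components are independently
#: reproducible under one master seed
STREAMS = {
    "velocity": 0,
    "events": 1,
    "cells": 2,
    "chi_noise": 3,
    "da_noise": 4,
    "rewards": 5,
    "static_noise": 6,
    "chi_async": 7,
}

EVENT_TYPES = ("jerk", "initiation", "termination", "micro")


class PlacementError(RuntimeError):
    """Requested event rates cannot be placed without overlap."""


@dataclass
class PopulationEvent:
    """One ground-truth population transient (shared drive across cells)."""

    time_s: float
    kind: str  # onset | rest | locomotion | reward
    chi_amp: float
    da_amp: float


@dataclass
class SynthConfig:
    # -- session geometry ----------------------------------------------------
    duration_s: float = 300.0
    raw_rate_hz: float = 1000.0
    n_cells: int = 0
    cell_rate_hz: float = 30.0  # 2-photon ROI frame rate
    field_size_um: float = 400.0

    # -- behavioral structure (events/min; margins beat the classifier
    #    thresholds by ≥20% so clean events are unambiguous) ----------------
    jerk_rate_per_min: float = 2.0
    initiation_rate_per_min: float = 1.0
    micro_rate_per_min: float = 1.0
    bout_duration_s: Tuple[float, float] = (4.0, 8.0)
    bout_level_cmps: Tuple[float, float] = (7.5, 8.5)
    stride_freq_hz: Tuple[float, float] = (2.0, 4.0)
    stride_amp_cmps: float = 1.8
    slow_fluct_amp_cmps: float = 1.2
    slow_fluct_freq_hz: Tuple[float, float] = (0.25, 0.4)
    jerk_peak_cmps: Tuple[float, float] = (1.4, 1.8)
    micro_peak_cmps: float = 0.15
    velocity_noise_cmps: float = 0.02  # encoder noise floor

    # -- population transients ----------------------------------------------
    #: spontaneous population events while the animal rests, events/min
    rest_event_rate_per_min: float = 6.0
    #: asynchronous ChI population drive during bouts, events/s (amplitude
    #: scaled down: many cells firing out of phase)
    chi_loco_event_rate_hz: float = 0.5
    chi_loco_event_amp: float = 0.3
    participation_prob_rest: float = 0.6
    participation_prob_onset: float = 0.9
    participation_prob_locomotion: float = 0.5
    #: per-cell asynchronous transient rate during bouts, transients/s
    async_rate_locomotion: float = 0.5
    #: optional length constant (µm) for exponential distance decay of
    #: event participation; None = distance-independent
    distance_decay_um: Optional[float] = None
    transient_amp_range: Tuple[float, float] = (0.8, 1.2)
    transient_jitter_s: float = 0.005

    # -- indicator kernel (GCaMP6f-like double exponential) ------------------
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.4

    # -- DA channel -----------------------------------------------------------
    da_lag_s: float = 0.11
    da_jerk_sign: int = -1
    #: DA event-response amplitude relative to the ChI drive (keeps
    #: negative-going jerk responses within a physical ΔF/F range)
    da_amp_scale: float = 0.5
    #: velocity-proportional DA component during bouts (ΔF/F per (cm/s)/10)
    da_velocity_gain: float = 0.3
    #: DA amplitude range at rest population events (independent of the
    #: ChI amplitude, so rest transients span weak→strong DA accompaniment)
    da_rest_amp_range: Tuple[float, float] = (0.0, 1.0)
    #: velocity kick (cm/s per unit DA amplitude) added shortly after each
    #: rest population event; >0 makes post-transient Δv depend on the DA
    #: companion amplitude (off by default so rest stays rest)
    transient_velocity_coupling: float = 0.0

    # -- photometry channel model --------------------------------------------
    f0: float = 10.0  # tonic raw fluorescence
    autofluorescence: float = 2.0  # raw units, added to every channel
    noise_sd: float = 0.02  # ΔF/F units, i.i.d. Gaussian per raw sample
    drift_amplitude: float = 0.2  # raw units, sinusoidal drift
    drift_period_s: float = 90.0
    #: static-indicator control: replaces the activity drive with
    #: artifact_gain × |velocity| (movement artifact only)
    static_indicator: bool = False
    artifact_gain: float = 0.0

    # -- rewards ---------------------------------------------------------------
    n_rewards: int = 0
    reward_interval_s: Tuple[float, float] = (10.0, 30.0)
    reward_velocity_kick_cmps: float = 3.0
    reward_chi_baseline: float = 0.5
    reward_chi_coupling: float = 0.3  # ΔF/F per cm/s of imposed Δv
    lick_latency_s: float = 0.25
    lick_rate_hz: float = 8.0
    lick_train_s: float = 2.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("participation_prob_rest", "participation_prob_onset",
                     "participation_prob_locomotion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("jerk_rate_per_min", "initiation_rate_per_min",
                     "micro_rate_per_min", "rest_event_rate_per_min",
                     "async_rate_locomotion", "chi_loco_event_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kernel_rise_s <= 0 or self.kernel_decay_s <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.duration_s <= 0 or self.raw_rate_hz <= 0:
            raise ValueError("duration and raw rate must be positive")
        if abs(self.raw_rate_hz * 0.01 - round(self.raw_rate_hz * 0.01)) > 1e-9:
            raise ValueError("raw_rate_hz must divide into 10 ms analysis bins")
        if self.da_jerk_sign not in (-1, 1):
            raise ValueError("da_jerk_sign must be -1 or +1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        """Named RNG substream derived from the master seed."""
        return np.random.default_rng([int(self.seed), STREAMS[stream]])


@dataclass
class GroundTruth:
    """Everything the generator imposed, for round-trip validation."""

    movement_events: List[Tuple[float, str]] = field(default_factory=list)
    bouts: List[Tuple[float, float]] = field(default_factory=list)
    population_events: List[PopulationEvent] = field(default_factory=list)
    cell_transients: List[List[float]] = field(default_factory=list)
    da_lag_s: float = 0.0
    participation: Dict[str, float] = field(default_factory=dict)
    reward_truth: List[Dict[str, float]] = field(default_factory=list)
    duration_s: float = 0.0

    def validate(self) -> None:
        for t, kind in self.movement_events:
            if not 0 <= t <= self.duration_s:
                raise ValueError("event outside the session")
            if kind not in EVENT_TYPES:
                raise ValueError(f"unknown event type {kind!r}")

    def events_of(self, *types: str) -> List[float]:
        return [t for t, k in self.movement_events if k in types]

    def onset_events(self) -> List[Tuple[float, str]]:
        return [(t, k) for t, k in self.movement_events
                if k in ("jerk", "initiation")]
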