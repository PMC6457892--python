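"""Treadmill-velocity synthesis with ground-truth movement events.

Sessions are a rest background (encoder-noise floor) with non-overlapping
movement segments placed uniformly at random: jerks (brief sin² bumps that
cross 0.2 cm/s, peak ≥ 1 cm/s and die out before the 1–2 s window), loco-
motion initiations (ramp into a >4.5 cm/s bout carrying stride-cycle and
slow velocity oscillations, ending in a termination decay), and sub-
threshold micro-movements.  Every segment embeds ≥1 s of quiescence on
both sides so clean-onset detection is unambiguous.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .config import GroundTruth, PlacementError, SynthConfig

__all__ = ["generate_velocity"]

_EDGE_START_S = 2.5  # event-free margins at the trace edges
_EDGE_END_S = 3.5
_GUARD_S = 1.5  # quiescent guard on both sides of each segment


def _jerk_segment(cfg: SynthConfig, rng: np.random.Generator, rate: float
                  ) -> np.ndarray:
    peak = rng.uniform(*cfg.jerk_peak_cmps)
    dur = 0.8
    t = np.arange(int(round(dur * rate))) / rate
    seg = peak * np.sin(np.pi * t / dur) ** 2
    pad = np.zeros(int(round((3.0 - dur) * rate)))
    return np.concatenate([seg, pad])  # 3 s footprint, quiet 1–2 s window


def _bout_segment(cfg: SynthConfig, rng: np.random.Generator, rate: float
                  ) -> Tuple[np.ndarray, float, float]:
    """Ramp + bout + termination decay; returns (samples, t_bout_start,
    t_bout_end) relative to segment start."""
    bout_dur = rng.uniform(*cfg.bout_duration_s)
    level = rng.uniform(*cfg.bout_level_cmps)
    f_stride = rng.uniform(*cfg.stride_freq_hz)
    f_slow = rng.uniform(*cfg.slow_fluct_freq_hz)
    phase = rng.uniform(0, 2 * np.pi)

    ramp_s, decay_s, hold_s = 0.5, 0.7, 1.3
    t_r = np.arange(int(round(ramp_s * rate))) / rate
    ramp = level * 0.5 * (1 - np.cos(np.pi * t_r / ramp_s))
    t_b = np.arange(int(round(bout_dur * rate))) / rate
    bout = (level
            + cfg.stride_amp_cmps * np.sin(2 * np.pi * f_stride * t_b)
            + cfg.slow_fluct_amp_cmps * np.sin(2 * np.pi * f_slow * t_b + phase))
    t_d = np.arange(int(round(decay_s * rate))) / rate
    decay = bout[-1] * 0.5 * (1 + np.cos(np.pi * t_d / decay_s))
    hold = np.zeros(int(round(hold_s * rate)))
    seg = np.concatenate([ramp, bout, decay, hold])
    return seg, ramp_s, ramp_s + bout_dur


def _micro_segment(cfg: SynthConfig, rate: float) -> np.ndarray:
    dur = 0.6
    t = np.arange(int(round(dur * rate))) / rate
    seg = cfg.micro_peak_cmps * np.sin(np.pi * t / dur) ** 2
    return np.concatenate([seg, np.zeros(int(round(0.4 * rate)))])


def generate_velocity(
    config: SynthConfig, seed: int | None = None
) -> Tuple[np.ndarray, GroundTruth]:
    """Synthesize a raw-rate velocity trace and its ground-truth events.

    Raises :class:`PlacementError` when the requested event rates cannot
    be placed without overlap.
    """
    cfg = config
    rng = (cfg.rng("velocity") if seed is None
           else np.random.default_rng([int(seed), 0]))
    rate = cfg.raw_rate_hz
    n = int(round(cfg.duration_s * rate))
    v = np.zeros(n)

    # build segments (samples + per-segment metadata)
    segments: List[Tuple[str, np.ndarray, float, float]] = []
    counts = {
        "jerk": int(round(cfg.jerk_rate_per_min * cfg.duration_s / 60.0)),
        "initiation": int(round(cfg.initiation_rate_per_min * cfg.duration_s / 60.0)),
        "micro": int(round(cfg.micro_rate_per_min * cfg.duration_s / 60.0)),
    }
    for _ in range(counts["jerk"]):
        segments.append(("jerk", _jerk_segment(cfg, rng, rate), 0.0, 0.0))
    for _ in range(counts["initiation"]):
        seg, b0, b1 = _bout_segment(cfg, rng, rate)
        segments.append(("initiation", seg, b0, b1))
    for _ in range(counts["micro"]):
        segments.append(("micro", _micro_segment(cfg, rate), 0.0, 0.0))
    rng.shuffle(segments)

    guard = int(round(_GUARD_S * rate))
    footprints = [seg.size + 2 * guard for _, seg, _, _ in segments]
    usable = n - int(round((_EDGE_START_S + _EDGE_END_S) * rate))
    free = usable - sum(footprints)
    if segments and free < 0:
        raise PlacementError(
            f"event rates need {sum(footprints) / rate:.1f} s of segment time "
            f"but only {usable / rate:.1f} s is available")

    # uniform non-overlapping placement via the stick-breaking construction
    offsets = np.sort(rng.uniform(0.0, max(free, 1), size=len(segments))
                      ).astype(int) if segments else np.array([], dtype=int)
    gt = GroundTruth(da_lag_s=cfg.da_lag_s, duration_s=cfg.duration_s,
                     participation={
                         "rest": cfg.participation_prob_rest,
                         "onset": cfg.participation_prob_onset,
                         "locomotion": cfg.participation_prob_locomotion,
                     })
    base = int(round(_EDGE_START_S * rate))
    prev_foot = 0
    for (kind, seg, b0, b1), off in zip(segments, offsets):
        start = base + int(off) + prev_foot + guard
        v[start: start + seg.size] = seg
        t_start = start / rate
        if kind == "micro":
            gt.movement_events.append((t_start, "micro"))
        else:
            cross = np.flatnonzero(seg > 0.2)
            t_cross = t_start + cross[0] / rate
            gt.movement_events.append((t_cross, kind))
            if kind == "initiation":
                gt.bouts.append((t_start + b0, t_start + b1))
                below = np.flatnonzero(seg[int(b1 * rate):] < 2.2)
                gt.movement_events.append(
                    (t_start + b1 + below[0] / rate, "termination"))
        prev_foot += seg.size + 2 * guard
    # encoder noise floor (kept ≪ the 0.2 cm/s rest threshold)
    if cfg.velocity_noise_cmps > 0:
        v = v + rng.normal(0.0, cfg.velocity_noise_cmps, size=n)
    gt.movement_events.sort()
    gt.validate()
    return v, gt
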