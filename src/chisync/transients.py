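"""Significant calcium-transient detection with noise-calibrated thresholds.

A positive excursion of ΔF/F counts as a significant transient only if it
stays above mean + k·SD (k = 1…6) for at least a minimum duration d_k.
The d_k are calibrated so that, among suprathreshold excursions, positive
events outnumber mirrored negative events 99:1 (fraction ≥ 0.99, i.e.
p < 0.01 that a detected event is a noise or artifact fluctuation).
Calibration pools all provided recordings; the resulting thresholds are
then applied to each session individually.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .behavior import BehaviorAnnotation, _runs
from .config import AnalysisConfig
from .preprocessing import DffTrace

logger = logging.getLogger(__name__)

__all__ = [
    "DurationThresholds",
    "TransientEvent",
    "calibrate_duration_thresholds",
    "detect_transients",
    "noise_event_counts",
    "transient_state_metrics",
]


@dataclass
class DurationThresholds:
    """Minimum event duration (s) per SD level; math.inf marks a level at
    which no duration achieved the required positive:negative ratio."""

    durations_s: Dict[int, float]
    bin_s: float
    event_ratio: float
    n_pos: Dict[int, int] = field(default_factory=dict)
    n_neg: Dict[int, int] = field(default_factory=dict)
    n_traces: int = 0

    def finite_levels(self) -> List[int]:
        return [k for k, d in sorted(self.durations_s.items()) if math.isfinite(d)]

    def duration_bins(self, k: int) -> float:
        d = self.durations_s[k]
        return d / self.bin_s if math.isfinite(d) else math.inf


@dataclass
class TransientEvent:
    """One significant positive ΔF/F excursion."""

    onset_s: float
    offset_s: float
    peak_dff: float
    sd_level: int  # highest SD level satisfied
    source: str = ""

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def _trace_stats(trace: DffTrace, config: AnalysisConfig,
                 rest_mask: Optional[np.ndarray] = None) -> Tuple[float, float]:
    x = trace.dff
    if config.calibration_scope == "rest":
        if rest_mask is None or not np.any(rest_mask):
            raise ValueError("calibration_scope='rest' requires a rest mask")
        x = x[rest_mask]
    return float(x.mean()), float(x.std())


def _run_lengths(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return np.array([j - i for i, j in _runs(mask)], dtype=int)


def calibrate_duration_thresholds(
    dff_set: Iterable[DffTrace],
    config: AnalysisConfig,
    rest_masks: Optional[Sequence[np.ndarray]] = None,
) -> DurationThresholds:
    """Calibrate the per-SD-level minimum durations on a pool of recordings.

    For each level k, positive events are maximal runs of ΔF/F above
    mean + k·SD and negative events maximal runs below mean − k·SD (mean
    and SD per trace, pooled event durations across traces).  d_k is the
    smallest whole-bin duration at which

        N_pos(≥d) / (N_pos(≥d) + N_neg(≥d)) ≥ config.event_ratio

    with at least one positive event remaining; levels where no duration
    qualifies get d_k = inf and are unusable for detection.
    """
    traces = list(dff_set)
    if not traces:
        raise ValueError("empty calibration set")
    bin_s = traces[0].bin_s
    total_s = sum(t.dff.size for t in traces) * bin_s
    if total_s < 60.0:
        raise ValueError("calibration requires at least 60 s of signal")

    pos_runs: Dict[int, List[np.ndarray]] = {k: [] for k in config.sd_levels}
    neg_runs: Dict[int, List[np.ndarray]] = {k: [] for k in config.sd_levels}
    for idx, tr in enumerate(traces):
        if abs(tr.bin_s - bin_s) > 1e-12:
            raise ValueError("all calibration traces must share bin_s")
        rm = rest_masks[idx] if rest_masks is not None else None
        mu, sd = _trace_stats(tr, config, rm)
        if sd == 0:
            raise ValueError("trace SD is zero; cannot calibrate")
        x = tr.dff
        for k in config.sd_levels:
            pos_runs[k].append(_run_lengths(x, x > mu + k * sd))
            neg_runs[k].append(_run_lengths(x, x < mu - k * sd))

    durations: Dict[int, float] = {}
    n_pos: Dict[int, int] = {}
    n_neg: Dict[int, int] = {}
    for k in config.sd_levels:
        p = np.concatenate(pos_runs[k]) if pos_runs[k] else np.array([], dtype=int)
        q = np.concatenate(neg_runs[k]) if neg_runs[k] else np.array([], dtype=int)
        n_pos[k], n_neg[k] = int(p.size), int(q.size)
        durations[k] = _min_duration(p, q, config) * bin_s if p.size else math.inf
        if not math.isfinite(durations[k]):
            logger.info("SD level %d: no duration reaches ratio %.3f; level unusable",
                        k, config.event_ratio)
    return DurationThresholds(
        durations_s=durations,
        bin_s=bin_s,
        event_ratio=config.event_ratio,
        n_pos=n_pos,
        n_neg=n_neg,
        n_traces=len(traces),
    )


def _min_duration(pos: np.ndarray, neg: np.ndarray, config: AnalysisConfig) -> float:
    """Smallest duration (bins) meeting the positive:negative ratio rule."""
    if pos.size == 0:
        return math.inf
    for d in range(1, int(pos.max()) + 1):
        np_ = int((pos >= d).sum())
        nn = int((neg >= d).sum())
        if np_ == 0:
            return math.inf
        if config.ratio_mode == "fraction_of_total":
            ok = np_ / (np_ + nn) >= config.event_ratio
        else:  # literal N_pos / N_neg ratio
            ok = nn == 0 or np_ / nn >= config.event_ratio
        if ok:
            return float(d)
    return math.inf


def detect_transients(
    dff: DffTrace,
    thresholds: DurationThresholds,
    config: Optional[AnalysisConfig] = None,
    source: str = "",
    rest_mask: Optional[np.ndarray] = None,
) -> List[TransientEvent]:
    """Detect significant positive transients in one trace.

    For every SD level with a finite calibrated duration, runs above
    mean + k·SD lasting at least d_k are accepted; accepted runs that
    overlap across levels merge into one event whose onset comes from the
    lowest accepted level (earliest physiological start) and whose
    ``sd_level`` is the highest level satisfied.
    """
    config = config or AnalysisConfig()
    if abs(dff.bin_s - thresholds.bin_s) > 1e-12:
        raise ValueError("thresholds calibrated at a different bin width")
    mu, sd = _trace_stats(dff, config, rest_mask)
    if sd == 0:
        return []
    x = dff.dff
    accepted: List[Tuple[int, int, int]] = []  # (start, stop, level)
    for k in thresholds.finite_levels():
        need = int(round(thresholds.duration_bins(k)))
        for i, j in _runs(x > mu + k * sd):
            if j - i >= need:
                accepted.append((i, j, k))
    if not accepted:
        return []
    accepted.sort()
    merged: List[List[int]] = []
    for i, j, k in accepted:
        if merged and i < merged[-1][1]:  # overlap with current cluster
            merged[-1][1] = max(merged[-1][1], j)
            merged[-1][2] = max(merged[-1][2], k)
        else:
            merged.append([i, j, k])
    events = [
        TransientEvent(
            onset_s=dff.t0 + i * dff.bin_s,
            offset_s=dff.t0 + j * dff.bin_s,
            peak_dff=float(x[i:j].max()),
            sd_level=k,
            source=source,
        )
        for i, j, k in merged
    ]
    events.sort(key=lambda e: e.onset_s)
    return events


def noise_event_counts(
    dff: DffTrace,
    thresholds: DurationThresholds,
    config: Optional[AnalysisConfig] = None,
) -> Tuple[int, int]:
    """Count positive and mirrored negative events at the calibrated
    durations (false-positive control: on signal-free traces a detected
    event of either sign is a false event)."""
    config = config or AnalysisConfig()
    mu, sd = _trace_stats(dff, config)
    x = dff.dff
    n_pos = n_neg = 0
    for k in thresholds.finite_levels():
        need = int(round(thresholds.duration_bins(k)))
        n_pos += sum(1 for i, j in _runs(x > mu + k * sd) if j - i >= need)
        n_neg += sum(1 for i, j in _runs(x < mu - k * sd) if j - i >= need)
    return n_pos, n_neg


def transient_state_metrics(
    events: Sequence[TransientEvent],
    dff: DffTrace,
    annotation: BehaviorAnnotation,
    config: Optional[AnalysisConfig] = None,
) -> Dict[str, Dict[str, float]]:
    """Per-state mean transient ΔF/F and transient rate.

    The transient-masked trace equals ΔF/F inside detected events and 0
    elsewhere; its mean is taken over the bins of each state.  States:
    ``rest`` and ``movement`` from the per-bin labels, ``onset`` = bins in
    the onset epoch window around clean onsets, ``locomotion`` = bins in
    continuous-locomotion bouts.  Rates count event onsets per minute of
    state time.  States with no bins report NaN.
    """
    config = config or AnalysisConfig()
    x = dff.dff
    masked = np.zeros_like(x)
    onset_bins = np.full(x.size, -1, dtype=int)
    for n, ev in enumerate(events):
        i = int(round((ev.onset_s - dff.t0) / dff.bin_s))
        j = int(round((ev.offset_s - dff.t0) / dff.bin_s))
        masked[max(i, 0): j] = x[max(i, 0): j]
        if 0 <= i < x.size:
            onset_bins[i] = n

    # state masks on the dff time base (annotation may use a different bin)
    def resample(mask: np.ndarray) -> np.ndarray:
        if abs(annotation.bin_s - dff.bin_s) < 1e-12 and mask.size == x.size:
            return mask
        t = dff.times
        idx = np.clip(((t - annotation.t0) / annotation.bin_s).astype(int),
                      0, mask.size - 1)
        return mask[idx]

    states = {
        "rest": resample(annotation.mask("rest")),
        "movement": resample(annotation.mask("movement")),
        "onset": resample(annotation.onset_window_mask(config.onset_epoch_window_s)),
        "locomotion": resample(annotation.bout_mask()),
    }
    out: Dict[str, Dict[str, float]] = {}
    for name, m in states.items():
        n_bins = int(m.sum())
        if n_bins == 0:
            out[name] = {"mean_transient_dff": math.nan,
                         "events_per_min": math.nan, "state_s": 0.0}
            continue
        state_s = n_bins * dff.bin_s
        n_ev = int((onset_bins[m] >= 0).sum())
        out[name] = {
            "mean_transient_dff": float(masked[m].mean()),
            "events_per_min": 60.0 * n_ev / state_s,
            "state_s": state_s,
        }
    return out
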