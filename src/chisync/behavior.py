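"""Behavioral state segmentation and movement-event classification.

Treadmill velocity is segmented into movement / rest / unclassified bins
and into typed events:

* clean movement onsets from rest — positive-going 0.2 cm/s crossings with
  a ≥1 cm/s peak within 1 s and no |v| > 0.2 cm/s in the 0.5 s before;
* jerks — clean onsets whose maximum |v| 1–2 s post-crossing stays below
  2.2 cm/s (rapidly terminated movements);
* locomotion initiations — clean onsets whose mean v 0.5–2 s post-crossing
  exceeds 4.5 cm/s;
* continuous-locomotion bouts — >3 s of bout-smoothed v above 4.5 cm/s;
* terminations — the first downward 2.2 cm/s crossing after a bout held
  below threshold for 1 s;
* within-bout velocity peaks/troughs for extrema-aligned averaging.

All thresholds come from :class:`~chisync.config.AnalysisConfig` and are
absolute (cm/s, cm/s²), not scaled to the session.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .preprocessing import Kinematics, smooth_centered

__all__ = [
    "BehaviorAnnotation",
    "label_states",
    "detect_clean_onsets",
    "detect_locomotion_bouts",
    "detect_terminations",
    "detect_velocity_extrema",
    "annotate",
]

EVENT_TYPES = ("jerk", "initiation", "onset_other", "termination", "micro")
LABELS = ("movement", "rest", "unclassified")


@dataclass
class BehaviorAnnotation:
    """Per-bin state labels plus typed movement events for one session."""

    labels: np.ndarray  # str array over bins: movement|rest|unclassified
    events: List[Tuple[float, str]]  # (time_s, type), sorted by time
    bouts: List[Tuple[float, float]]  # [start_s, end_s) continuous locomotion
    velocity_extrema: List[Tuple[float, str]]  # (time_s, peak|trough)
    bin_s: float = 0.01
    t0: float = 0.0

    def event_times(self, *types: str) -> np.ndarray:
        """Times of events of the given type(s) (all types if none given)."""
        sel = types or EVENT_TYPES
        return np.array([t for t, k in self.events if k in sel])

    def onset_times(self) -> np.ndarray:
        """All clean movement onsets (jerk + initiation + other)."""
        return self.event_times("jerk", "initiation", "onset_other")

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def bout_mask(self) -> np.ndarray:
        m = np.zeros(self.labels.size, dtype=bool)
        for a, b in self.bouts:
            i = int(round((a - self.t0) / self.bin_s))
            j = int(round((b - self.t0) / self.bin_s))
            m[max(i, 0): max(j, 0)] = True
        return m

    def onset_window_mask(self, window: Tuple[float, float]) -> np.ndarray:
        """Bins within ``window`` (s, relative) of any clean onset."""
        m = np.zeros(self.labels.size, dtype=bool)
        for t in self.onset_times():
            i = int(np.ceil((t + window[0] - self.t0) / self.bin_s))
            j = int(np.floor((t + window[1] - self.t0) / self.bin_s))
            m[max(i, 0): max(j + 1, 0)] = True
        return m


def _win_bins(s: float, bin_s: float) -> int:
    return int(round(s / bin_s))


def label_states(kin: Kinematics, config: AnalysisConfig) -> np.ndarray:
    """Label each bin movement / rest / unclassified.

    A bin is *movement* if both |v| > 2.2 cm/s and |a| > 40 cm/s² occur
    somewhere within ±1 s of it; *rest* if |v| never exceeds 0.2 cm/s within
    ±1 s.  Bins within 1 s of the trace edges are unclassified.
    """
    w = 2 * _win_bins(config.state_window_s, kin.bin_s) + 1
    vmax = maximum_filter1d(np.abs(kin.velocity), size=w, mode="nearest")
    amax = maximum_filter1d(np.abs(kin.acceleration), size=w, mode="nearest")

    labels = np.full(kin.n_bins, "unclassified", dtype=object)
    labels[(vmax > config.movement_velocity_cmps)
           & (amax > config.movement_accel_cmps2)] = "movement"
    labels[vmax <= config.rest_velocity_cmps] = "rest"
    edge = _win_bins(config.state_window_s, kin.bin_s)
    labels[:edge] = "unclassified"
    if edge > 0:
        labels[-edge:] = "unclassified"
    return labels.astype(str)


def detect_clean_onsets(
    kin: Kinematics, config: AnalysisConfig
) -> List[Tuple[float, str]]:
    """Find clean movement onsets from rest and classify each.

    Returns (time_s, type) with type in {jerk, initiation, onset_other};
    a crossing satisfying both (adversarial traces) or neither rule is
    ``onset_other``.  Crossing time is the first bin strictly above
    0.2 cm/s; onsets too close to the trace edges to evaluate the 2 s
    post-windows (or the 0.5 s pre-window) are dropped.
    """
    v = kin.velocity
    b = kin.bin_s
    thr = config.rest_velocity_cmps
    cross = np.flatnonzero((v[1:] > thr) & (v[:-1] <= thr)) + 1

    pre = _win_bins(config.pre_quiet_s, b)
    peak_w = _win_bins(config.onset_peak_window_s, b)
    j0, j1 = (_win_bins(s, b) for s in config.jerk_window_s)
    i0, i1 = (_win_bins(s, b) for s in config.initiation_window_s)
    post = max(j1, i1, peak_w)

    out: List[Tuple[float, str]] = []
    for c in cross:
        if c - pre < 0 or c + post >= v.size:
            continue
        if np.any(np.abs(v[c - pre: c]) > thr):
            continue  # not preceded by quiescence
        if np.max(v[c: c + peak_w + 1]) < config.onset_min_peak_cmps:
            continue  # too small to count as an onset
        is_jerk = np.max(np.abs(v[c + j0: c + j1 + 1])) < config.movement_velocity_cmps
        is_init = np.mean(v[c + i0: c + i1 + 1]) > config.bout_velocity_cmps
        if is_jerk and not is_init:
            kind = "jerk"
        elif is_init and not is_jerk:
            kind = "initiation"
        else:
            kind = "onset_other"
        out.append((kin.t0 + c * b, kind))
    return out


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal True runs of ``mask`` as half-open [start, stop) index pairs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(m.size)
    return list(zip(starts, stops))


def detect_locomotion_bouts(
    kin: Kinematics, config: AnalysisConfig
) -> List[Tuple[float, float]]:
    """Maximal intervals of bout-smoothed velocity above 4.5 cm/s lasting
    strictly longer than 3 s.

    Bout detection uses an additional 250 ms centered smoothing so that
    stride-cycle velocity dips do not fragment bouts.
    """
    w = max(1, _win_bins(config.smooth_bout_s, kin.bin_s))
    vs = smooth_centered(kin.velocity, w)
    out = []
    for i, j in _runs(vs > config.bout_velocity_cmps):
        if (j - i) * kin.bin_s > config.bout_min_s:
            out.append((kin.t0 + i * kin.bin_s, kin.t0 + j * kin.bin_s))
    return out


def detect_terminations(
    kin: Kinematics,
    bouts: List[Tuple[float, float]],
    config: AnalysisConfig,
) -> List[float]:
    """First downward 2.2 cm/s crossing after each bout that then stays
    below 2.2 cm/s for 1 s.  Bouts whose ends re-accelerate before any
    qualifying crossing (before the next bout) yield no termination."""
    v = kin.velocity
    b = kin.bin_s
    thr = config.movement_velocity_cmps
    hold = _win_bins(config.termination_hold_s, b)
    out: List[float] = []
    bout_starts = [int(round((a - kin.t0) / b)) for a, _ in bouts]
    for n, (_, end) in enumerate(bouts):
        i = int(round((end - kin.t0) / b))
        limit = bout_starts[n + 1] if n + 1 < len(bouts) else v.size
        while i < limit:
            if np.abs(v[i]) < thr:
                if i + hold <= v.size and np.all(np.abs(v[i: i + hold]) < thr):
                    out.append(kin.t0 + i * b)
                    break
                # hold violated: skip past the sub-threshold stretch
                while i < limit and np.abs(v[i]) < thr:
                    i += 1
            else:
                i += 1
    return out


def detect_velocity_extrema(
    kin: Kinematics,
    bouts: List[Tuple[float, float]],
    config: AnalysisConfig,
) -> List[Tuple[float, str]]:
    """Local velocity peaks and troughs inside bouts (on bout-smoothed
    velocity, prominence ≥ ``extrema_prominence_cmps``)."""
    w = max(1, _win_bins(config.smooth_bout_s, kin.bin_s))
    vs = smooth_centered(kin.velocity, w)
    out: List[Tuple[float, str]] = []
    for a, e in bouts:
        i = int(round((a - kin.t0) / kin.bin_s))
        j = int(round((e - kin.t0) / kin.bin_s))
        seg = vs[i:j]
        if seg.size < 3:
            continue
        pk, _ = find_peaks(seg, prominence=config.extrema_prominence_cmps)
        tr, _ = find_peaks(-seg, prominence=config.extrema_prominence_cmps)
        out += [(kin.t0 + (i + p) * kin.bin_s, "peak") for p in pk]
        out += [(kin.t0 + (i + t) * kin.bin_s, "trough") for t in tr]
    out.sort()
    return out


def annotate(kin: Kinematics, config: AnalysisConfig) -> BehaviorAnnotation:
    """Full behavioral annotation of one session's kinematics."""
    labels = label_states(kin, config)
    onsets = detect_clean_onsets(kin, config)
    bouts = detect_locomotion_bouts(kin, config)
    terms = detect_terminations(kin, bouts, config)
    extrema = detect_velocity_extrema(kin, bouts, config)
    events = sorted(onsets + [(t, "termination") for t in terms])
    return BehaviorAnnotation(
        labels=labels,
        events=events,
        bouts=bouts,
        velocity_extrema=extrema,
        bin_s=kin.bin_s,
        t0=kin.t0,
    )
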