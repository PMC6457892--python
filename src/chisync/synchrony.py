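"""Pairwise single-cell synchrony within behavioral epochs.

For every simultaneously imaged cell pair, the ΔF/F snippets belonging to
one behavioral epoch (rest bins, −0.1…+2 s windows around movement onsets,
or continuous-locomotion bouts) are concatenated and the lagged Pearson
cross-correlogram computed (±1 s).  Peak correlation, peak lag and the
anatomical distance between ROI centroids feed the distance-dependence
regression; clustered transient onsets across cells give the per-event
co-activation fraction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .behavior import BehaviorAnnotation
from .config import AnalysisConfig
from .preprocessing import DffTrace
from .transients import TransientEvent
from .xcorr import cross_correlogram, lag_axis, peak_and_trough

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelation",
    "SessionExcluded",
    "epoch_intervals",
    "pairwise_xcorr_by_state",
    "correlation_vs_distance",
    "coactivation_fraction",
]

EPOCHS = ("rest", "onset", "locomotion", "all")


class SessionExcluded(RuntimeError):
    """Raised when a session has too little time in a required epoch."""


@dataclass
class PairCorrelation:
    cell_a: int
    cell_b: int
    distance_um: float
    lags_s: np.ndarray
    correlogram: np.ndarray
    peak_r: float
    peak_lag_s: float
    zero_lag_r: float
    epoch: str
    field_id: int = 0


def epoch_intervals(
    annotation: BehaviorAnnotation,
    epoch: str,
    config: AnalysisConfig,
    total_s: Optional[float] = None,
) -> List[Tuple[float, float]]:
    """Time intervals [start, end) making up a behavioral epoch."""
    if epoch == "all":
        end = total_s if total_s is not None else (
            annotation.t0 + annotation.labels.size * annotation.bin_s)
        return [(annotation.t0, end)]
    if epoch == "locomotion":
        return list(annotation.bouts)
    if epoch == "onset":
        w0, w1 = config.onset_epoch_window_s
        return [(t + w0, t + w1) for t in annotation.onset_times()]
    if epoch == "rest":
        m = annotation.mask("rest")
        out = []
        for i, j in _mask_runs(m):
            out.append((annotation.t0 + i * annotation.bin_s,
                        annotation.t0 + j * annotation.bin_s))
        return out
    raise ValueError(f"unknown epoch {epoch!r}")


def _mask_runs(m: np.ndarray) -> List[Tuple[int, int]]:
    from .behavior import _runs
    return _runs(m)


def _concat_epoch(trace: DffTrace, intervals: Sequence[Tuple[float, float]]) -> np.ndarray:
    t = trace.times
    sel = np.zeros(t.size, dtype=bool)
    for a, b in intervals:
        sel |= (t >= a) & (t < b)
    return trace.dff[sel]


def pairwise_xcorr_by_state(
    cells: Sequence[DffTrace],
    annotation: BehaviorAnnotation,
    epoch: str,
    config: Optional[AnalysisConfig] = None,
    positions_um: Optional[np.ndarray] = None,
    field_id: int = 0,
) -> List[PairCorrelation]:
    """Cross-correlograms for every cell pair over one behavioral epoch.

    Raises :class:`SessionExcluded` when the epoch totals less than
    ``config.min_epoch_s`` (the session-inclusion rule).
    """
    config = config or AnalysisConfig()
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    bin_s = cells[0].bin_s
    intervals = epoch_intervals(annotation, epoch, config,
                                total_s=cells[0].t0 + cells[0].dff.size * bin_s)
    concat = [_concat_epoch(c, intervals) for c in cells]
    epoch_s = concat[0].size * bin_s
    if epoch_s < config.min_epoch_s:
        raise SessionExcluded(
            f"epoch {epoch!r} totals {epoch_s:.2f} s < {config.min_epoch_s} s")

    max_lag = int(round(config.max_lag_s / bin_s))
    lags = lag_axis(max_lag, bin_s)
    zero = max_lag
    out: List[PairCorrelation] = []
    for ia, ib in itertools.combinations(range(len(cells)), 2):
        r = cross_correlogram(concat[ia], concat[ib], max_lag)
        peak_r, peak_lag, _, _ = peak_and_trough(r, bin_s)
        dist = math.nan
        if positions_um is not None:
            dist = float(np.linalg.norm(positions_um[ia] - positions_um[ib]))
        out.append(PairCorrelation(
            cell_a=ia, cell_b=ib, distance_um=dist, lags_s=lags,
            correlogram=r, peak_r=peak_r, peak_lag_s=peak_lag,
            zero_lag_r=float(r[zero]), epoch=epoch, field_id=field_id,
        ))
    return out


def correlation_vs_distance(
    pairs: Sequence[PairCorrelation],
    config: Optional[AnalysisConfig] = None,
    per_field: bool = False,
    use: str = "peak_r",
) -> Dict[str, object]:
    """Linear regression of pairwise correlation on centroid distance.

    Per-field regressions are reported only for fields contributing more
    than ``config.min_pairs_per_field`` pairs.
    """
    config = config or AnalysisConfig()
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    d = np.array([p.distance_um for p in pairs])
    r = np.array([getattr(p, use) for p in pairs])
    if np.any(~np.isfinite(d)):
        raise ValueError("pairs lack distances")
    fit = stats.linregress(d, r)
    out: Dict[str, object] = {
        "slope_per_um": float(fit.slope), "intercept": float(fit.intercept),
        "pearson_r": float(fit.rvalue), "p_value": float(fit.pvalue),
        "n_pairs": len(pairs),
    }
    if per_field:
        fields: Dict[int, List[PairCorrelation]] = {}
        for p in pairs:
            fields.setdefault(p.field_id, []).append(p)
        per = {}
        for fid, ps in fields.items():
            if len(ps) > config.min_pairs_per_field:
                sub = correlation_vs_distance(ps, config, per_field=False, use=use)
                per[fid] = sub
        out["per_field"] = per
    return out


def _epoch_of_time(
    t: float, annotation: BehaviorAnnotation, config: AnalysisConfig
) -> str:
    w0, w1 = config.onset_epoch_window_s
    for on in annotation.onset_times():
        if on + w0 <= t < on + w1:
            return "onset"
    for a, b in annotation.bouts:
        if a <= t < b:
            return "locomotion"
    i = int((t - annotation.t0) / annotation.bin_s)
    if 0 <= i < annotation.labels.size and annotation.labels[i] == "rest":
        return "rest"
    return "other"


def coactivation_fraction(
    cell_transients: Sequence[Sequence[TransientEvent]],
    annotation: BehaviorAnnotation,
    config: Optional[AnalysisConfig] = None,
) -> Dict[str, object]:
    """Fraction of cells participating in each population transient event.

    Transient onsets pooled across cells are clustered by single linkage
    with a ``coactivation_window_s`` gap; a cell is active in an event if
    it has an onset within the cluster span ± window/2.  Clusters with
    fewer than ``coactivation_min_cells`` distinct cells are not population
    events and are dropped.  Events are assigned to the epoch containing
    their earliest onset.
    """
    config = config or AnalysisConfig()
    n_cells = len(cell_transients)
    onsets = []  # (time, cell)
    for ci, evs in enumerate(cell_transients):
        onsets += [(e.onset_s, ci) for e in evs]
    if not onsets:
        return {"events": [], "by_epoch": {}}
    onsets.sort()
    w = config.coactivation_window_s
    clusters: List[List[Tuple[float, int]]] = [[onsets[0]]]
    for t, c in onsets[1:]:
        if t - clusters[-1][-1][0] <= w:
            clusters[-1].append((t, c))
        else:
            clusters.append([(t, c)])

    events = []
    for cl in clusters:
        t_first, t_last = cl[0][0], cl[-1][0]
        active = {c for t, c in cl if t_first - w / 2 <= t <= t_last + w / 2}
        if len(active) < config.coactivation_min_cells:
            continue
        epoch = _epoch_of_time(t_first, annotation, config)
        events.append({
            "time_s": t_first,
            "fraction": len(active) / n_cells,
            "n_active": len(active),
            "epoch": epoch,
        })
    by_epoch: Dict[str, float] = {}
    for ep in ("rest", "onset", "locomotion"):
        fr = [e["fraction"] for e in events if e["epoch"] == ep]
        by_epoch[ep] = float(np.mean(fr)) if fr else math.nan
    return {"events": events, "by_epoch": by_epoch}
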