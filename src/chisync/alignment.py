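"""Event-triggered averaging and trialwise response analyses.

Signals are cut into per-event snippets on a common lag axis, averaged
with ±SEM, and tested binwise against pooled rest values (two-sided
Wilcoxon rank-sum, p < 0.01, uncorrected — optional Benjamini–Hochberg).
Also: peak-normalized per-event matrices, trialwise response-vs-velocity-
change regression for reward deliveries, and realignment of triggers to
the first following event of a secondary stream (e.g. first spout lick).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import AnalysisConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TriggeredAverage",
    "triggered_average",
    "per_event_matrix",
    "trial_response_vs_velocity_change",
    "realign_to_first_event",
]


@dataclass
class TriggeredAverage:
    lags_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    per_event: np.ndarray  # events × lags
    significance_mask: Optional[np.ndarray] = None
    n_dropped: int = 0


def _snippets(
    trace: np.ndarray,
    bin_s: float,
    t0: float,
    event_times: Sequence[float],
    window_s: Tuple[float, float],
) -> Tuple[np.ndarray, np.ndarray, int]:
    lo = int(round(window_s[0] / bin_s))
    hi = int(round(window_s[1] / bin_s))
    lags = np.arange(lo, hi + 1) * bin_s
    rows, dropped = [], 0
    for t in event_times:
        c = int(round((t - t0) / bin_s))
        if c + lo < 0 or c + hi >= trace.size:
            dropped += 1
            continue
        rows.append(trace[c + lo: c + hi + 1])
    if dropped:
        logger.info("dropped %d events without full window coverage", dropped)
    mat = np.array(rows) if rows else np.empty((0, lags.size))
    return mat, lags, dropped


def triggered_average(
    trace: np.ndarray,
    event_times: Sequence[float],
    window_s: Tuple[float, float] = (-2.0, 4.0),
    rest_values: Optional[np.ndarray] = None,
    bin_s: float = 0.01,
    t0: float = 0.0,
    alpha: float = 0.01,
    fdr: bool = False,
) -> TriggeredAverage:
    """Event-triggered mean ± SEM, with optional binwise significance
    versus pooled rest values.

    A lag is marked significant when the per-event values differ from the
    rest pool (two-sided rank-sum p < ``alpha``) *and* their mean exceeds
    the rest mean.  Events without full window coverage are dropped.
    """
    mat, lags, dropped = _snippets(trace, bin_s, t0, event_times, window_s)
    if mat.shape[0] == 0:
        raise ValueError("no events with full window coverage")
    mean = mat.mean(axis=0)
    n = mat.shape[0]
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)

    mask = None
    if rest_values is not None and rest_values.size:
        rest_mean = rest_values.mean()
        pvals = np.ones(lags.size)
        for i in range(lags.size):
            col = mat[:, i]
            if np.ptp(col) == 0 and np.ptp(rest_values) == 0 and col[0] == rest_values[0]:
                continue
            pvals[i] = stats.ranksums(col, rest_values).pvalue
        if fdr:
            order = np.argsort(pvals)
            ranked = pvals[order] * pvals.size / (np.arange(pvals.size) + 1)
            ranked = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty_like(pvals)
            adj[order] = np.minimum(ranked, 1.0)
            pvals = adj
        mask = (pvals < alpha) & (mean > rest_mean)
    return TriggeredAverage(
        lags_s=lags, mean=mean, sem=sem, n_events=n, per_event=mat,
        significance_mask=mask, n_dropped=dropped,
    )


def per_event_matrix(per_event: np.ndarray, post_only_from: int = 0) -> np.ndarray:
    """Peak-normalize each row and sort rows by descending post-event peak.

    Each row is divided by its maximum |value| (all-zero rows stay zero);
    rows are then ordered by the peak of the normalized response from
    column ``post_only_from`` on.  Ties preserve the original order.
    """
    mat = np.asarray(per_event, dtype=float)
    if mat.shape[0] < 1:
        raise ValueError("need at least one event")
    scale = np.abs(mat).max(axis=1)
    safe = np.where(scale == 0, 1.0, scale)
    norm = mat / safe[:, None]
    peaks = norm[:, post_only_from:].max(axis=1)
    order = np.argsort(-peaks, kind="stable")
    return norm[order]


def trial_response_vs_velocity_change(
    dff: np.ndarray,
    velocity: np.ndarray,
    trial_times: Sequence[float],
    config: Optional[AnalysisConfig] = None,
    bin_s: float = 0.01,
    t0: float = 0.0,
) -> Dict[str, object]:
    """Per-trial (mean ΔF/F response, Δvelocity) pairs with Pearson R.

    Response = mean ΔF/F in the post window (default 0…+1 s); Δv = mean
    velocity in the post window minus the pre window (default −1…0 s).
    Also returns triggered averages for the top and bottom quartile of Δv
    (accelerate-from-rest vs decelerate-from-locomotion trials).
    """
    config = config or AnalysisConfig()
    if len(trial_times) < 3:
        raise ValueError("need at least 3 trials")
    r0, r1 = config.response_window_s
    p0, p1 = config.dv_pre_window_s
    resp, dv, used = [], [], []
    for t in trial_times:
        c = int(round((t - t0) / bin_s))
        i0, i1 = c + int(round(r0 / bin_s)), c + int(round(r1 / bin_s))
        j0, j1 = c + int(round(p0 / bin_s)), c + int(round(p1 / bin_s))
        if j0 < 0 or i1 >= dff.size:
            continue
        resp.append(dff[i0:i1 + 1].mean())
        dv.append(velocity[i0:i1 + 1].mean() - velocity[j0:j1 + 1].mean())
        used.append(t)
    if len(used) < 3:
        raise ValueError("fewer than 3 trials with full window coverage")
    resp_a, dv_a = np.array(resp), np.array(dv)
    r, p = stats.pearsonr(dv_a, resp_a)

    q = len(used) // 4
    result: Dict[str, object] = {
        "trial_times": np.array(used), "response": resp_a, "dvelocity": dv_a,
        "pearson_r": float(r), "p_value": float(p), "n_trials": len(used),
    }
    if q >= 1:
        order = np.argsort(dv_a)
        bottom = [used[i] for i in order[:q]]
        top = [used[i] for i in order[-q:]]
        win = config.triggered_window_s
        for name, times in (("top", top), ("bottom", bottom)):
            result[f"{name}_quartile_dff"] = triggered_average(
                dff, times, win, None, bin_s, t0)
            result[f"{name}_quartile_velocity"] = triggered_average(
                velocity, times, win, None, bin_s, t0)
    return result


def realign_to_first_event(
    primary_times: Sequence[float],
    secondary_stream: Sequence[float],
    max_latency_s: float,
) -> Tuple[np.ndarray, int]:
    """For each primary trigger, the first secondary event within
    (0, max_latency] s; primaries without one are dropped and counted."""
    sec = np.asarray(secondary_stream, dtype=float)
    out, dropped = [], 0
    for t in primary_times:
        after = sec[(sec > t) & (sec <= t + max_latency_s)]
        if after.size:
            out.append(after[0])
        else:
            dropped += 1
    return np.array(out), dropped
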