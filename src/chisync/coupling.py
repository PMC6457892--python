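"""Dual-population (ChI/DA) coupling analyses.

Cross-correlograms between two population signals or between a signal and
a kinematic channel, with peak *and* trough lags (positive lag = channel B
lags channel A); quartile-conditional triggered averages splitting primary
transients by the companion population's amplitude; and joint z(ChI) ×
z(DA) maps of the velocity outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .alignment import TriggeredAverage, triggered_average
from .config import AnalysisConfig
from .transients import TransientEvent
from .xcorr import cross_correlogram, lag_axis, peak_and_trough

__all__ = [
    "CouplingResult",
    "population_xcorr",
    "kinematic_xcorr",
    "quartile_conditional_average",
    "joint_signal_velocity_map",
]


@dataclass
class CouplingResult:
    lags_s: np.ndarray
    correlogram: np.ndarray
    peak_r: float
    peak_lag_s: float
    trough_r: float
    trough_lag_s: float
    epoch: str = "all"
    convention: str = "positive lag: B lags A"
    n_bins: int = 0


def population_xcorr(
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    epoch_mask: Optional[np.ndarray] = None,
    config: Optional[AnalysisConfig] = None,
    bin_s: float = 0.01,
    epoch: str = "all",
) -> CouplingResult:
    """Lagged Pearson cross-correlogram between two population signals
    over the masked region (whole session when no mask is given)."""
    config = config or AnalysisConfig()
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signals must share length and bin width")
    if epoch_mask is not None:
        m = np.asarray(epoch_mask, dtype=bool)
        if m.sum() * bin_s < config.min_epoch_s:
            raise ValueError(
                f"epoch {epoch!r} shorter than {config.min_epoch_s} s")
        a, b = a[m], b[m]
    max_lag = int(round(config.max_lag_s / bin_s))
    r = cross_correlogram(a, b, max_lag)
    peak_r, peak_lag, trough_r, trough_lag = peak_and_trough(r, bin_s)
    return CouplingResult(
        lags_s=lag_axis(max_lag, bin_s), correlogram=r,
        peak_r=peak_r, peak_lag_s=peak_lag,
        trough_r=trough_r, trough_lag_s=trough_lag,
        epoch=epoch, n_bins=a.size,
    )


def kinematic_xcorr(
    dff: np.ndarray,
    kin_channel: np.ndarray,
    epoch_mask: Optional[np.ndarray] = None,
    config: Optional[AnalysisConfig] = None,
    bin_s: float = 0.01,
    epoch: str = "all",
) -> CouplingResult:
    """Cross-correlogram between ΔF/F and a kinematic channel (velocity or
    acceleration); same machinery and conventions as
    :func:`population_xcorr` with B = the kinematic channel."""
    return population_xcorr(dff, kin_channel, epoch_mask, config, bin_s, epoch)


def quartile_conditional_average(
    primary_transients: Sequence[TransientEvent],
    companion_dff: np.ndarray,
    velocity: np.ndarray,
    epoch_times: Optional[Tuple[float, float]] = None,
    config: Optional[AnalysisConfig] = None,
    bin_s: float = 0.01,
    t0: float = 0.0,
    primary_dff: Optional[np.ndarray] = None,
) -> Dict[str, object]:
    """Triggered averages split by companion-signal amplitude quartile.

    Each primary transient is scored by the mean companion ΔF/F in a
    window around its onset (default −0.1…+0.5 s); the top and bottom
    quartiles (⌊n/4⌋ each) yield separate velocity- (and signal-)
    triggered averages, alongside the all-transient mean.  Requires at
    least 8 transients for the quartiles to be meaningful.
    """
    config = config or AnalysisConfig()
    times = [e.onset_s for e in primary_transients]
    if epoch_times is not None:
        a, b = epoch_times
        times = [t for t in times if a <= t < b]
    if len(times) < 8:
        raise ValueError("need at least 8 primary transients in the epoch")
    w0, w1 = config.companion_window_s
    amps, used = [], []
    for t in times:
        c = int(round((t - t0) / bin_s))
        i0, i1 = c + int(round(w0 / bin_s)), c + int(round(w1 / bin_s))
        if i0 < 0 or i1 >= companion_dff.size:
            continue
        amps.append(companion_dff[i0:i1 + 1].mean())
        used.append(t)
    if len(used) < 8:
        raise ValueError("fewer than 8 transients with companion coverage")
    amps_a = np.array(amps)
    degenerate = bool(np.ptp(amps_a) == 0)
    q = len(used) // 4
    order = np.argsort(amps_a, kind="stable")
    bottom = [used[i] for i in order[:q]]
    top = [used[i] for i in order[-q:]]

    win = config.triggered_window_s
    out: Dict[str, object] = {
        "n_transients": len(used),
        "companion_amplitude": amps_a,
        "degenerate_split": degenerate,
        "top_times": np.array(top),
        "bottom_times": np.array(bottom),
        "all_velocity": triggered_average(velocity, used, win, None, bin_s, t0),
        "top_velocity": triggered_average(velocity, top, win, None, bin_s, t0),
        "bottom_velocity": triggered_average(velocity, bottom, win, None, bin_s, t0),
        "top_companion": triggered_average(companion_dff, top, win, None, bin_s, t0),
        "bottom_companion": triggered_average(companion_dff, bottom, win, None, bin_s, t0),
    }
    if primary_dff is not None:
        out["top_primary"] = triggered_average(primary_dff, top, win, None, bin_s, t0)
        out["bottom_primary"] = triggered_average(primary_dff, bottom, win, None, bin_s, t0)
    return out


def delta_velocity(
    velocity: np.ndarray,
    times: Sequence[float],
    config: Optional[AnalysisConfig] = None,
    bin_s: float = 0.01,
    t0: float = 0.0,
) -> np.ndarray:
    """Post-minus-pre mean velocity change around each time (post 0…+1 s,
    pre −0.5…0 s by default); NaN where the windows run off the trace."""
    config = config or AnalysisConfig()
    a0, a1 = config.outcome_post_window_s
    b0, b1 = config.outcome_pre_window_s
    out = np.full(len(times), np.nan)
    for n, t in enumerate(times):
        c = int(round((t - t0) / bin_s))
        i0, i1 = c + int(round(a0 / bin_s)), c + int(round(a1 / bin_s))
        j0, j1 = c + int(round(b0 / bin_s)), c + int(round(b1 / bin_s))
        if j0 < 0 or i1 >= velocity.size:
            continue
        out[n] = velocity[i0:i1 + 1].mean() - velocity[j0:j1 + 1].mean()
    return out


def joint_signal_velocity_map(
    z_a: np.ndarray,
    z_b: np.ndarray,
    velocity: np.ndarray,
    config: Optional[AnalysisConfig] = None,
    bin_s: float = 0.01,
    t0: float = 0.0,
    mode: str = "locomotion",
    epoch_mask: Optional[np.ndarray] = None,
    transient_times: Optional[Sequence[float]] = None,
) -> Dict[str, object]:
    """Mean velocity outcome on a 2-D grid of (z_A, z_B) values.

    ``mode='locomotion'``: samples are time bins inside the epoch mask and
    the outcome is the velocity in the same bin.  ``mode='transient'``:
    samples are transient events; z values are read at the event onset and
    the outcome is the post-minus-pre velocity change.  Grid cells with
    fewer than ``config.map_min_count`` samples are masked (NaN).
    """
    config = config or AnalysisConfig()
    edges = np.arange(config.map_z_low,
                      config.map_z_high + config.map_z_width / 2,
                      config.map_z_width)
    if mode == "locomotion":
        m = (np.ones(z_a.size, dtype=bool) if epoch_mask is None
             else np.asarray(epoch_mask, dtype=bool))
        xa, xb, y = z_a[m], z_b[m], velocity[m]
    elif mode == "transient":
        if not transient_times:
            raise ValueError("transient mode requires transient_times")
        idx = np.array([int(round((t - t0) / bin_s)) for t in transient_times])
        ok = (idx >= 0) & (idx < z_a.size)
        dv = delta_velocity(velocity, list(np.asarray(transient_times)[ok]),
                            config, bin_s, t0)
        keep = np.isfinite(dv)
        xa, xb, y = z_a[idx[ok]][keep], z_b[idx[ok]][keep], dv[keep]
    else:
        raise ValueError("mode must be 'locomotion' or 'transient'")
    if xa.size == 0:
        raise ValueError("no samples fall on the map grid")

    nb = edges.size - 1
    ia = np.digitize(xa, edges) - 1
    ib = np.digitize(xb, edges) - 1
    ok = (ia >= 0) & (ia < nb) & (ib >= 0) & (ib < nb)
    grid = np.full((nb, nb), np.nan)
    count = np.zeros((nb, nb), dtype=int)
    sums = np.zeros((nb, nb))
    np.add.at(count, (ia[ok], ib[ok]), 1)
    np.add.at(sums, (ia[ok], ib[ok]), y[ok])
    dense = count >= config.map_min_count
    grid[dense] = sums[dense] / count[dense]
    if not dense.any():
        raise ValueError("no grid cell reaches map_min_count samples")
    return {"grid": grid, "count": count, "edges": edges, "mode": mode,
            "axis": "rows: z_A bins, cols: z_B bins"}
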