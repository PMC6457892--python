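"""Raw trace → binned ΔF/F, kinematics, and rest-referenced z-scores.

Raw fluorescence (PMT output sampled at 1 kHz) and treadmill velocity
(rotary encoder, 1 kHz) are averaged into 10 ms bins.  ΔF/F uses a sliding
8th-percentile baseline over a 16 s window, corrected for fiber/tissue
autofluorescence, with a deterministic two-pass exclusion of transient-
containing bins.  Acceleration is the first difference of 50 ms-smoothed
velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import AnalysisConfig

__all__ = [
    "RawTrace",
    "DffTrace",
    "Kinematics",
    "bin_trace",
    "sliding_percentile",
    "compute_dff",
    "compute_kinematics",
    "zscore_to_rest",
    "smooth_centered",
]


@dataclass
class RawTrace:
    """A uniformly sampled raw channel (fluorescence in arbitrary units, or
    velocity in cm/s)."""

    samples: np.ndarray
    rate_hz: float
    channel_role: str = "ChI_pop"  # ChI_pop | DA_pop | cell | velocity

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")


@dataclass
class DffTrace:
    """ΔF/F series with the baseline it was computed against.

    ``baseline`` is the autofluorescence-corrected baseline (raw units,
    floored strictly positive); ``baseline_raw`` the uncorrected percentile
    baseline.  ``low_confidence`` flags bins whose baseline window was
    truncated by a trace edge.
    """

    dff: np.ndarray
    baseline: np.ndarray
    bin_s: float = 0.01
    t0: float = 0.0
    baseline_raw: Optional[np.ndarray] = None
    low_confidence: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        if self.dff.shape != self.baseline.shape:
            raise ValueError("dff and baseline must have the same length")
        if np.any(self.baseline <= 0):
            raise ValueError("baseline must be strictly positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.dff.size) * self.bin_s


@dataclass
class Kinematics:
    """Smoothed velocity (cm/s) and its derivative (cm/s²) on the analysis
    time base."""

    velocity: np.ndarray
    acceleration: np.ndarray
    bin_s: float = 0.01
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.acceleration = np.asarray(self.acceleration, dtype=float)
        if self.velocity.shape != self.acceleration.shape:
            raise ValueError("velocity and acceleration must share length")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.velocity.size) * self.bin_s

    @property
    def n_bins(self) -> int:
        return self.velocity.size


def bin_trace(raw: RawTrace, bin_s: float) -> np.ndarray:
    """Average ``raw`` into bins of ``bin_s`` seconds.

    The raw sampling rate must be an integer multiple of the bin rate
    (e.g. 1000 Hz into 10 ms bins); a trailing partial bin is dropped.
    """
    per = raw.rate_hz * bin_s
    n_per = int(round(per))
    if n_per <= 0 or abs(per - n_per) > 1e-9:
        raise ValueError(
            f"rate {raw.rate_hz} Hz does not divide into {bin_s} s bins; "
            "resample the trace or analyze at its native rate"
        )
    n_bins = raw.samples.size // n_per
    if n_bins == 0:
        raise ValueError("trace shorter than one bin")
    return raw.samples[: n_bins * n_per].reshape(n_bins, n_per).mean(axis=1)


def smooth_centered(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Centered moving average with windows truncated at the edges."""
    if window_bins <= 1:
        return np.asarray(x, dtype=float).copy()
    kernel = np.ones(window_bins)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def sliding_percentile(
    x: np.ndarray,
    window_bins: int,
    q: float,
    exclude: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-bin ``q``-th percentile over a centered window, truncated at edges.

    ``exclude`` marks bins that are left out of every window they fall in
    (used to drop transient-containing bins on the second baseline pass).
    Windows that lose all their samples to exclusion fall back to the
    unexcluded percentile.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if window_bins > n:
        raise ValueError("trace shorter than the baseline window")
    half = window_bins // 2
    out = np.empty(n)

    if exclude is not None and exclude.any():
        xm = x.copy()
        xm[exclude] = np.nan
    else:
        xm = None

    # interior: vectorized over stacked windows, chunked to bound memory
    lo = half
    hi = n - (window_bins - 1 - half)
    if hi > lo:
        src = xm if xm is not None else x
        win = np.lib.stride_tricks.sliding_window_view(src, window_bins)
        chunk = max(1, 4_000_000 // window_bins)
        for c0 in range(0, hi - lo, chunk):
            c1 = min(c0 + chunk, hi - lo)
            block = win[c0:c1]
            if xm is not None:
                vals = np.nanpercentile(block, q, axis=1)
                # windows fully excluded → fall back to plain percentile
                bad = ~np.isfinite(vals)
                if bad.any():
                    plain = np.lib.stride_tricks.sliding_window_view(
                        x, window_bins)[c0:c1]
                    vals[bad] = np.percentile(plain[bad], q, axis=1)
            else:
                vals = np.percentile(block, q, axis=1)
            out[lo + c0: lo + c1] = vals

    # edges: truncated windows
    for i in list(range(lo)) + list(range(hi, n)):
        a, b = max(0, i - half), min(n, i + (window_bins - half))
        seg = x[a:b]
        if xm is not None:
            segm = xm[a:b]
            segm = segm[np.isfinite(segm)]
            seg = segm if segm.size else seg
        out[i] = np.percentile(seg, q)
    return out


def compute_dff(
    binned: np.ndarray,
    config: AnalysisConfig,
    autofluorescence: float = 0.0,
    bin_s: Optional[float] = None,
    t0: float = 0.0,
) -> DffTrace:
    """Convert a binned raw-fluorescence trace to ΔF/F.

    The baseline for each bin is the ``baseline_percentile``-th percentile
    of raw fluorescence over a centered ``baseline_window_s`` window,
    recomputed on a second pass with transient-containing bins excluded
    (provisional ΔF/F above ``baseline_exclude_nsd`` robust SD).  The
    baseline is then reduced by the session autofluorescence:

        ΔF/F = (F − BaselineF) / (BaselineF − F_auto)

    where the numerator subtracts the uncorrected percentile baseline by
    default (``config.dff_numerator``) and the denominator is the corrected
    baseline, floored strictly positive.
    """
    binned = np.asarray(binned, dtype=float)
    bin_s = config.bin_s if bin_s is None else bin_s
    if autofluorescence < 0:
        raise ValueError("autofluorescence must be non-negative")
    if autofluorescence >= binned.min():
        raise ValueError(
            "autofluorescence >= min(trace): corrected baseline would be "
            "non-positive; check the autofluorescence measurement"
        )
    window_bins = int(round(config.baseline_window_s / bin_s))
    window_bins = max(3, window_bins)

    q = config.baseline_percentile
    base1 = sliding_percentile(binned, window_bins, q)
    # provisional ΔF/F against the pass-1 baseline
    denom1 = np.maximum(base1 - autofluorescence, 1e-12)
    prov = (binned - base1) / denom1
    med = np.median(prov)
    mad = np.median(np.abs(prov - med))
    robust_sd = 1.4826 * mad
    if robust_sd > 0:
        exclude = prov > med + config.baseline_exclude_nsd * robust_sd
        base = sliding_percentile(binned, window_bins, q, exclude=exclude)
    else:
        base = base1

    eps = 1e-9 * max(abs(binned).max(), 1.0)
    corrected = np.maximum(base - autofluorescence, eps)
    num_base = base if config.dff_numerator == "uncorrected" else corrected
    dff = (binned - num_base) / corrected

    half = window_bins // 2
    low_conf = np.zeros(binned.size, dtype=bool)
    low_conf[:half] = True
    low_conf[binned.size - (window_bins - 1 - half):] = True
    return DffTrace(
        dff=dff,
        baseline=corrected,
        bin_s=bin_s,
        t0=t0,
        baseline_raw=base,
        low_confidence=low_conf,
    )


def compute_kinematics(
    velocity_binned: np.ndarray,
    config: AnalysisConfig,
    bin_s: Optional[float] = None,
    t0: float = 0.0,
) -> Kinematics:
    """Smooth binned velocity and differentiate it.

    Velocity is smoothed with a centered ``smooth_velocity_s`` moving
    average; acceleration is the forward difference of the smoothed
    velocity divided by the bin width, with the last bin replicated so the
    arrays stay aligned.
    """
    bin_s = config.bin_s if bin_s is None else bin_s
    v = np.asarray(velocity_binned, dtype=float)
    w = max(1, int(round(config.smooth_velocity_s / bin_s)))
    v_s = smooth_centered(v, w)
    acc = np.empty_like(v_s)
    acc[:-1] = np.diff(v_s) / bin_s
    acc[-1] = acc[-2] if v_s.size > 1 else 0.0
    return Kinematics(velocity=v_s, acceleration=acc, bin_s=bin_s, t0=t0)


def zscore_to_rest(dff: DffTrace, rest_mask: np.ndarray) -> np.ndarray:
    """z-score ΔF/F against the mean and SD of its rest bins."""
    rest_mask = np.asarray(rest_mask, dtype=bool)
    if rest_mask.shape != dff.dff.shape:
        raise ValueError("rest_mask must match the trace length")
    if not rest_mask.any():
        raise ValueError(
            "no rest bins available for z-scoring; relax the behavior "
            "thresholds or skip normalization"
        )
    rest = dff.dff[rest_mask]
    sd = rest.std()
    if sd == 0:
        raise ValueError("rest SD is zero; cannot z-score")
    return (dff.dff - rest.mean()) / sd
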