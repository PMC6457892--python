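"""Lagged Pearson cross-correlograms shared by the pairwise-synchrony and
population-coupling analyses.

Convention: ``r[lag]`` correlates a(t) with b(t + lag), so a *positive*
peak lag means channel B lags channel A.  Series are mean-removed over the
full (masked) region and normalized by the full-region SDs at every lag;
ties in the peak search break toward zero lag.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

__all__ = ["cross_correlogram", "peak_and_trough", "lag_axis"]


def lag_axis(max_lag_bins: int, bin_s: float) -> np.ndarray:
    return np.arange(-max_lag_bins, max_lag_bins + 1) * bin_s


def cross_correlogram(
    a: np.ndarray, b: np.ndarray, max_lag_bins: int
) -> np.ndarray:
    """Pearson correlation of a(t) with b(t+lag) for lags −L…+L bins."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("series must share length")
    n = a.size
    if n <= max_lag_bins:
        raise ValueError("series shorter than the maximum lag")
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("constant channel: correlation undefined")
    r = np.empty(2 * max_lag_bins + 1)
    for i, lag in enumerate(range(-max_lag_bins, max_lag_bins + 1)):
        if lag >= 0:
            num = np.dot(a[: n - lag], b[lag:])
        else:
            num = np.dot(a[-lag:], b[: n + lag])
        r[i] = num / ((n - abs(lag)) * sa * sb)
    return r


def peak_and_trough(
    r: np.ndarray, bin_s: float
) -> Tuple[float, float, float, float]:
    """(peak_r, peak_lag_s, trough_r, trough_lag_s) with ties toward 0 lag."""
    max_lag = (r.size - 1) // 2
    lags = np.arange(-max_lag, max_lag + 1)
    # visit lags ordered by |lag| so the first argmax is the smallest |lag|
    order = np.lexsort((lags, np.abs(lags)))
    rs = r[order]
    ip = int(np.argmax(rs))
    it = int(np.argmin(rs))
    return (
        float(rs[ip]), float(lags[order[ip]] * bin_s),
        float(rs[it]), float(lags[order[it]] * bin_s),
    )
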