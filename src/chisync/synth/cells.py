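"""Per-cell fluorescence synthesis with state-dependent synchrony.

Each cell is a tonic baseline plus transients convolved with a double-
exponential GCaMP6f-like kernel (rise 50 ms, decay 400 ms by default).
At every population event the cell participates independently with the
state's participation probability — this is what sets cross-cell
*synchrony*.  During continuous locomotion cells additionally emit
asynchronous Poisson transients, so the single-cell transient rate can
stay high while synchrony drops: synchrony, not single-cell rate, is the
state-dependent quantity.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .config import GroundTruth, PopulationEvent, SynthConfig

__all__ = ["double_exp_kernel", "generate_cell_population"]


def double_exp_kernel(rise_s: float, decay_s: float, rate_hz: float) -> np.ndarray:
    """Double-exponential kernel (1 − e^{−t/rise}) · e^{−t/decay},
    normalized to unit peak, truncated at 6 decay constants."""
    if rise_s <= 0 or decay_s <= 0:
        raise ValueError("kernel time constants must be positive")
    t = np.arange(0, 6.0 * decay_s, 1.0 / rate_hz)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def _in_bouts(t: float, bouts: List[Tuple[float, float]]) -> bool:
    return any(a <= t < b for a, b in bouts)


def generate_cell_population(
    velocity: np.ndarray,
    events: GroundTruth,
    config: SynthConfig,
    seed: int | None = None,
) -> Tuple[np.ndarray, np.ndarray, List[List[float]]]:
    """Synthesize per-cell raw fluorescence traces at the ROI frame rate.

    Returns ``(traces, positions_um, transient_times)`` where ``traces``
    is (n_cells × n_frames) raw fluorescence (tonic baseline 1.0),
    ``positions_um`` the (n_cells × 2) centroids uniform in a square
    field, and ``transient_times`` the imposed per-cell transient onsets.
    ``events.cell_transients`` is filled in place.
    """
    cfg = config
    rng = (cfg.rng("cells") if seed is None
           else np.random.default_rng([int(seed), 2]))
    n_cells = cfg.n_cells
    rate = cfg.cell_rate_hz
    n_frames = int(np.floor(cfg.duration_s * rate))
    positions = rng.uniform(0.0, cfg.field_size_um, size=(n_cells, 2))
    kernel = double_exp_kernel(cfg.kernel_rise_s, cfg.kernel_decay_s, rate)

    if n_cells == 0:
        events.cell_transients = []
        return np.empty((0, n_frames)), positions, []

    # participation probability per population event (optionally decaying
    # with distance from a random event focus)
    def participation(p: float, rng_: np.random.Generator) -> np.ndarray:
        if cfg.distance_decay_um is None:
            probs = np.full(n_cells, p)
        else:
            focus = rng_.uniform(0.0, cfg.field_size_um, size=2)
            d = np.linalg.norm(positions - focus, axis=1)
            probs = p * np.exp(-d / cfg.distance_decay_um)
        return rng_.random(n_cells) < probs

    per_cell: List[List[float]] = [[] for _ in range(n_cells)]
    for ev in events.population_events:
        if ev.kind == "onset":
            p = cfg.participation_prob_onset
        elif ev.kind == "rest":
            p = cfg.participation_prob_rest
        else:
            p = cfg.participation_prob_locomotion
        active = participation(p, rng)
        jitter = rng.normal(0.0, cfg.transient_jitter_s, size=n_cells)
        for ci in np.flatnonzero(active):
            t = ev.time_s + jitter[ci]
            if 0 <= t < cfg.duration_s:
                per_cell[ci].append(float(t))

    # asynchronous transients during continuous locomotion
    for a, b in events.bouts:
        span = b - a
        for ci in range(n_cells):
            k = rng.poisson(cfg.async_rate_locomotion * span)
            for t in np.sort(rng.uniform(a, b, size=k)):
                per_cell[ci].append(float(t))

    traces = np.ones((n_cells, n_frames))
    for ci in range(n_cells):
        per_cell[ci].sort()
        dff = np.zeros(n_frames)
        for t in per_cell[ci]:
            amp = rng.uniform(*cfg.transient_amp_range)
            i = int(round(t * rate))
            if 0 <= i < n_frames:
                j = min(n_frames, i + kernel.size)
                dff[i:j] += amp * kernel[: j - i]
        noise = rng.normal(0.0, cfg.noise_sd, size=n_frames) if cfg.noise_sd else 0.0
        traces[ci] = 1.0 * (1.0 + dff) + noise

    events.cell_transients = per_cell
    return traces, positions, per_cell
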