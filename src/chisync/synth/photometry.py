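"""Population fiber-photometry channel synthesis.

A population channel is an activity drive (ΔF/F scale) passed through the
fluorescence model

    raw(t) = autofluorescence + F0·(1 + drive(t)) + drift(t) + F0·σ·ε(t)

with sinusoidal slow drift and i.i.d. Gaussian noise per raw sample.  The
ChI drive sums kernel responses at population events (plus a weak
asynchronous component during bouts); the DA drive is delayed by
``da_lag_s`` with a positive response at initiations, ``da_jerk_sign`` ×
response at jerks, and a velocity-proportional component during bouts.
The static-indicator control replaces the activity drive with
``artifact_gain × |velocity|`` (pure movement artifact).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cells import double_exp_kernel
from .config import GroundTruth, PopulationEvent, SynthConfig

__all__ = [
    "event_train",
    "drive_from_events",
    "chi_drive",
    "da_drive",
    "generate_population_photometry",
]


def event_train(
    n_events: int,
    duration_s: float,
    rng: np.random.Generator,
    min_gap_s: float = 1.0,
) -> np.ndarray:
    """Random event times with a minimum gap (uniform via stick-breaking)."""
    free = duration_s - n_events * min_gap_s
    if free < 0:
        raise ValueError("too many events for the duration")
    x = np.sort(rng.uniform(0.0, free, size=n_events))
    return x + min_gap_s * np.arange(n_events)


def drive_from_events(
    times: Sequence[float],
    amps: Sequence[float],
    duration_s: float,
    rate_hz: float,
    kernel: np.ndarray,
    lag_s: float = 0.0,
) -> np.ndarray:
    """Sum of amplitude-scaled kernels at (lagged) event times."""
    n = int(round(duration_s * rate_hz))
    d = np.zeros(n)
    for t, a in zip(times, amps):
        i = int(round((t + lag_s) * rate_hz))
        if i >= n:
            continue
        j = min(n, max(i, 0) + kernel.size - max(0, -i))
        k0 = max(0, -i)
        i = max(i, 0)
        d[i:j] += a * kernel[k0: k0 + (j - i)]
    return d


def chi_drive(
    gt: GroundTruth, config: SynthConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """ChI population drive: population events plus a weak asynchronous
    component during locomotion bouts."""
    cfg = config
    kernel = double_exp_kernel(cfg.kernel_rise_s, cfg.kernel_decay_s, cfg.raw_rate_hz)
    times = [e.time_s for e in gt.population_events]
    amps = [e.chi_amp for e in gt.population_events]
    d = drive_from_events(times, amps, cfg.duration_s, cfg.raw_rate_hz, kernel)
    if rng is not None and cfg.chi_loco_event_rate_hz > 0:
        for a, b in gt.bouts:
            k = rng.poisson(cfg.chi_loco_event_rate_hz * (b - a))
            ts = rng.uniform(a, b, size=k)
            d += drive_from_events(
                ts, np.full(k, cfg.chi_loco_event_amp),
                cfg.duration_s, cfg.raw_rate_hz, kernel)
    return d


def da_drive(
    gt: GroundTruth, config: SynthConfig, velocity: Optional[np.ndarray] = None
) -> np.ndarray:
    """DA population drive: event responses delayed by ``da_lag_s`` with a
    state-dependent sign (``da_jerk_sign`` at jerks) plus a velocity-
    proportional component during bouts."""
    cfg = config
    kernel = double_exp_kernel(cfg.kernel_rise_s, cfg.kernel_decay_s, cfg.raw_rate_hz)
    jerks = set()
    for t, kind in gt.movement_events:
        if kind == "jerk":
            jerks.add(round(t, 6))
    times, amps = [], []
    for e in gt.population_events:
        sign = 1.0
        if e.kind == "onset" and round(e.time_s, 6) in jerks:
            sign = float(cfg.da_jerk_sign)
        times.append(e.time_s)
        amps.append(sign * cfg.da_amp_scale * e.da_amp)
    d = drive_from_events(times, amps, cfg.duration_s, cfg.raw_rate_hz,
                          kernel, lag_s=cfg.da_lag_s)
    if velocity is not None and cfg.da_velocity_gain > 0 and gt.bouts:
        mask = np.zeros(d.size, dtype=bool)
        for a, b in gt.bouts:
            mask[int(a * cfg.raw_rate_hz): int(b * cfg.raw_rate_hz)] = True
        d[mask] += cfg.da_velocity_gain * velocity[mask] / 10.0
    return d


def generate_population_photometry(
    drive: np.ndarray,
    config: SynthConfig,
    role: str = "ChI",
    seed: int | None = None,
    velocity: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Raw-rate photometry channel from an activity drive (ΔF/F scale).

    In static-indicator mode the drive is replaced by ``artifact_gain ×
    |velocity|`` — an activity-independent control channel.
    """
    cfg = config
    stream = {"ChI": "chi_noise", "DA": "da_noise"}.get(role, "static_noise")
    rng = (cfg.rng(stream) if seed is None
           else np.random.default_rng([int(seed), 10 + len(stream)]))
    n = int(round(cfg.duration_s * cfg.raw_rate_hz))
    if cfg.static_indicator:
        if velocity is None:
            raise ValueError("static-indicator mode requires the velocity trace")
        drive = cfg.artifact_gain * np.abs(velocity)
    drive = np.asarray(drive, dtype=float)
    if drive.size != n:
        raise ValueError("drive length does not match the session duration")
    t = np.arange(n) / cfg.raw_rate_hz
    drift = cfg.drift_amplitude * np.sin(2 * np.pi * t / cfg.drift_period_s)
    noise = rng.normal(0.0, cfg.noise_sd * cfg.f0, size=n) if cfg.noise_sd else 0.0
    # fluorescence cannot dip below a small fraction of the tonic level
    activity = cfg.f0 * np.maximum(1.0 + drive, 0.05)
    return cfg.autofluorescence + activity + drift + noise
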