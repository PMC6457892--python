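"""Full synthetic-session assembly.

Orders the generator stages so every piece of ground truth is fixed
before the signals that depend on it: velocity and movement events →
rest-period population events → reward perturbations → optional
transient-coupled velocity kicks → per-cell traces → population
photometry channels.  All randomness flows from the master seed through
named substreams, so a fixed seed fixes every output bit-for-bit.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

from .cells import generate_cell_population
from .config import GroundTruth, PopulationEvent, SynthConfig
from .photometry import chi_drive, da_drive, generate_population_photometry
from .reward import generate_reward_stream
from .velocity import generate_velocity

if TYPE_CHECKING:  # pragma: no cover
    from ..session import Session

__all__ = ["generate_session"]


def _place_rest_events(
    velocity: np.ndarray, gt: GroundTruth, cfg: SynthConfig,
    rng: np.random.Generator,
) -> None:
    """Draw spontaneous population-event times inside rest periods, clear
    of movement-segment guard zones and of each other."""
    n_target = int(round(cfg.rest_event_rate_per_min * cfg.duration_s / 60.0))
    if n_target == 0:
        return
    guards = [(t - 1.5, t + 3.5) for t, _ in gt.movement_events]
    guards += [(a - 2.0, b + 2.5) for a, b in gt.bouts]
    placed: list[float] = []
    tries = 0
    while len(placed) < n_target and tries < 200 * n_target:
        tries += 1
        t = rng.uniform(2.0, cfg.duration_s - 4.0)
        if any(a <= t < b for a, b in guards):
            continue
        if any(abs(t - p) < 2.5 for p in placed):
            continue
        placed.append(t)
    for t in sorted(placed):
        gt.population_events.append(PopulationEvent(
            time_s=t, kind="rest",
            chi_amp=rng.uniform(*cfg.transient_amp_range),
            da_amp=rng.uniform(*cfg.da_rest_amp_range),
        ))


def generate_session(config: SynthConfig) -> "Session":
    """Generate one complete synthetic session with ground truth."""
    from ..session import Session  # deferred: avoids a circular import

    cfg = config
    velocity, gt = generate_velocity(cfg)

    ev_rng = cfg.rng("events")
    # movement onsets drive a shared population transient
    for t, kind in gt.onset_events():
        amp = ev_rng.uniform(*cfg.transient_amp_range)
        gt.population_events.append(PopulationEvent(
            time_s=t, kind="onset", chi_amp=amp, da_amp=amp))
    _place_rest_events(velocity, gt, cfg, ev_rng)
    gt.population_events.sort(key=lambda e: e.time_s)

    rewards = licks = None
    chi_extra = np.zeros_like(velocity)
    if cfg.n_rewards > 0:
        stream = generate_reward_stream(cfg, None, velocity, gt)
        velocity = velocity + stream.velocity_delta
        chi_extra = stream.chi_drive
        rewards, licks = stream.solenoid_times, stream.lick_times

    # optional: velocity outcome after rest transients scales with the DA
    # companion amplitude (the DA-gated movement-reset construction)
    if cfg.transient_velocity_coupling > 0:
        rate = cfg.raw_rate_hz
        bump_t = np.arange(int(round(0.8 * rate))) / rate
        bump = np.sin(np.pi * bump_t / 0.8) ** 2
        for e in gt.population_events:
            if e.kind != "rest":
                continue
            amp = cfg.transient_velocity_coupling * e.da_amp
            i = int(round((e.time_s + 0.2) * rate))
            j = min(velocity.size, i + bump.size)
            if i >= 0 and j > i:
                velocity[i:j] += amp * bump[: j - i]

    cell_traces, positions, _ = generate_cell_population(velocity, gt, cfg)

    d_chi = chi_drive(gt, cfg, cfg.rng("chi_async")) + chi_extra
    d_da = da_drive(gt, cfg, velocity)
    channels = {
        "chi_pop": generate_population_photometry(d_chi, cfg, role="ChI",
                                                  velocity=velocity),
        "da_pop": generate_population_photometry(d_da, cfg, role="DA",
                                                 velocity=velocity),
    }
    if cfg.static_indicator:
        channels = {"static_pop": generate_population_photometry(
            np.zeros_like(velocity), cfg, role="static", velocity=velocity)}

    return Session(
        raw_rate_hz=cfg.raw_rate_hz,
        velocity=velocity,
        channels=channels,
        autofluorescence=cfg.autofluorescence,
        cell_rate_hz=cfg.cell_rate_hz,
        cell_traces=cell_traces if cfg.n_cells else None,
        cell_positions=positions if cfg.n_cells else None,
        rewards=rewards,
        licks=licks,
        ground_truth=gt,
        meta={"seed": cfg.seed, "generator": "chisync.synth"},
    )
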