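"""Unpredicted-reward stream synthesis.

Solenoid openings occur at random inter-reward intervals (uniform
10–30 s).  Each delivery perturbs velocity in a state-dependent way —
a brief acceleration when the mouse is resting (it moves to the spout),
a deceleration when it is running (it stops to consume) — and triggers a
lick train a configurable latency after the movement change.  The ChI
drive added at each reward scales positively with the imposed velocity
change, so the trialwise response-vs-Δv correlation has a known positive
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .cells import double_exp_kernel
from .config import GroundTruth, SynthConfig
from .photometry import drive_from_events

logger = logging.getLogger(__name__)

__all__ = ["RewardStream", "generate_reward_stream"]


@dataclass
class RewardStream:
    solenoid_times: np.ndarray
    lick_times: np.ndarray
    velocity_delta: np.ndarray  # raw-rate additive velocity perturbation
    chi_drive: np.ndarray  # raw-rate additive ChI drive (ΔF/F scale)
    truth: List[Dict[str, float]] = field(default_factory=list)


def generate_reward_stream(
    config: SynthConfig,
    seed: int | None,
    velocity: np.ndarray,
    ground_truth: GroundTruth,
) -> RewardStream:
    """Synthesize solenoid/lick streams plus the induced velocity and ChI
    perturbations.  Rewards colliding with a movement-onset guard zone are
    skipped with a logged warning."""
    cfg = config
    rng = (cfg.rng("rewards") if seed is None
           else np.random.default_rng([int(seed), 5]))
    n = velocity.size
    rate = cfg.raw_rate_hz
    dv = np.zeros(n)
    drive = np.zeros(n)
    kernel = double_exp_kernel(cfg.kernel_rise_s, cfg.kernel_decay_s, rate)

    # keep rewards clear of spontaneous movements and of bout edges so the
    # pre/post Δv windows reflect the reward, not ongoing transitions;
    # rewards deep inside a bout remain valid (deceleration trials)
    onset_guards = [(t - 2.0, t + 3.0) for t, k in ground_truth.movement_events
                    if k in ("jerk", "initiation", "termination")]
    onset_guards += [g for a, b in ground_truth.bouts
                     for g in ((a - 2.0, a + 2.0), (b - 2.0, b + 4.0))]

    t_next = rng.uniform(*cfg.reward_interval_s)
    solenoid: List[float] = []
    licks: List[float] = []
    truth: List[Dict[str, float]] = []
    while t_next < cfg.duration_s - 5.0 and len(solenoid) < (cfg.n_rewards or 10**9):
        t = t_next
        t_next = t + rng.uniform(*cfg.reward_interval_s)
        if any(a <= t < b for a, b in onset_guards):
            logger.warning("reward at %.2f s collides with a movement onset; "
                           "skipped", t)
            continue
        in_bout = any(a <= t < b for a, b in ground_truth.bouts)
        i = int(round(t * rate))
        local_v = float(np.mean(velocity[i: i + int(0.5 * rate)]))
        bump_t = np.arange(int(round(1.0 * rate))) / rate
        bump = np.sin(np.pi * bump_t / 1.0) ** 2
        if in_bout:
            # decelerate toward the spout: remove up to kick cm/s
            amp = -min(cfg.reward_velocity_kick_cmps, max(local_v, 0.0))
        else:
            # spout approach vigor varies trial to trial
            amp = cfg.reward_velocity_kick_cmps * rng.uniform(0.2, 1.0)
        j = min(n, i + bump.size)
        dv[i:j] += amp * bump[: j - i]
        dv_true = amp * float(bump.mean())  # mean Δv over the 1 s window
        chi_amp = cfg.reward_chi_baseline + cfg.reward_chi_coupling * dv_true
        drive += drive_from_events([t], [chi_amp], cfg.duration_s, rate, kernel)
        solenoid.append(t)
        truth.append({"time_s": t, "dv_true": dv_true, "chi_amp": chi_amp,
                      "state": "locomotion" if in_bout else "rest"})
        # consumption licks after the movement change
        lick_start = t + 0.3 + cfg.lick_latency_s + rng.normal(0.0, 0.05)
        k = 0
        while k / cfg.lick_rate_hz < cfg.lick_train_s:
            licks.append(lick_start + k / cfg.lick_rate_hz)
            k += 1

    ground_truth.reward_truth = truth
    return RewardStream(
        solenoid_times=np.array(solenoid),
        lick_times=np.array(sorted(licks)),
        velocity_delta=dv,
        chi_drive=drive,
        truth=truth,
    )
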