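#!/usr/bin/env python
"""Generate the synthetic study sessions used by the downstream analyses.

Writes to scratch/sessions/ (large time-series tables) and a summary of
what was generated to results/session_summary.csv:

* ``photometry_XX`` — 300 s two-channel (ChI + DA) sessions with jerks,
  initiations, micro-movements and a DA delay of 110 ms (jerk sign −1);
* ``cells_XX`` — sessions with 10 imaged cells, onset participation 0.9
  and asynchronous locomotion firing (the synchrony-dissociation regime);
* ``reward_XX`` — sessions with unpredicted rewards (uniform 10–30 s);
* ``static_control`` — activity-independent static-indicator session.
"""

from pathlib import Path

import pandas as pd

from chisync.session import write_session
from chisync.synth import SynthConfig, generate_session

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def main() -> None:
    SESSIONS.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    configs = {}
    for i in range(3):
        configs[f"photometry_{i:02d}"] = SynthConfig(seed=100 + i, duration_s=300.0)
    for i in range(2):
        configs[f"cells_{i:02d}"] = SynthConfig(
            seed=200 + i, duration_s=300.0, n_cells=10,
            participation_prob_onset=0.9, participation_prob_rest=0.6,
            async_rate_locomotion=0.5, jerk_rate_per_min=2.0,
            initiation_rate_per_min=2.0)
    for i in range(2):
        configs[f"reward_{i:02d}"] = SynthConfig(
            seed=300 + i, duration_s=600.0, n_rewards=40,
            initiation_rate_per_min=1.0, jerk_rate_per_min=0.5,
            micro_rate_per_min=0.0, rest_event_rate_per_min=0.5)
    configs["static_control"] = SynthConfig(
        seed=400, duration_s=300.0, static_indicator=True, artifact_gain=0.0)

    for name, cfg in configs.items():
        session = generate_session(cfg)
        write_session(session, SESSIONS / name)
        gt = session.ground_truth
        rows.append({
            "session": name, "seed": cfg.seed, "duration_s": cfg.duration_s,
            "n_cells": session.n_cells,
            "n_jerks": len(gt.events_of("jerk")),
            "n_initiations": len(gt.events_of("initiation")),
            "n_micro": len(gt.events_of("micro")),
            "n_rewards": 0 if session.rewards is None else session.rewards.size,
            "n_population_events": len(gt.population_events),
        })
        print(f"{name}: {rows[-1]['n_jerks']} jerks, "
              f"{rows[-1]['n_initiations']} initiations, "
              f"{rows[-1]['n_population_events']} population events")
    pd.DataFrame(rows).to_csv(RESULTS / "session_summary.csv", index=False)
    print(f"wrote {len(rows)} sessions under {SESSIONS}")


if __name__ == "__main__":
    main()
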