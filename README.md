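# chisync

Analysis of simultaneous cholinergic-interneuron (ChI) and dopamine-axon
(DA) calcium signaling in mouse dorsal striatum during spontaneous
treadmill behavior — as a tested, reusable pipeline with a synthetic
session generator that provides ground truth for every stage.

Head-fixed mice on a cylindrical treadmill alternate spontaneously
between rest, brief "jerks", and bouts of continuous locomotion, while
fiber photometry (1 kHz) or two-photon ROI traces (~30 Hz) report
GCaMP6f fluorescence from ChIs and/or DA axon terminals alongside rotary-
encoder velocity. The package implements the full analysis chain for such
recordings:

1. **Preprocessing** — 10 ms binning; ΔF/F with a sliding 8th-percentile
   baseline over a 16 s window, corrected for fiber/tissue
   autofluorescence: ΔF/F = (F − F₀)/(F₀ − F_auto); velocity smoothing
   (50 ms) and differentiation; z-scoring against rest bins.
2. **Behavior** — per-bin movement/rest segmentation (|v| > 2.2 cm/s and
   |a| > 40 cm/s² vs |v| ≤ 0.2 cm/s in ±1 s windows) and typed events:
   clean onsets (0.2 cm/s crossings, peak ≥ 1 cm/s within 1 s, 0.5 s
   pre-quiescence) split into jerks (max v in 1–2 s < 2.2 cm/s) and
   locomotion initiations (mean v in 0.5–2 s > 4.5 cm/s); bouts (> 3 s
   above 4.5 cm/s), terminations (2.2 cm/s downward crossing held 1 s),
   and within-bout velocity extrema.
3. **Transients** — per-SD-level (k = 1…6) minimum-duration thresholds
   calibrated so positive events outnumber mirrored negative events
   ≥ 99:1 (p < 0.01 that a detected event is noise), then applied per
   session; per-state transient ΔF/F and rates.
4. **Alignment** — event-triggered averages ± SEM with binwise rank-sum
   significance vs rest; peak-normalized per-event matrices; trialwise
   reward response vs Δvelocity (Pearson R) with quartile splits and
   first-lick realignment.
5. **Synchrony** — pairwise cell–cell cross-correlograms (±1 s) over
   concatenated behavioral epochs; correlation-vs-distance regression;
   co-activation fraction per clustered population transient.
6. **Coupling** — ChI↔DA and signal↔kinematics cross-correlograms with
   peak *and* trough lags (positive lag = B lags A); quartile-conditional
   triggered averages by companion-signal amplitude; joint z(ChI) × z(DA)
   maps of the velocity outcome.
7. **Synthetic data** — `chisync.synth` generates complete sessions with
   known ground truth: movement events that satisfy the classifier rules
   with margin, per-cell transients whose *synchrony* (not single-cell
   rate) is state-dependent, a DA channel with configurable lag and
   state-dependent sign, rewards, drift/noise, and an activity-independent
   static-indicator control.

## Worked example

```python
from chisync import AnalysisConfig
from chisync.pipeline import preprocess_session
from chisync.coupling import population_xcorr
from chisync.synth import SynthConfig, generate_session

config = AnalysisConfig()
session = generate_session(SynthConfig(seed=7, duration_s=300, n_cells=8,
                                       da_velocity_gain=0.0))
proc = preprocess_session(session, config)

ann = proc.annotation
print(len(ann.event_times("jerk")), len(ann.event_times("initiation")),
      len(ann.bouts))
res = population_xcorr(proc.dff["chi_pop"].dff, proc.dff["da_pop"].dff,
                       None, config, config.bin_s)
print(f"DA lags ChI by {res.peak_lag_s * 1e3:+.0f} ms (peak r {res.peak_r:.2f})")
```

prints

```
10 5 5
DA lags ChI by +110 ms (peak r 0.17)
```

— the classifier recovers all 10 generated jerks, 5 initiations and 5
locomotion bouts, and the cross-correlogram recovers the generator's
imposed 110 ms DA delay at the 10 ms bin resolution. The `chisync`
console script exposes the same pipeline
(`chisync simulate | preprocess | classify | detect | align | synchrony |
couple | run-all`).

The numbered scripts under `analysis/` run the full study narrative —
session synthesis, preprocessing + classification, transient calibration,
onset-triggered averages (the DA jerk/initiation divergence), reward
trials, cell-pair synchrony by state, and population coupling — writing
their tables under `results/` (large session files go to `scratch/`).
Run them in order: `python analysis/01_simulate_sessions.py`, etc.

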