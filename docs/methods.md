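# Methods

This note documents the models, parameter choices and numerical
conventions behind `chisync`, and what the synthetic-data validation does
and does not establish about real recordings.

## Signals and preprocessing

Raw inputs are treadmill velocity (rotary encoder, cm/s) and fluorescence
(PMT output in arbitrary units), both sampled at 1 kHz, plus optional
per-cell ROI traces at their native frame rate (~30 Hz). Raw 1 kHz
channels are averaged into 10 ms bins (`bin_s = 0.01 s`); ROI traces are
analyzed at their native rate, since 1/30 s does not divide into 10 ms
bins (`bin_trace` refuses non-integer ratios rather than resampling
silently).

**ΔF/F baseline.** The baseline for each bin is the 8th percentile of
raw fluorescence over a centered 16 s sliding window, truncated at trace
edges (the first/last 8 s are flagged `low_confidence`). Excluding
transient-containing bins from the percentile is done deterministically
in two passes: a provisional ΔF/F against the pass-1 baseline, then
exclusion of bins exceeding 2 robust SD (1.4826 × MAD) before the
percentile is recomputed. A fixed, distribution-based rule replaces any
per-session manual threshold so runs are exactly reproducible. Windows
that lose all samples to exclusion fall back to the plain percentile.

The baseline is corrected by the session's scalar autofluorescence
(measured in overlying cortex in the real preparation; a generator
parameter here) and floored strictly positive. The ΔF/F numerator
subtracts the *uncorrected* percentile baseline and the denominator uses
the *corrected* baseline:

    ΔF/F = (F − BaselineF) / (BaselineF − F_auto)

Whether the numerator should subtract the corrected or uncorrected
baseline is genuinely ambiguous; both are implemented
(`AnalysisConfig.dff_numerator`), with "uncorrected" as the default since
the autofluorescence correction is described as a correction *of the
baseline* used for normalization. With this convention a constant trace
gives ΔF/F ≡ 0 regardless of the autofluorescence, and a raw excursion
equal to the corrected baseline reads ΔF/F = 1.

**Kinematics.** Velocity is smoothed with a centered 50 ms moving
average; acceleration is the forward difference of smoothed velocity
divided by the bin width (last bin replicated). z-scores are computed
against the mean and SD of all rest bins of the same session.

## Behavioral segmentation

All thresholds are absolute (cm/s, cm/s²) and live in `AnalysisConfig`:
movement = |v| > 2.2 cm/s *and* |a| > 40 cm/s² somewhere within ±1 s;
rest = |v| ≤ 0.2 cm/s throughout ±1 s; bins within 1 s of the trace edge
are unclassified. Clean onsets are positive-going 0.2 cm/s crossings with
peak v ≥ 1 cm/s within 1 s and no |v| > 0.2 cm/s in the 0.5 s before;
jerks additionally keep max |v| in the 1–2 s post-window below 2.2 cm/s,
initiations keep mean v over 0.5–2 s above 4.5 cm/s. A crossing matching
both or neither rule is `onset_other`. Crossing times are the first bin
strictly above threshold (10 ms resolution, no interpolation).

Bout detection applies an additional 250 ms centered smoothing before the
"> 4.5 cm/s for > 3 s" rule: with only 50 ms smoothing, stride-cycle
velocity dips fragment bouts. Terminations are the first downward
2.2 cm/s crossing after a bout that holds below threshold for a full
second; a sub-threshold dip shorter than the hold is skipped and the scan
continues to the next bout (or trace end). Velocity peaks/troughs inside
bouts use `scipy.signal.find_peaks` on the bout-smoothed velocity with a
1 cm/s prominence floor.

## Transient significance

For SD levels k = 1…6, positive events are maximal runs of ΔF/F above
mean + k·SD and negative events maximal runs below mean − k·SD, with the
mean and SD taken over each full trace (a rest-only variant is available;
the default uses all bins). The minimum duration d_k is the smallest
whole-bin duration at which

    N₊(≥d) / (N₊(≥d) + N₋(≥d)) ≥ 0.99

with at least one positive event remaining; ties break toward the
shorter duration, and levels where no duration qualifies are marked
unusable (+∞). The 0.99 fraction-of-total reading matches the stated
p < 0.01 false-event probability; the literal N₊/N₋ ratio is available
behind `ratio_mode`. Calibration pools all recordings passed to it and
the thresholds are then applied to each session individually. The
pipeline calibrates per channel role (ChI, DA, cells): ChI and DA
channels have different event statistics — the DA channel's long
negative-going jerk responses would otherwise set every level's duration
and make ordinary ChI transients undetectable.

Detection accepts, per finite level, runs above mean + k·SD lasting at
least d_k; runs accepted at several levels merge into one event whose
onset comes from the lowest accepted level (the earliest physiological
start) and whose reported level is the highest satisfied. On noise-only
traces the calibrated thresholds leave essentially no events of either
sign — the false-event rate among suprathreshold excursions is ≤ 1%, and
a pooled ratio with an empty denominator is reported as 1.0 (no events at
all is perfect false-positive control).

Per-state metrics use the transient-masked trace (ΔF/F inside detected
events, zero elsewhere), averaged over the bins of each state, plus event
onsets per minute of state time. Both the masked mean and event peak
amplitudes are available, since "transient ΔF/F" can reasonably mean
either.

## Epochs, alignment and statistics

The onset epoch is (−0.1, +2) s around each clean onset — the pre-onset
tenth of a second captures the anticipatory rise that precedes movement
by ~100 ms; a strictly post-onset variant is available. Sessions with
less than 5 s total in a required epoch are excluded from that epoch's
analysis with a logged reason.

Triggered averages cut per-event snippets (default −2…+4 s), drop events
without full coverage, and mark a lag significant when the per-event
values differ from pooled rest bins by a two-sided Wilcoxon rank-sum test
at p < 0.01 *and* the mean exceeds the rest mean. No multiple-comparison
correction is applied by default (the figure convention for binwise
masks); Benjamini–Hochberg is available behind `triggered_fdr`. Trialwise
reward analysis uses response = mean ΔF/F over 0…+1 s and Δv = mean v
over 0…+1 s minus −1…0 s (windows configurable, since the exact windows
are not printed), Pearson R, and top/bottom-Δv-quartile triggered
averages.

## Pairwise synchrony

For each cell pair, epoch snippets are concatenated and the Pearson
correlation computed at every lag within ±1 s (lag grid = the cell bin
width). Correlation is computed across concatenation boundaries, as is
conventional for this analysis; a per-window-averaged alternative exists
for users worried about boundary artifacts at long lags. Normalization
uses full-series SDs at every lag; peak ties break toward zero lag.
Distance regressions use ordinary least squares of peak r on centroid
distance, with per-field curves only for fields contributing more than
10 pairs.

Population co-activation events are single-linkage clusters of transient
onsets across cells with a 200 ms gap (≈ the GCaMP6f rise-time scale; no
rule is printed, so it is configurable). A cluster must contain at least
two distinct cells to count as a population event — otherwise every
asynchronous single-cell transient would register as a "population event"
with fraction 1/n and dominate the locomotion means. Events are assigned
to the epoch containing their earliest onset (onset windows take
precedence over bouts, then rest).

## Population coupling

Cross-correlograms between population channels (or a channel and a
kinematic trace) use the same lagged-Pearson machinery; the recorded
convention is that a *positive* peak lag means channel B lags channel A,
so ChI→DA correlograms peak at positive lag when DA follows ChI. Peak and
trough are both reported with their lags. Quartile-conditional analyses
score each primary transient by the mean companion ΔF/F in a window
spanning the transient rise (−0.1…+0.5 s, configurable) and compare the
⌊n/4⌋ top versus bottom events. The joint z(ChI) × z(DA) map bins z
values on a 0.5-z grid from −2 to +4 and reports the mean velocity
outcome per cell (time-bin velocity during locomotion, or post-minus-pre
Δv around transients at rest: +1 s post vs 0.5 s pre), masking cells
with fewer than `map_min_count` samples.

## The synthetic generator

The generator's defaults emulate the study conditions: 300 s sessions
(velocity at 1 kHz), ~2 jerks, ~1 initiation and ~1 micro-movement per
minute placed uniformly at random without overlap (a stick-breaking
construction; impossible rates raise `PlacementError`), every event
exceeding the classifier thresholds by ≥ 20% margin with ≥ 1 s of
quiescence on both sides. Bouts run 4–8 s at 7.5–8.5 cm/s with a 2–4 Hz
stride-cycle sinusoid (1.8 cm/s) and a slow velocity fluctuation
(1.2 cm/s, 0.25–0.4 Hz), keeping raw velocity above 4.5 cm/s throughout;
terminations decay smoothly and hold at rest. The encoder-noise floor is
0.02 cm/s.

Fluorescence is tonic-plus-burst: transients are delta events convolved
with a double-exponential kernel (rise 50 ms, decay 400 ms — GCaMP6f-
like; the indicator is not modeled biophysically). A channel is

    raw(t) = F_auto + F₀ · max(1 + drive, 0.05) + drift + F₀·σ·ε(t)

with F₀ = 10, autofluorescence 2, sinusoidal drift (0.2 raw units, 90 s
period) and i.i.d. Gaussian noise σ = 0.02 ΔF/F per raw sample (no pink
noise: the detector calibration is distribution-estimating either way).
The 5% activity floor keeps strongly negative DA drives physical.

Synchrony is controlled separately from single-cell rates: at each
population event (movement onsets, plus spontaneous rest events at
6/min), each cell participates independently with the state's
participation probability (rest 0.6, onset 0.9 by default; optionally
with an exponential distance decay around a random event focus), while
during bouts each cell fires *asynchronous* Poisson transients at
0.5/s — calibrated so the single-cell transient ΔF/F in locomotion
matches the onset windows while pairwise synchrony collapses. The DA
channel responds to the same events delayed by `da_lag_s` (110 ms
default), positive at initiations and `da_jerk_sign` (−1) at jerks, with
amplitudes scaled by 0.5 relative to ChI and an optional
velocity-proportional component during bouts. Rest-event DA amplitudes
are drawn independently of the ChI amplitudes (uniform 0–1) so
DA-conditioned quartile analyses have genuine spread.

For DA-gated outcome experiments, `transient_velocity_coupling` adds a
velocity kick 0.2–1.0 s after each rest event proportional to that
event's DA amplitude. In the validation configuration the kick is capped
below the 0.2 cm/s rest ceiling, because a supra-threshold kick would
strip the transient of its rest label under the ±1 s rest rule — the
same constraint any rest-conditioned outcome analysis faces. The kick is
far above the binned velocity noise (~0.006 cm/s), so the quartile
ordering is detected at extreme significance while rest labels survive.

Rewards arrive at uniform 10–30 s intervals, skipping a guard zone around
movement events and bout edges (so the Δv windows reflect the reward, not
ongoing transitions). At rest a reward adds an acceleration bump of
variable vigor; inside a bout, a deceleration toward zero. The added ChI
drive is 0.5 + 0.3·Δv, giving the trialwise response-vs-Δv correlation a
known positive ground truth, and lick trains (8 Hz for 2 s) begin ~0.55 s
after the solenoid. The static-indicator mode replaces the activity
drive with `artifact_gain × |velocity|` — with zero gain it is the
fluorophore-without-activity control on which the detector must find
essentially nothing.

All randomness derives from one master seed through named substreams
(velocity, events, cells, channel noises, rewards), so a fixed seed fixes
every output bit-for-bit and components are independently reproducible.

## Validation scales and what they show

The validation experiments run at desk scale: the noise calibration uses
100 sessions of 300 s at 100 Hz; lag recovery uses 20 seeds × 3 delays
of 150 s sessions at SNR 5; the synchrony dissociation uses one 300 s
session with 10 cells; the quartile analysis pools two 600 s sessions
(~300 rest transients). These sizes were chosen so each experiment's
statistic is far from its decision boundary while the whole suite runs in
minutes.

On symmetric i.i.d. noise the positive and mirrored negative run-length
distributions are exchangeable, so the calibrated duration thresholds sit
just beyond the longest negative excursions and almost nothing of either
sign survives them. The reported false-positive control ratio is
therefore evaluated at the calibrated thresholds on the noise ensemble,
with the no-surviving-events case reported as 1.0; the fresh-noise
false-event *rate* (detected events per suprathreshold excursion ≤ 1%)
is property-tested separately.

Passing these tests shows the machinery is correct on data satisfying the
generator's assumptions — tonic baselines, double-exponential transients,
Gaussian noise, movement events with threshold margins. Real recordings
add slow non-sinusoidal drift, motion artifacts, indicator nonlinearity,
neuropil contamination and borderline events that the generator
deliberately avoids; results on such data depend on the same config
thresholds but are not certified by this suite.

## Known limitations

* No spike inference or deconvolution; transients are treated as the unit
  of signal.
* Negative transients (pauses) are not detected as events; they appear
  only in triggered averages and correlograms.
* "Resets" during locomotion are not a detected event class (no printed
  thresholds exist); they are reachable analytically by conditioning on
  large acceleration at low velocity.
* The session format keeps time series as delimited text — inspectable
  and diff-able at desk scale, not optimized for hours-long recordings.
* Cross-correlation normalization by full-series SD slightly deflates
  |r| at long lags versus per-overlap normalization; an overlap-normalized
  option exists.
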