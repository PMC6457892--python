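"""Significance calibration against mirrored negative events, transient
detection and per-state metrics."""

import math

import numpy as np
import pytest

from chisync.config import AnalysisConfig
from chisync.preprocessing import DffTrace
from chisync.transients import (
    calibrate_duration_thresholds,
    detect_transients,
    noise_event_counts,
    transient_state_metrics,
)

from conftest import rng_noise_trace


def signal_trace(seed=0, n=12000, noise=0.05, n_transients=20, amp=0.6,
                 width=60):
    """Noise plus long, high positive transients."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise, n)
    for start in rng.integers(200, n - 200, n_transients):
        x[start:start + width] += amp
    return DffTrace(dff=x, baseline=np.ones(n), bin_s=0.01)


class TestCalibration:
    def test_durations_shrink_at_higher_sd_levels_on_signal(self, acfg):
        # at higher k the noise run-length distribution collapses faster
        # than the transient one, so d_4 <= d_2 on a signal mixture
        traces = [signal_trace(seed=s) for s in range(6)]
        th = calibrate_duration_thresholds(traces, acfg)
        assert math.isfinite(th.durations_s[2])
        assert math.isfinite(th.durations_s[4])
        assert th.durations_s[4] <= th.durations_s[2]

    def test_durations_non_increasing_in_level_on_signal(self, acfg):
        traces = [signal_trace(seed=100 + s) for s in range(6)]
        th = calibrate_duration_thresholds(traces, acfg)
        finite = [th.durations_s[k] for k in sorted(th.durations_s)
                  if math.isfinite(th.durations_s[k])]
        assert all(a >= b for a, b in zip(finite, finite[1:]))

    def test_empty_input_rejected(self, acfg):
        with pytest.raises(ValueError):
            calibrate_duration_thresholds([], acfg)

    def test_constant_trace_rejected(self, acfg):
        tr = DffTrace(dff=np.zeros(12000), baseline=np.ones(12000))
        with pytest.raises(ValueError, match="SD"):
            calibrate_duration_thresholds([tr], acfg)

    def test_false_event_rate_controlled_on_fresh_noise(self, acfg):
        # the operating point of the calibrated thresholds: on signal-free
        # noise, detected events are <=1% of suprathreshold positive
        # excursions (here: essentially none survive the duration rule)
        cal = [rng_noise_trace([11, i], n=30000) for i in range(30)]
        th = calibrate_duration_thresholds(cal, acfg)
        detected = excursions = 0
        for i in range(30):
            tr = rng_noise_trace([12, i], n=30000)
            evs = detect_transients(tr, th, acfg)
            detected += len(evs)
            mu, sd = tr.dff.mean(), tr.dff.std()
            from chisync.behavior import _runs
            excursions += len(_runs(tr.dff > mu + sd))
        assert excursions > 1000
        assert detected / excursions <= 0.01


class TestDetection:
    def test_flat_trace_has_no_events(self, acfg):
        th = calibrate_duration_thresholds([signal_trace()], acfg)
        tr = DffTrace(dff=np.random.default_rng(0).normal(0, 1e-3, 3000),
                      baseline=np.ones(3000))
        # noise-only trace against signal-calibrated thresholds
        evs = detect_transients(tr, th, acfg)
        assert evs == [] or all(e.duration_s < 1.0 for e in evs)

    def test_single_big_transient_detected_once_at_high_level(self, acfg):
        traces = [signal_trace(seed=s) for s in range(4)]
        th = calibrate_duration_thresholds(traces, acfg)
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 0.05, 12000)
        sd0 = x.std()
        x[6000:6600] += 5 * sd0 * 2  # amplitude 10 sigma, long duration
        tr = DffTrace(dff=x, baseline=np.ones(12000))
        evs = detect_transients(tr, th, acfg)
        big = [e for e in evs if 59.0 <= e.onset_s <= 60.5]
        assert len(big) == 1
        assert big[0].sd_level >= 5

    def test_translation_equivariance(self, acfg):
        traces = [signal_trace(seed=s) for s in range(4)]
        th = calibrate_duration_thresholds(traces, acfg)
        x = signal_trace(seed=77).dff
        shift = 500
        a = detect_transients(DffTrace(dff=x, baseline=np.ones(x.size)), th, acfg)
        b = detect_transients(
            DffTrace(dff=np.roll(x, shift), baseline=np.ones(x.size)), th, acfg)
        a_on = {round(e.onset_s + shift * 0.01, 3) for e in a
                if e.offset_s < (x.size - shift) * 0.01}
        b_on = {round(e.onset_s, 3) for e in b}
        assert a_on <= b_on | {round(t, 3) for t in np.arange(0, 5, 0.01)}
        assert len(a_on & b_on) >= max(1, int(0.8 * len(a_on)))

    def test_added_transient_keeps_existing_nonoverlapping_events(self, acfg):
        traces = [signal_trace(seed=s) for s in range(4)]
        th = calibrate_duration_thresholds(traces, acfg)
        tr = signal_trace(seed=5)
        before = detect_transients(tr, th, acfg)
        x = tr.dff.copy()
        x[200:260] += 1.0  # new transient far from existing events
        after = detect_transients(
            DffTrace(dff=x, baseline=np.ones(x.size)), th, acfg)
        # detection statistics (mu, sd) shift slightly; all events clear of
        # the insertion that were found before must still be found
        before_far = [e for e in before if e.onset_s > 5.0]
        after_on = [e.onset_s for e in after]
        recovered = sum(any(abs(e.onset_s - t) < 0.05 for t in after_on)
                        for e in before_far)
        assert recovered >= int(0.9 * len(before_far))

    def test_events_sorted_and_consistent(self, acfg):
        traces = [signal_trace(seed=s) for s in range(4)]
        th = calibrate_duration_thresholds(traces, acfg)
        evs = detect_transients(signal_trace(seed=9), th, acfg)
        assert evs == sorted(evs, key=lambda e: e.onset_s)
        for e in evs:
            assert e.offset_s > e.onset_s
            assert e.sd_level in range(1, 7)


class TestStateMetrics:
    def test_no_events_means_zero_state_means(self, basic_processed, acfg):
        tr = basic_processed.dff["chi_pop"]
        out = transient_state_metrics([], tr, basic_processed.annotation, acfg)
        for state in ("rest", "movement"):
            assert out[state]["mean_transient_dff"] == 0.0
            assert out[state]["events_per_min"] == 0.0

    def test_onset_transients_raise_onset_mean_above_rest(
            self, basic_processed, acfg):
        tr = basic_processed.dff["chi_pop"]
        th = calibrate_duration_thresholds([tr], acfg)
        evs = detect_transients(tr, th, acfg)
        out = transient_state_metrics(evs, tr, basic_processed.annotation, acfg)
        # generator ties population transients to movement onsets
        assert out["onset"]["mean_transient_dff"] > out["rest"]["mean_transient_dff"]
        assert out["movement"]["mean_transient_dff"] > 0
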