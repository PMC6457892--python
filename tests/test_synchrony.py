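"""Cross-correlogram core, pairwise synchrony by behavioral epoch,
distance dependence and co-activation fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chisync.config import AnalysisConfig
from chisync.pipeline import preprocess_session
from chisync.preprocessing import DffTrace
from chisync.synchrony import (
    SessionExcluded,
    coactivation_fraction,
    correlation_vs_distance,
    pairwise_xcorr_by_state,
)
from chisync.synth import SynthConfig, generate_cell_population, generate_velocity
from chisync.transients import TransientEvent
from chisync.xcorr import cross_correlogram, peak_and_trough


class TestCrossCorrelogram:
    def test_identical_series_peak_one_at_zero_lag(self):
        x = np.random.default_rng(0).normal(0, 1, 2000)
        r = cross_correlogram(x, x, 50)
        peak_r, peak_lag, _, _ = peak_and_trough(r, 0.01)
        assert peak_r == pytest.approx(1.0, abs=1e-9)
        assert peak_lag == 0.0

    @given(shift=st.integers(min_value=-20, max_value=20))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_shift_moves_the_peak_by_the_shift(self, shift):
        rng = np.random.default_rng(1)
        x = np.convolve(rng.normal(0, 1, 4000), np.ones(20) / 20, "same")
        y = np.roll(x, shift)
        r = cross_correlogram(x[100:-100], y[100:-100], 50)
        _, peak_lag, _, _ = peak_and_trough(r, 0.01)
        # b lags a by `shift` bins → positive peak lag
        assert peak_lag == pytest.approx(shift * 0.01, abs=1e-9)

    def test_swap_reverses_the_correlogram(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 1500)
        y = np.roll(x, 7) + rng.normal(0, 0.1, 1500)
        assert np.allclose(cross_correlogram(x, y, 40),
                           cross_correlogram(y, x, 40)[::-1])

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cross_correlogram(np.ones(100), np.random.default_rng(0).normal(size=100), 5)


class TestPairwiseByState:
    def test_identical_cells_fully_correlated_at_zero_lag(self, acfg,
                                                          cell_processed):
        c = cell_processed.cell_dff[0]
        twin = DffTrace(dff=c.dff.copy(), baseline=c.baseline.copy(),
                        bin_s=c.bin_s)
        pairs = pairwise_xcorr_by_state([c, twin], cell_processed.annotation,
                                        "all", acfg)
        assert pairs[0].peak_r == pytest.approx(1.0, abs=1e-9)
        assert pairs[0].peak_lag_s == 0.0

    def test_peak_r_invariant_to_affine_rescaling(self, acfg, cell_processed):
        cells = cell_processed.cell_dff[:3]
        scaled = [DffTrace(dff=5.0 * c.dff + 1.0, baseline=c.baseline,
                           bin_s=c.bin_s) for c in cells]
        a = pairwise_xcorr_by_state(cells, cell_processed.annotation, "onset", acfg)
        b = pairwise_xcorr_by_state(scaled, cell_processed.annotation, "onset", acfg)
        for pa, pb in zip(a, b):
            assert pa.peak_r == pytest.approx(pb.peak_r, abs=1e-9)
            assert pa.peak_lag_s == pb.peak_lag_s

    def test_cogenerated_cells_peak_near_zero_lag(self, acfg, cell_processed,
                                                  cell_session):
        pairs = pairwise_xcorr_by_state(
            cell_processed.cell_dff, cell_processed.annotation, "onset", acfg,
            positions_um=cell_session.cell_positions)
        lags = np.array([p.peak_lag_s for p in pairs])
        # co-driven transients synchronize within one ROI frame
        assert np.median(np.abs(lags)) <= 1.0 / 30.0 + 1e-9
        assert (np.abs(lags) <= 1.0 / 30.0 + 1e-9).mean() > 0.6

    def test_onset_synchrony_exceeds_locomotion_synchrony(self, acfg,
                                                          cell_processed):
        on = pairwise_xcorr_by_state(cell_processed.cell_dff,
                                     cell_processed.annotation, "onset", acfg)
        lo = pairwise_xcorr_by_state(cell_processed.cell_dff,
                                     cell_processed.annotation, "locomotion", acfg)
        assert np.mean([p.peak_r for p in on]) > np.mean([p.peak_r for p in lo])

    def test_short_epoch_excludes_the_session(self, acfg):
        cells = [DffTrace(dff=np.random.default_rng(i).normal(0, 1, 200),
                          baseline=np.ones(200), bin_s=1 / 30) for i in range(2)]
        from chisync.behavior import BehaviorAnnotation
        ann = BehaviorAnnotation(
            labels=np.array(["unclassified"] * 600), events=[], bouts=[(0.0, 0.1)],
            velocity_extrema=[], bin_s=0.01)
        with pytest.raises(SessionExcluded):
            pairwise_xcorr_by_state(cells, ann, "locomotion", acfg)


def _synth_population(seed, decay=None, n_cells=8, duration=200.0):
    cfg = SynthConfig(seed=seed, duration_s=duration, n_cells=n_cells,
                      jerk_rate_per_min=3.0, initiation_rate_per_min=0.0,
                      micro_rate_per_min=0.0, distance_decay_um=decay,
                      rest_event_rate_per_min=8.0)
    v, gt = generate_velocity(cfg)
    from chisync.synth.config import PopulationEvent
    rng = cfg.rng("events")
    for t, kind in gt.onset_events():
        amp = rng.uniform(*cfg.transient_amp_range)
        gt.population_events.append(PopulationEvent(t, "onset", amp, amp))
    traces, pos, _ = generate_cell_population(v, gt, cfg)
    return cfg, traces, pos, gt


class TestDistanceDependence:
    def test_distance_independent_generator_gives_flat_slope(self, acfg):
        rows = []
        for seed in range(3):
            cfg, traces, pos, gt = _synth_population(seed)
            bin_s = 1.0 / cfg.cell_rate_hz
            cells = [DffTrace(dff=traces[i] - 1.0, baseline=np.ones(traces.shape[1]),
                              bin_s=bin_s) for i in range(traces.shape[0])]
            from chisync.behavior import BehaviorAnnotation
            n_bins = int(cfg.duration_s / 0.01)
            ann = BehaviorAnnotation(labels=np.array(["unclassified"] * n_bins),
                                     events=[(t, k) for t, k in gt.onset_events()],
                                     bouts=[], velocity_extrema=[], bin_s=0.01)
            rows += pairwise_xcorr_by_state(cells, ann, "onset", acfg,
                                            positions_um=pos)
        out = correlation_vs_distance(rows, acfg)
        # slope per µm on r in [-1, 1]: flat within a small band
        assert abs(out["slope_per_um"]) < 5e-4

    def test_exponential_decay_generator_gives_negative_slope(self, acfg):
        rows = []
        for seed in range(5):
            cfg, traces, pos, gt = _synth_population(seed + 50, decay=150.0)
            bin_s = 1.0 / cfg.cell_rate_hz
            cells = [DffTrace(dff=traces[i] - 1.0, baseline=np.ones(traces.shape[1]),
                              bin_s=bin_s) for i in range(traces.shape[0])]
            from chisync.behavior import BehaviorAnnotation
            n_bins = int(cfg.duration_s / 0.01)
            ann = BehaviorAnnotation(labels=np.array(["unclassified"] * n_bins),
                                     events=[(t, k) for t, k in gt.onset_events()],
                                     bouts=[], velocity_extrema=[], bin_s=0.01)
            rows += pairwise_xcorr_by_state(cells, ann, "onset", acfg,
                                            positions_um=pos)
        out = correlation_vs_distance(rows, acfg)
        assert out["slope_per_um"] < 0
        assert out["pearson_r"] < 0

    def test_too_few_pairs_rejected(self, acfg):
        with pytest.raises(ValueError):
            correlation_vs_distance([], acfg)


def _ev(t, cell):
    return TransientEvent(onset_s=t, offset_s=t + 0.2, peak_dff=1.0,
                          sd_level=2, source=f"cell_{cell}")


class TestCoactivation:
    def _rest_annotation(self, n_bins=12000):
        from chisync.behavior import BehaviorAnnotation
        return BehaviorAnnotation(labels=np.array(["rest"] * n_bins),
                                  events=[], bouts=[], velocity_extrema=[],
                                  bin_s=0.01)

    def test_all_cells_simultaneous_gives_fraction_one(self, acfg):
        ann = self._rest_annotation()
        cells = [[_ev(10.0, c)] for c in range(6)]
        out = coactivation_fraction(cells, ann, acfg)
        assert out["by_epoch"]["rest"] == 1.0

    def test_half_participation_gives_fraction_half(self, acfg):
        ann = self._rest_annotation()
        cells = [[_ev(10.0, c)] if c < 3 else [] for c in range(6)]
        out = coactivation_fraction(cells, ann, acfg)
        assert out["by_epoch"]["rest"] == 0.5

    def test_no_transients_empty_result(self, acfg):
        out = coactivation_fraction([[], []], self._rest_annotation(), acfg)
        assert out["events"] == []

    def test_onset_fraction_exceeds_locomotion_fraction(self, acfg,
                                                        cell_processed):
        from chisync.transients import calibrate_duration_thresholds, detect_transients
        th = calibrate_duration_thresholds(cell_processed.cell_dff, acfg)
        evs = [detect_transients(d, th, acfg) for d in cell_processed.cell_dff]
        out = coactivation_fraction(evs, cell_processed.annotation, acfg)
        by = out["by_epoch"]
        assert by["onset"] > by["locomotion"]
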