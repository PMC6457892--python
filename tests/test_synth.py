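"""The synthetic-session generator: velocity structure, placement rules,
kernel, reproducibility, photometry model, rewards and controls."""

import numpy as np
import pytest

from chisync.config import AnalysisConfig
from chisync.preprocessing import RawTrace, bin_trace, compute_dff, compute_kinematics
from chisync.synth import (
    PlacementError,
    SynthConfig,
    double_exp_kernel,
    generate_cell_population,
    generate_population_photometry,
    generate_reward_stream,
    generate_session,
    generate_velocity,
)


class TestVelocityGeneration:
    def test_zero_rates_give_pure_rest(self):
        cfg = SynthConfig(seed=0, duration_s=60.0, jerk_rate_per_min=0,
                          initiation_rate_per_min=0, micro_rate_per_min=0)
        v, gt = generate_velocity(cfg)
        assert gt.movement_events == []
        assert np.abs(v).max() < 0.2

    def test_generated_events_satisfy_the_printed_rules(self):
        # jerks cross 0.2, peak >=1 within 1 s, stay <2.2 in the 1-2 s
        # window; initiations average >4.5 over 0.5-2 s; micro stays <0.2
        cfg = SynthConfig(seed=3, duration_s=300.0)
        v, gt = generate_velocity(cfg)
        rate = cfg.raw_rate_hz
        for t, kind in gt.movement_events:
            i = int(t * rate)
            if kind == "jerk":
                # crossing recorded on the noise-free waveform; allow the
                # encoder-noise floor at the exact crossing sample
                assert v[i:i + 50].max() > 0.2
                assert v[i:i + 1000].max() >= 1.0
                assert np.abs(v[i + 1000:i + 2000]).max() < 2.2
                # quiet before the onset (outside the bump's own sub-
                # threshold rise and the encoder noise floor)
                assert np.abs(v[i - 500:i - 60]).max() <= 0.2
            elif kind == "initiation":
                assert v[i + 500:i + 2000].mean() > 4.5
                assert np.abs(v[i - 500:i - 60]).max() <= 0.2
            elif kind == "micro":
                # sub-threshold at the classifier's 10 ms resolution
                seg = v[i - 100:i + 1100]
                binned = seg[: seg.size // 10 * 10].reshape(-1, 10).mean(1)
                assert np.abs(binned).max() < 0.2
            elif kind == "termination":
                assert np.abs(v[i + 10:i + 1000]).max() < 2.2

    def test_requested_counts_are_delivered(self):
        cfg = SynthConfig(seed=7, duration_s=300.0, jerk_rate_per_min=0.6,
                          initiation_rate_per_min=0.4, micro_rate_per_min=0)
        _, gt = generate_velocity(cfg)
        assert len(gt.events_of("jerk")) == 3
        assert len(gt.events_of("initiation")) == 2
        assert len(gt.events_of("termination")) == 2

    def test_impossible_rates_raise_placement_error(self):
        cfg = SynthConfig(seed=0, duration_s=60.0, jerk_rate_per_min=40.0)
        with pytest.raises(PlacementError):
            generate_velocity(cfg)

    def test_event_times_inside_session_and_types_closed(self):
        cfg = SynthConfig(seed=9, duration_s=200.0)
        _, gt = generate_velocity(cfg)
        gt.validate()  # raises on out-of-range times or unknown types


class TestKernel:
    def test_sub_second_full_width(self):
        k = double_exp_kernel(0.05, 0.4, 1000.0)
        above_half = (k > 0.5).sum() / 1000.0
        assert 0.1 < above_half < 1.0

    def test_negative_constants_rejected(self):
        with pytest.raises(ValueError):
            double_exp_kernel(-0.05, 0.4, 1000.0)


class TestCellPopulation:
    def test_zero_cells_is_empty_not_an_error(self):
        cfg = SynthConfig(seed=0, duration_s=60.0, n_cells=0)
        v, gt = generate_velocity(cfg)
        traces, pos, per_cell = generate_cell_population(v, gt, cfg)
        assert traces.shape[0] == 0
        assert per_cell == []

    def test_full_participation_without_noise_synchronizes_every_cell(self):
        cfg = SynthConfig(seed=1, duration_s=200.0, n_cells=5,
                          participation_prob_onset=1.0, noise_sd=0.0,
                          transient_jitter_s=0.0, micro_rate_per_min=0,
                          rest_event_rate_per_min=0, async_rate_locomotion=0,
                          initiation_rate_per_min=0, jerk_rate_per_min=3.0)
        session = generate_session(cfg)
        gt = session.ground_truth
        onsets = [t for t, _ in gt.onset_events()]
        assert onsets
        for ts in gt.cell_transients:
            for t in onsets:
                assert any(abs(x - t) < 1e-9 for x in ts)
        # noiseless co-generated traces are identical inside event windows
        rate = cfg.cell_rate_hz
        i = int(onsets[0] * rate)
        win = session.cell_traces[:, i:i + 30]
        amps = win.max(axis=1) - 1.0
        norm = (win - 1.0) / amps[:, None]
        corr = np.corrcoef(norm)
        assert np.allclose(corr, 1.0, atol=1e-9)

    def test_higher_participation_raises_pairwise_correlation(self):
        # Monte-Carlo over 20 seeds: mean pairwise zero-lag correlation of
        # event-window traces grows with the participation probability
        def mean_corr(p, seed):
            cfg = SynthConfig(seed=seed, duration_s=120.0, n_cells=6,
                              participation_prob_onset=p, noise_sd=0.01,
                              micro_rate_per_min=0, rest_event_rate_per_min=0,
                              async_rate_locomotion=0.0,
                              initiation_rate_per_min=0, jerk_rate_per_min=4.0)
            s = generate_session(cfg)
            x = s.cell_traces
            return np.mean(np.corrcoef(x)[np.triu_indices(x.shape[0], 1)])

        hi = np.mean([mean_corr(1.0, s) for s in range(20)])
        lo = np.mean([mean_corr(0.3, s) for s in range(20)])
        assert hi > lo

    def test_locomotion_async_rate_keeps_single_cell_rate_up(self):
        cfg = SynthConfig(seed=2, duration_s=300.0, n_cells=6,
                          async_rate_locomotion=0.5,
                          initiation_rate_per_min=2.0, jerk_rate_per_min=1.0)
        s = generate_session(cfg)
        gt = s.ground_truth
        bout_time = sum(b - a for a, b in gt.bouts)
        n_bout = sum(sum(1 for t in ts if any(a <= t < b for a, b in gt.bouts))
                     for ts in gt.cell_transients)
        rate = n_bout / (bout_time * cfg.n_cells)
        assert rate == pytest.approx(cfg.async_rate_locomotion, rel=0.5)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(seed=13, duration_s=120.0, n_cells=4, n_rewards=3)
        a = generate_session(cfg)
        b = generate_session(cfg)
        assert np.array_equal(a.velocity, b.velocity)
        for role in a.channels:
            assert np.array_equal(a.channels[role], b.channels[role])
        assert np.array_equal(a.cell_traces, b.cell_traces)
        assert a.ground_truth.movement_events == b.ground_truth.movement_events

    def test_different_seeds_differ(self):
        a = generate_session(SynthConfig(seed=1, duration_s=60.0))
        b = generate_session(SynthConfig(seed=2, duration_s=60.0))
        assert not np.array_equal(a.velocity, b.velocity)


class TestPhotometryModel:
    def test_static_indicator_with_zero_gain_is_activity_free(self, acfg):
        cfg = SynthConfig(seed=4, duration_s=300.0, static_indicator=True,
                          artifact_gain=0.0)
        s = generate_session(cfg)
        binned = bin_trace(RawTrace(s.channels["static_pop"], 1000.0), 0.01)
        tr = compute_dff(binned, acfg, s.autofluorescence)
        from chisync.transients import calibrate_duration_thresholds, detect_transients
        th = calibrate_duration_thresholds([tr], acfg)
        evs = detect_transients(tr, th, acfg)
        from chisync.behavior import _runs
        mu, sd = tr.dff.mean(), tr.dff.std()
        excursions = len(_runs(tr.dff > mu + sd))
        assert len(evs) / max(excursions, 1) <= 0.01

    def test_da_channel_lag_is_recoverable(self, acfg):
        from chisync.coupling import population_xcorr
        cfg = SynthConfig(seed=6, duration_s=200.0, da_lag_s=0.11,
                          da_jerk_sign=1, da_velocity_gain=0.0,
                          noise_sd=0.05, jerk_rate_per_min=3.0)
        s = generate_session(cfg)
        a = bin_trace(RawTrace(s.channels["chi_pop"], 1000.0), 0.01)
        b = bin_trace(RawTrace(s.channels["da_pop"], 1000.0), 0.01)
        res = population_xcorr(a - a.mean(), b - b.mean(), None, acfg)
        assert res.peak_lag_s == pytest.approx(0.11, abs=0.011)

    def test_drive_length_mismatch_rejected(self):
        cfg = SynthConfig(seed=0, duration_s=10.0)
        with pytest.raises(ValueError, match="length"):
            generate_population_photometry(np.zeros(5), cfg)


class TestRewards:
    def test_zero_rewards_requested_gives_empty_streams(self):
        cfg = SynthConfig(seed=0, duration_s=120.0, n_rewards=0)
        s = generate_session(cfg)
        assert s.rewards is None

    def test_intervals_drawn_between_10_and_30_s(self):
        cfg = SynthConfig(seed=5, duration_s=600.0, n_rewards=100,
                          jerk_rate_per_min=0, initiation_rate_per_min=0,
                          micro_rate_per_min=0)
        v, gt = generate_velocity(cfg)
        stream = generate_reward_stream(cfg, None, v, gt)
        gaps = np.diff(stream.solenoid_times)
        assert gaps.min() >= 10.0 - 1e-9
        assert gaps.max() <= 60.0 + 1e-9  # skipped collisions may merge gaps

    def test_trialwise_coupling_ground_truth_is_positive(self, acfg):
        # rewards at rest accelerate, during bouts decelerate; the ChI
        # response scales with Δv, so the trialwise Pearson R is positive
        from chisync.alignment import trial_response_vs_velocity_change
        cfg = SynthConfig(seed=8, duration_s=600.0, n_rewards=40,
                          initiation_rate_per_min=1.0, jerk_rate_per_min=0.5,
                          micro_rate_per_min=0, rest_event_rate_per_min=0.5)
        s = generate_session(cfg)
        binned = bin_trace(RawTrace(s.channels["chi_pop"], 1000.0), 0.01)
        dff = compute_dff(binned, acfg, s.autofluorescence)
        kin = compute_kinematics(
            bin_trace(RawTrace(s.velocity, 1000.0, "velocity"), 0.01), acfg)
        out = trial_response_vs_velocity_change(
            dff.dff, kin.velocity, list(s.rewards), acfg)
        assert out["pearson_r"] > 0.3
        assert out["p_value"] < 0.05

    def test_lick_trains_follow_the_movement_change(self):
        cfg = SynthConfig(seed=5, duration_s=300.0, n_rewards=10,
                          jerk_rate_per_min=0, initiation_rate_per_min=0,
                          micro_rate_per_min=0)
        s = generate_session(cfg)
        for t in s.rewards:
            after = s.licks[(s.licks > t) & (s.licks < t + 2.0)]
            assert after.size > 0


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("participation_prob_onset", 1.5),
        ("jerk_rate_per_min", -1.0),
        ("kernel_decay_s", -0.4),
        ("da_jerk_sign", 0),
        ("n_cells", -2),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            SynthConfig(**{field: value})
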