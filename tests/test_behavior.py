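"""Behavioral state labeling and movement-event classification."""

import numpy as np
import pytest

from chisync.behavior import (
    annotate,
    detect_clean_onsets,
    detect_locomotion_bouts,
    detect_terminations,
    detect_velocity_extrema,
    label_states,
)
from chisync.preprocessing import compute_kinematics
from chisync.synth import SynthConfig, generate_velocity


def kin_from(v, acfg):
    return compute_kinematics(np.asarray(v, dtype=float), acfg)


def make_trace(n=3000):
    return np.zeros(n)


class TestLabelStates:
    def test_zero_velocity_is_rest_except_edges(self, acfg):
        labels = label_states(kin_from(make_trace(), acfg), acfg)
        assert set(labels[100:-100]) == {"rest"}
        assert set(labels[:100]) == {"unclassified"}

    def test_micro_scale_velocity_is_rest(self, acfg):
        # 0.15 cm/s sits below the 0.2 cm/s rest ceiling
        labels = label_states(kin_from(np.full(3000, 0.15), acfg), acfg)
        assert set(labels[100:-100]) == {"rest"}

    def test_step_marks_movement_around_the_step(self, acfg):
        v = make_trace()
        v[1500:] = 10.0
        labels = label_states(kin_from(v, acfg), acfg)
        assert set(labels[1405:1595]) == {"movement"}
        assert labels[1300] != "movement"


def bump(peak, rise_s=0.3, total_s=0.8, rate=100):
    t = np.arange(int(total_s * rate)) / rate
    return peak * np.sin(np.pi * t / total_s) ** 2


class TestCleanOnsets:
    def test_triangular_bump_is_a_jerk(self, acfg):
        v = make_trace()
        v[1000:1080] = bump(1.5)
        (t, kind), = detect_clean_onsets(kin_from(v, acfg), acfg)
        assert kind == "jerk"
        assert 9.9 <= t <= 10.4

    def test_sustained_ramp_is_an_initiation(self, acfg):
        v = make_trace()
        v[1000:1050] = np.linspace(0, 8.0, 50)
        v[1050:1400] = 8.0
        v[1400:1450] = np.linspace(8.0, 0.0, 50)
        events = detect_clean_onsets(kin_from(v, acfg), acfg)
        assert [k for _, k in events] == ["initiation"]

    def test_sub_centimeter_bump_is_not_an_onset(self, acfg):
        v = make_trace()
        v[1000:1080] = bump(0.8)  # peak below the 1 cm/s requirement
        assert detect_clean_onsets(kin_from(v, acfg), acfg) == []

    def test_pre_onset_movement_disqualifies(self, acfg):
        v = make_trace()
        v[960:990] = -0.3  # |v| > 0.2 inside the 0.5 s pre-window
        v[1000:1080] = bump(1.5)
        assert detect_clean_onsets(kin_from(v, acfg), acfg) == []

    def test_halved_velocity_turns_initiations_into_non_initiations(self, acfg):
        # thresholds are absolute: scaling an 8 cm/s initiation by 0.5
        # leaves a clean onset that no longer meets the 4.5 cm/s rule
        v = make_trace(4000)
        v[1000:1050] = np.linspace(0, 8.0, 50)
        v[1050:1400] = 8.0
        v[1400:1450] = np.linspace(8.0, 0.0, 50)
        full = detect_clean_onsets(kin_from(v, acfg), acfg)
        half = detect_clean_onsets(kin_from(0.5 * v, acfg), acfg)
        assert [k for _, k in full] == ["initiation"]
        assert half and all(k != "initiation" for _, k in half)


class TestBoutsAndTerminations:
    def test_ten_seconds_above_threshold_is_one_bout(self, acfg):
        v = make_trace()
        v[1000:2000] = 6.0
        bouts = detect_locomotion_bouts(kin_from(v, acfg), acfg)
        assert len(bouts) == 1
        start, end = bouts[0]
        assert end - start == pytest.approx(10.0, abs=0.3)

    def test_two_seconds_is_no_bout(self, acfg):
        v = make_trace()
        v[1000:1200] = 6.0
        assert detect_locomotion_bouts(kin_from(v, acfg), acfg) == []

    def test_stride_oscillation_does_not_fragment_the_bout(self, acfg):
        t = np.arange(1000) / 100.0
        v = make_trace()
        v[1000:2000] = 6.0 + 1.0 * np.sin(2 * np.pi * 3.0 * t)
        bouts = detect_locomotion_bouts(kin_from(v, acfg), acfg)
        assert len(bouts) == 1

    def test_decay_to_rest_yields_one_termination(self, acfg):
        v = make_trace()
        v[1000:2000] = 6.0
        v[2000:2100] = np.linspace(6.0, 0.0, 100)
        kin = kin_from(v, acfg)
        bouts = detect_locomotion_bouts(kin, acfg)
        terms = detect_terminations(kin, bouts, acfg)
        assert len(terms) == 1
        # crossing at v = 2.2 on the decay ramp
        assert terms[0] == pytest.approx(20.0 + (6.0 - 2.2) / 6.0, abs=0.1)

    def test_brief_dip_with_reacceleration_is_not_a_termination(self, acfg):
        v = make_trace(4000)
        v[1000:2000] = 6.0
        v[2000:2030] = 2.0  # 0.3 s dip, then re-acceleration
        v[2030:2600] = 6.0
        v[2600:2700] = np.linspace(6.0, 0.0, 100)
        kin = kin_from(v, acfg)
        bouts = detect_locomotion_bouts(kin, acfg)
        terms = detect_terminations(kin, bouts, acfg)
        # only the final decay terminates; the dip's hold is violated
        assert len(terms) == 1
        assert terms[0] > 26.0


class TestVelocityExtrema:
    def test_monotone_bout_has_no_interior_extrema(self, acfg):
        v = make_trace()
        v[1000:2000] = np.linspace(5.0, 9.0, 1000)
        v[2000:2500] = 9.0  # stay up past the bout end: no edge artifacts
        kin = kin_from(v, acfg)
        bouts = [(10.0, 20.0)]
        assert detect_velocity_extrema(kin, bouts, acfg) == []

    def test_imposed_swell_gives_one_peak(self, acfg):
        t = np.arange(1500) / 100.0
        v = make_trace(3500)
        v[1000:2500] = 6.0 + 3.0 * np.exp(-((t - 7.5) ** 2) / 2.0)
        kin = kin_from(v, acfg)
        extrema = detect_velocity_extrema(kin, [(10.0, 25.0)], acfg)
        peaks = [t for t, k in extrema if k == "peak"]
        assert len(peaks) == 1
        assert peaks[0] == pytest.approx(17.5, abs=0.3)


class TestGeneratorRoundTrip:
    def test_all_clean_generator_events_recovered_with_types(
            self, basic_session, basic_processed):
        gt = basic_session.ground_truth
        ann = basic_processed.annotation
        for kind in ("jerk", "initiation", "termination"):
            truth = sorted(gt.events_of(kind))
            det = sorted(ann.event_times(kind))
            assert len(det) == len(truth), kind
            assert all(abs(d - t) <= 0.15 for d, t in zip(det, truth)), kind

    def test_micro_movements_are_labeled_rest(self, basic_session, basic_processed):
        ann = basic_processed.annotation
        for t in basic_session.ground_truth.events_of("micro"):
            assert ann.labels[int(t / ann.bin_s)] == "rest"

    def test_every_initiation_is_followed_by_a_bout(self, basic_processed):
        ann = basic_processed.annotation
        for t in ann.event_times("initiation"):
            assert any(t <= a <= t + 2.0 for a, _ in ann.bouts)

    def test_no_event_sits_in_a_rest_bin(self, basic_processed):
        ann = basic_processed.annotation
        for t, kind in ann.events:
            assert ann.labels[int(t / ann.bin_s)] != "rest", (t, kind)

    def test_annotation_is_deterministic(self, basic_processed, acfg):
        a = annotate(basic_processed.kin, acfg)
        b = annotate(basic_processed.kin, acfg)
        assert a.events == b.events
        assert a.bouts == b.bouts
        assert (a.labels == b.labels).all()
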