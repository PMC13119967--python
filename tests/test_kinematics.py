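"""Smoothing, repetition splitting, event detection and angle computation."""

import numpy as np
import pytest

from sts_neurokin import GeneratorConfig, SegmentationError, generate_trial
from sts_neurokin import kinematics as kin
from sts_neurokin.kinematics import StsEvents


def _as_markers(name_to_curve, n=None):
    """Build a minimal (n, 3) marker dict from 1D component curves."""
    out = {}
    for name, (x, y, z) in name_to_curve.items():
        n_ = len(x) if n is None else n
        arr = np.zeros((n_, 3))
        arr[:, 0], arr[:, 1], arr[:, 2] = x, y, z
        out[name] = arr
    return out


class TestSmoothing:
    def test_constant_trajectory_unchanged(self):
        m = {"C7": np.full((200, 3), 1.25)}
        out = kin.smooth_markers(m, 100.0)
        np.testing.assert_allclose(out["C7"], m["C7"], atol=1e-9)

    @pytest.mark.parametrize("freq,check", [
        (1.0, lambda amp: amp > 0.99),    # passband: preserved within 1%
        (40.0, lambda amp: amp < 0.05),   # 2x cutoff: attenuated >= 95%
    ])
    def test_frequency_response(self, freq, check):
        t = np.arange(2000) / 100.0
        m = {"C7": np.stack([np.sin(2 * np.pi * freq * t)] * 3, axis=1)}
        out = kin.smooth_markers(m, 100.0)["C7"][:, 0]
        amp = np.ptp(out[500:1500]) / 2.0  # steady-state, away from edges
        assert check(amp)

    def test_short_trajectory_names_marker(self):
        with pytest.raises(SegmentationError, match="RTROC"):
            kin.smooth_markers({"RTROC": np.zeros((5, 3))}, 100.0)


class TestSplitRepetitions:
    def test_five_repetitions_recovered(self, clean_block, clean_config):
        sm = kin.smooth_markers(clean_block.markers, clean_config.kin_rate)
        windows = kin.split_repetitions(sm, clean_config.kin_rate)
        assert len(windows) == 5
        # each window brackets exactly one ground-truth stand instant
        for w, ev in zip(windows, clean_block.truth.event_times):
            assert w[0] / clean_config.kin_rate < ev["stand"] < w[1] / clean_config.kin_rate

    def test_single_repetition(self, clean_trial, clean_config):
        sm = kin.smooth_markers(clean_trial.markers, clean_config.kin_rate)
        assert len(kin.split_repetitions(sm, clean_config.kin_rate)) == 1

    def test_constant_markers_no_movement(self):
        m = {"C7": np.full((1000, 3), 0.5)}
        with pytest.raises(SegmentationError, match="no movement"):
            kin.split_repetitions(m, 100.0)


class TestDetectEvents:
    def test_noise_free_recovery_within_two_samples(self, clean_block, clean_config):
        rate = clean_config.kin_rate
        sm = kin.smooth_markers(clean_block.markers, rate)
        windows = kin.split_repetitions(sm, rate)
        for w, truth in zip(windows, clean_block.truth.event_times):
            ev = kin.detect_events(sm, rate, w)
            for key in ("start", "liftoff", "stand", "end"):
                assert abs(getattr(ev, key) - truth[key]) <= 2.0 / rate + 1e-9

    def test_noisy_recovery_at_default_marker_noise(self):
        # 0.5 mm white marker noise: median error <= 2 samples, >= 90% of
        # events within 5 samples (the Stand apex rule owns the tail)
        errors = []
        for s in range(6):
            cfg = GeneratorConfig(emg_noise_sd=0.0, spike_rate=0.0, seed=s)
            tr = generate_trial(cfg, f"S{s:02d}", "free_arms", n_repetitions=3)
            sm = kin.smooth_markers(tr.markers, cfg.kin_rate)
            for w, truth in zip(kin.split_repetitions(sm, cfg.kin_rate),
                                tr.truth.event_times):
                ev = kin.detect_events(sm, cfg.kin_rate, w)
                for key in ("start", "liftoff", "stand", "end"):
                    errors.append(abs(getattr(ev, key) - truth[key])
                                  * cfg.kin_rate)
        errors = np.array(errors)
        assert np.median(errors) <= 2.0
        assert np.mean(errors <= 5.0) >= 0.9

    def test_trapezoidal_speed_start_threshold(self):
        # C7 X integrates a trapezoidal speed with unit peak; brute-force
        # scan of the profile is the oracle for the 10%-of-peak crossing
        rate = 100.0
        t = np.arange(1200) / rate
        speed = np.interp(t, [0, 2, 3, 6, 7, 12], [0, 0, 1, 1, 0, 0])
        x = np.cumsum(speed) / rate
        bump = np.exp(-0.5 * ((t - 4.5) / 0.8) ** 2)
        markers = _as_markers({
            "C7": (x, 1.2 + 0.3 * bump, np.zeros_like(t)),
            "RTROC": (np.zeros_like(t), 0.5 + 0.4 * bump, np.zeros_like(t)),
            "LTROC": (np.zeros_like(t), 0.5 + 0.4 * bump, np.zeros_like(t)),
        })
        ev = kin.detect_events(markers, rate, (0, len(t)))
        oracle_speed = np.abs(np.gradient(x, 1.0 / rate))
        oracle_start = t[int(np.flatnonzero(
            oracle_speed >= 0.1 * oracle_speed.max())[0])]
        assert abs(ev.start - oracle_start) <= 1.0 / rate + 1e-9

    def test_time_reversal_mirrors_start_and_end(self, clean_trial, clean_config):
        rate = clean_config.kin_rate
        sm = kin.smooth_markers(clean_trial.markers, rate)
        fwd = kin.detect_events(sm, rate,
                                kin.split_repetitions(sm, rate)[0])
        rev_markers = {k: v[::-1].copy() for k, v in sm.items()}
        rev = kin.detect_events(rev_markers, rate,
                                kin.split_repetitions(rev_markers, rate)[0])
        total = (len(clean_trial.t_kin) - 1) / rate
        assert abs(rev.start - (total - fwd.end)) <= 2.0 / rate + 1e-9
        assert abs(rev.end - (total - fwd.start)) <= 2.0 / rate + 1e-9

    def test_event_order_enforced(self):
        with pytest.raises(SegmentationError):
            StsEvents(start=2.0, liftoff=1.0, stand=3.0, end=4.0)

    def test_translation_and_scale_invariance(self, clean_trial, clean_config):
        rate = clean_config.kin_rate
        sm = kin.smooth_markers(clean_trial.markers, rate)
        w = kin.split_repetitions(sm, rate)[0]
        base = kin.detect_events(sm, rate, w)
        shifted = {k: v + np.array([1.3, -0.2, 4.0]) for k, v in sm.items()}
        scaled = {k: 2.5 * v for k, v in sm.items()}
        for variant in (shifted, scaled):
            ev = kin.detect_events(variant, rate,
                                   kin.split_repetitions(variant, rate)[0])
            assert ev == base


class TestDuration:
    def test_simple_subtraction(self):
        ev = StsEvents(start=1.0, liftoff=2.0, stand=3.0, end=5.2)
        assert kin.movement_duration(ev) == pytest.approx(4.2)

    def test_matches_generator_truth(self, clean_trial, clean_config):
        rate = clean_config.kin_rate
        sm = kin.smooth_markers(clean_trial.markers, rate)
        ev = kin.detect_events(sm, rate, kin.split_repetitions(sm, rate)[0])
        truth = clean_trial.truth.event_times[0]
        assert kin.movement_duration(ev) == pytest.approx(
            truth["end"] - truth["start"], abs=0.04)


class TestTrunkAngles:
    @pytest.mark.parametrize("vec,sag,front", [
        ((0.0, 1.0, 0.0), 0.0, 0.0),
        ((1.0, 1.0, 0.0), 45.0, 0.0),
        ((0.0, 1.0, 1.0), 0.0, 45.0),
    ])
    def test_reference_orientations(self, vec, sag, front):
        n = 10
        markers = {
            "SACR": np.zeros((n, 3)),
            "C7": np.tile(np.asarray(vec, dtype=float), (n, 1)),
        }
        out = kin.trunk_angles(markers)
        np.testing.assert_allclose(out["trunk_sag"], sag, atol=1e-9)
        np.testing.assert_allclose(out["trunk_front"], front, atol=1e-9)

    def test_zero_length_vector_rejected(self):
        markers = {"SACR": np.zeros((5, 3)), "C7": np.zeros((5, 3))}
        with pytest.raises(ValueError):
            kin.trunk_angles(markers)


def _pose_markers(thigh_vec, shank_vec, foot_vec, trunk_vec, n=5):
    """Assemble both-side marker chains for a static pose."""
    markers = {"SACR": np.zeros((n, 3)),
               "C7": np.tile(trunk_vec, (n, 1)).astype(float)}
    for p in ("R", "L"):
        mall = np.zeros(3)
        femepi = mall + shank_vec
        troc = femepi + thigh_vec
        heel = mall + np.array([-0.05, -0.05, 0.0])
        met5 = heel + foot_vec
        for name, point in (("MALL", mall), ("FEMEPI", femepi),
                            ("TROC", troc), ("HEEL", heel), ("MET5", met5)):
            markers[f"{p}{name}"] = np.tile(point, (n, 1)).astype(float)
    return markers


class TestPlanarJointAngles:
    def test_neutral_standing_pose(self):
        markers = _pose_markers(
            thigh_vec=np.array([0.0, 0.44, 0.0]),
            shank_vec=np.array([0.0, 0.43, 0.0]),
            foot_vec=np.array([0.2, 0.0, 0.0]),
            trunk_vec=np.array([0.0, 0.5, 0.0]))
        out = kin.planar_joint_angles(markers)
        for side in ("MI", "LI"):
            np.testing.assert_allclose(out[f"hip_{side}"], 0.0, atol=1e-9)
            np.testing.assert_allclose(out[f"knee_{side}"], 0.0, atol=1e-9)
            np.testing.assert_allclose(out[f"ankle_{side}"], 0.0, atol=1e-9)

    def test_seated_right_angles(self):
        # vertical trunk and shank, horizontal thigh -> hip 90, knee 90
        markers = _pose_markers(
            thigh_vec=np.array([-0.44, 0.0, 0.0]),
            shank_vec=np.array([0.0, 0.43, 0.0]),
            foot_vec=np.array([0.2, 0.0, 0.0]),
            trunk_vec=np.array([0.0, 0.5, 0.0]))
        out = kin.planar_joint_angles(markers)
        np.testing.assert_allclose(out["hip_MI"], 90.0, atol=1e-9)
        np.testing.assert_allclose(out["knee_MI"], 90.0, atol=1e-9)

    def test_missing_marker_named(self):
        markers = _pose_markers(np.array([0.0, 0.44, 0.0]),
                                np.array([0.0, 0.43, 0.0]),
                                np.array([0.2, 0.0, 0.0]),
                                np.array([0.0, 0.5, 0.0]))
        del markers["LTROC"]
        with pytest.raises(KeyError, match="LTROC"):
            kin.planar_joint_angles(markers)

    def test_recovers_generator_commanded_knee(self, clean_trial, clean_config):
        sm = kin.smooth_markers(clean_trial.markers, clean_config.kin_rate)
        out = kin.planar_joint_angles(sm)
        for side in ("MI", "LI"):
            cmd = clean_trial.truth.commanded_angles[f"knee_{side}"]
            rms = np.sqrt(np.mean((out[f"knee_{side}"] - cmd) ** 2))
            assert rms < 2.0

    def test_translation_invariance(self, clean_trial, clean_config):
        sm = kin.smooth_markers(clean_trial.markers, clean_config.kin_rate)
        shifted = {k: v + np.array([0.7, 1.1, -0.4]) for k, v in sm.items()}
        a = kin.planar_joint_angles(sm)
        b = kin.planar_joint_angles(shifted)
        for key in a:
            np.testing.assert_allclose(a[key], b[key], atol=1e-9)


class TestLabelPhases:
    def test_boundaries_at_expected_nodes(self):
        ev = StsEvents(start=0.0, liftoff=2.0, stand=5.0, end=10.0)
        labels = kin.label_phases(ev, seat_contact=8.0, pad_s=0.0)
        assert len(labels) == 101
        assert labels[19] == "preparatory" and labels[20] == "rising"
        assert labels[49] == "rising" and labels[50] == "lowering"
        assert labels[79] == "lowering" and labels[80] == "final"

    def test_partition_covers_all_nodes(self):
        ev = StsEvents(start=1.0, liftoff=1.7, stand=3.3, end=5.9)
        labels = kin.label_phases(ev)
        counts = {p: int(np.sum(labels == p)) for p in kin.PHASES}
        assert sum(counts.values()) == 101
        # labels are contiguous
        changes = np.sum(labels[1:] != labels[:-1])
        assert changes == 3

    def test_generator_defaults_place_stand_near_midcycle(
            self, clean_trial, clean_config):
        rate = clean_config.kin_rate
        sm = kin.smooth_markers(clean_trial.markers, rate)
        w = kin.split_repetitions(sm, rate)[0]
        ev = kin.detect_events(sm, rate, w)
        sc = kin.seat_contact_time(sm, rate, w, ev)
        labels = kin.label_phases(ev, seat_contact=sc)
        boundary = int(np.flatnonzero(labels == "lowering")[0])
        assert abs(boundary - 50) <= 3
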