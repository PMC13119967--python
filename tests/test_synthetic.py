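"""Generator contracts: shapes, determinism, planted truth, artifact injection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sts_neurokin import (
    ConfigurationError,
    GeneratorConfig,
    SurplusSpec,
    generate_cohort,
    generate_trial,
    inject_spikes,
)
from sts_neurokin.config import EMG_CHANNELS, MARKER_NAMES, MUSCLES


class TestTrialStructure:
    def test_marker_and_channel_counts(self, clean_trial):
        # bilateral 7-muscle montage -> 14 channels; 28-marker protocol
        assert len(clean_trial.markers) == 28
        assert set(clean_trial.markers) == set(MARKER_NAMES)
        assert len(clean_trial.emg) == 14
        assert set(clean_trial.emg) == set(EMG_CHANNELS)

    def test_synchronized_time_bases(self, clean_trial):
        assert clean_trial.t_kin[0] == 0.0
        assert clean_trial.t_emg[0] == 0.0
        n = len(clean_trial.t_kin)
        for xyz in clean_trial.markers.values():
            assert xyz.shape == (n, 3)
        m = len(clean_trial.t_emg)
        for ch in clean_trial.emg.values():
            assert ch.shape == (m,)

    def test_truth_event_ordering(self, clean_block):
        prev_end = -np.inf
        for ev in clean_block.truth.event_times:
            assert ev["start"] < ev["liftoff"] < ev["stand"] < ev["end"]
            assert ev["start"] > prev_end  # repetitions ordered, non-overlapping
            prev_end = ev["end"]


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"phase_fractions": (0.5, 0.5, 0.1, 0.1)},
        {"phase_fractions": (1.0, 0.0, 0.0, 0.0)},
        {"kin_rate": -100.0},
        {"emg_rate": 50.0},  # below kin_rate
        {"n_repetitions": 0},
        {"cycle_duration_range": (0.0, 2.0)},
        {"conditions": ("hands_on_hips",)},
        {"side_asymmetry": {"BICEPS": {"amplitude": 2.0}}},
    ])
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(**kwargs)

    @given(st.floats(0.05, 0.45), st.floats(0.05, 0.45))
    @settings(max_examples=20, deadline=None)
    def test_valid_phase_fractions_accepted(self, f1, f2):
        rest = 1.0 - f1 - f2
        cfg = GeneratorConfig(phase_fractions=(f1, f2, rest / 2, rest / 2))
        assert abs(sum(cfg.phase_fractions) - 1.0) < 1e-9


class TestDeterminism:
    def test_same_seed_identical_trial(self, clean_config):
        a = generate_trial(clean_config, "S02", "crossed_arms")
        b = generate_trial(clean_config, "S02", "crossed_arms")
        for name in a.markers:
            np.testing.assert_array_equal(a.markers[name], b.markers[name])
        for ch in a.emg:
            np.testing.assert_array_equal(a.emg[ch], b.emg[ch])

    def test_cohort_reproducible_and_counted(self):
        cfg = GeneratorConfig(n_subjects=2, n_repetitions=2,
                              cycle_duration_range=(2.0, 3.0), seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        assert len(a.trials) == 2 * 2 * 2  # subjects x conditions x repetitions
        assert a.manifest.shape[0] == 8
        np.testing.assert_array_equal(a.trials[0].emg["LD_MI"],
                                      b.trials[0].emg["LD_MI"])
        pd_equal = a.manifest.equals(b.manifest)
        assert pd_equal

    def test_full_protocol_cohort_size(self):
        cfg = GeneratorConfig(n_subjects=7, n_repetitions=5,
                              cycle_duration_range=(2.0, 2.5), seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort.trials) == 70  # 7 subjects x 2 conditions x 5 reps

    def test_single_trial_per_condition(self):
        cfg = GeneratorConfig(n_subjects=1, n_repetitions=1,
                              cycle_duration_range=(2.0, 2.5), seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort.trials) == len(cfg.conditions)


class TestPlantedTruth:
    def test_symmetric_world_has_identical_model_envelopes(self, clean_trial):
        # side_asymmetry 1.0 and no surplus -> MI and LI model envelopes equal
        for m in MUSCLES:
            np.testing.assert_array_equal(
                clean_trial.truth.envelope_model[f"{m}_MI"],
                clean_trial.truth.envelope_model[f"{m}_LI"])

    def test_surplus_confined_to_planted_interval(self, clean_config):
        cfg = clean_config.with_(
            surplus=(SurplusSpec(muscle="LD", center=0.65, width=0.07,
                                 amplitude=0.3),))
        tr = generate_trial(cfg, "S01", "free_arms")
        diff = (tr.truth.envelope_model["LD_MI"]
                - tr.truth.envelope_model["LD_LI"])
        nodes = np.linspace(0, 1, 101)
        inside = (nodes >= 0.5) & (nodes <= 0.8)
        assert diff[inside].max() > 0.25
        assert np.all(diff[~inside] < 0.1)
        # other muscles untouched
        np.testing.assert_array_equal(tr.truth.envelope_model["MF_MI"],
                                      tr.truth.envelope_model["MF_LI"])


class TestInjectSpikes:
    def test_zero_rate_is_identity(self, rng):
        x = rng.standard_normal(5000)
        out, idx = inject_spikes(x, 0.0, 10.0, 1000.0, rng)
        np.testing.assert_array_equal(out, x)
        assert idx.size == 0

    def test_spikes_exceed_clipping_threshold(self, rng):
        x = rng.standard_normal(20000)
        pre_sd = 1.4826 * np.median(np.abs(x - np.median(x)))
        out, idx = inject_spikes(x, 2.0, 10.0, 1000.0, rng)
        assert idx.size > 0
        assert np.all(np.abs(out[idx]) > 5.0 * pre_sd)

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            inject_spikes(np.zeros(10), -1.0, 10.0, 1000.0, rng)

    def test_seed_changes_times_not_count_distribution(self):
        x = np.random.default_rng(0).standard_normal(10000)
        counts_a, counts_b = [], []
        first_idx = {}
        for fam, counts in ((1, counts_a), (2, counts_b)):
            for r in range(40):
                g = np.random.default_rng(1000 * fam + r)
                _, idx = inject_spikes(x, 1.0, 10.0, 1000.0, g)
                counts.append(idx.size)
                if r == 0:
                    first_idx[fam] = idx
        assert not np.array_equal(first_idx[1], first_idx[2])
        # same Poisson count distribution across seed families
        assert stats.ks_2samp(counts_a, counts_b).pvalue > 0.01
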