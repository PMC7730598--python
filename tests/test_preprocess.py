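"""Conditioning chain: filtering, stance detection, normalization,
mirroring, variance filter, tensor assembly and unfolding."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kneeload as kl
from kneeload.errors import ConfigurationError, ContractError, DataError, DomainError
from kneeload.preprocess import (
    ProcessedTrial,
    StanceInterval,
    assemble,
    build_tensor,
    detect_stance,
    downsample_grf,
    drop_low_variance,
    lowpass,
    mirror_left,
    normalize_bw,
    preprocess_trial,
    unfold,
)


class TestLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(lowpass(x, 6.0, 100.0), x, atol=1e-9)

    def test_high_frequency_tone_strongly_attenuated(self):
        t = np.arange(10000) / 1000.0
        tone = np.sin(2 * np.pi * 50 * t)
        out = lowpass(tone, 6.0, 1000.0)
        assert np.abs(out[500:-500]).max() < np.abs(tone).max() / 100

    def test_superposition_keeps_low_frequency_component(self):
        t = np.arange(10000) / 1000.0
        low = np.sin(2 * np.pi * 1 * t)
        mixed = low + np.sin(2 * np.pi * 50 * t)
        out = lowpass(mixed, 6.0, 1000.0)
        core = slice(500, -500)  # away from filter edge transients
        rms = np.sqrt(np.mean((out[core] - low[core]) ** 2))
        assert rms < 0.02

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            lowpass(np.zeros(100), 50.0, 100.0)


class TestDownsampleGrf:
    def test_constant_signal_identical(self, small_profiles, small_cfg):
        trial = kl.synthesize_trial(small_profiles[0], "right", 3, small_cfg)
        flat = replace_grf(trial, np.ones((3, trial.grf.shape[1])) * 5.0)
        out = downsample_grf(flat, cutoff_hz=None)
        np.testing.assert_allclose(out, 5.0)

    def test_linear_ramp_exact_at_kept_indices(self, one_trial):
        ramp = np.tile(np.arange(one_trial.grf.shape[1], dtype=float), (3, 1))
        trial = replace_grf(one_trial, ramp)
        out = downsample_grf(trial, cutoff_hz=None)
        np.testing.assert_array_equal(out, ramp[:, ::10][:, : out.shape[1]])

    def test_output_length_matches_angle_grid(self, one_trial):
        assert downsample_grf(one_trial).shape[1] == one_trial.angles.shape[1]

    def test_non_integer_ratio_rejected_at_construction(self, one_trial):
        with pytest.raises(ConfigurationError):
            kl.GaitTrial(
                subject=one_trial.subject, side=one_trial.side,
                speed=one_trial.speed, angle_rate=96.0,
                angles=one_trial.angles, grf_rate=1000.0, grf=one_trial.grf,
            )


def replace_grf(trial, grf):
    return kl.GaitTrial(
        subject=trial.subject, side=trial.side, speed=trial.speed,
        angle_rate=trial.angle_rate, angles=trial.angles,
        grf_rate=trial.grf_rate, grf=grf,
    )


class TestNormalizeBw:
    def test_definition(self):
        assert normalize_bw(np.array([686.7]), 70.0)[0] == pytest.approx(1.0, abs=1e-3)

    def test_zero_maps_to_zero_and_linearity(self):
        f = np.array([0.0, 100.0, -50.0])
        np.testing.assert_allclose(normalize_bw(2 * f, 70.0),
                                   2 * normalize_bw(f, 70.0))
        assert normalize_bw(np.zeros(3), 70.0).sum() == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(DomainError):
            normalize_bw(np.ones(3), 0.0)


class TestMirrorLeft:
    @pytest.fixture()
    def left_processed(self, small_profiles, small_cfg):
        trial = kl.synthesize_trial(small_profiles[0], "left", 3, small_cfg)
        kcf = kl.attach_ground_truth(trial)
        return preprocess_trial(trial, kcf, mirror=False)

    def test_z_channels_negated_others_untouched(self, left_processed):
        out = mirror_left(left_processed)
        np.testing.assert_array_equal(out.grf[2], -left_processed.grf[2])
        np.testing.assert_array_equal(out.grf[:2], left_processed.grf[:2])
        np.testing.assert_array_equal(out.kcf[2], -left_processed.kcf[2])
        np.testing.assert_array_equal(out.kcf[5], -left_processed.kcf[5])
        np.testing.assert_array_equal(out.kcf[[0, 1, 3, 4]],
                                      left_processed.kcf[[0, 1, 3, 4]])
        np.testing.assert_array_equal(out.angles, left_processed.angles)

    def test_double_mirror_rejected_by_units_tracking(self, left_processed):
        once = mirror_left(left_processed)
        with pytest.raises(ContractError):
            mirror_left(once)

    def test_right_side_rejected(self, one_processed):
        with pytest.raises(ContractError):
            mirror_left(one_processed)

    @given(z=st.lists(st.floats(-10, 10, allow_nan=False), min_size=3, max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_negation_is_involution(self, z):
        arr = np.array(z)
        np.testing.assert_array_equal(-(-arr), arr)

    def test_preprocess_rejects_processed_input(self, one_processed):
        with pytest.raises(ContractError):
            preprocess_trial(one_processed, None)


class TestDetectStance:
    def _processed_with_vertical(self, template, vertical):
        return ProcessedTrial(
            subject_id="X", side="right", speed=3.0, mass=70.0, rate=100.0,
            angles=np.zeros((13, len(vertical))),
            grf=np.vstack([np.zeros(len(vertical)), vertical,
                           np.zeros(len(vertical))]),
            kcf=np.zeros((6, len(vertical))),
        )

    def test_square_wave_intervals_recovered_to_one_sample(self, one_processed):
        vertical = np.zeros(1000)
        spans = [(100, 160), (300, 380), (600, 655)]
        for s, e in spans:
            vertical[s:e] = 1.0
        pt = self._processed_with_vertical(one_processed, vertical)
        intervals = detect_stance(pt)
        assert len(intervals) == len(spans)
        for interval, (s, e) in zip(intervals, spans):
            assert abs(interval.start_index - s) <= 1
            assert abs(interval.end_index - e) <= 1

    def test_all_zero_grf_yields_empty_list(self, one_processed):
        pt = self._processed_with_vertical(one_processed, np.zeros(500))
        assert detect_stance(pt) == []

    def test_boundary_touching_stances_discarded(self, one_processed):
        vertical = np.zeros(400)
        vertical[:50] = 1.0  # clipped heel strike
        vertical[360:] = 1.0  # clipped toe off
        vertical[150:220] = 1.0
        pt = self._processed_with_vertical(one_processed, vertical)
        intervals = detect_stance(pt)
        assert len(intervals) == 1
        assert intervals[0].start_index == pytest.approx(150, abs=1)

    def test_chatter_shorter_than_hysteresis_ignored(self, one_processed):
        vertical = np.zeros(600)
        vertical[100:200] = 1.0
        vertical[201] = 1.0  # 10 ms blip after a 10 ms gap: merged
        pt = self._processed_with_vertical(one_processed, vertical)
        intervals = detect_stance(pt)
        assert len(intervals) == 1
        assert intervals[0].end_index >= 200

    def test_walking_trial_has_at_least_four_stances(self, one_stances):
        assert len(one_stances) >= 4


class TestVarianceFilter:
    def test_full_variable_set_leaves_16_inputs_5_outputs(self, small_tensor):
        assert len(small_tensor.feature_names) == 16
        assert len(small_tensor.target_names) == 5
        assert "lat_x" not in small_tensor.target_names

    def test_matches_brute_force_sd(self, small_trials):
        from kneeload.msk import compute_kcf

        processed = []
        stances = []
        for trial in small_trials[:3]:
            pt = preprocess_trial(trial, compute_kcf(trial))
            processed.append(pt)
            stances.append(detect_stance(pt))
        tensor = assemble(processed, stances)
        pooled_x = np.concatenate(tensor.X, axis=1)
        pooled_y = np.concatenate(tensor.Y, axis=1)
        threshold = 1e-6
        expected_x = [n for n, sd in zip(tensor.feature_names, pooled_x.std(axis=1))
                      if sd >= threshold]
        expected_y = [n for n, sd in zip(tensor.target_names, pooled_y.std(axis=1))
                      if sd >= threshold]
        filtered, report = drop_low_variance(tensor, threshold)
        assert filtered.feature_names == expected_x
        assert filtered.target_names == expected_y
        assert report["outputs_dropped"] == ["lat_x"]

    def test_zero_threshold_drops_nothing(self, small_trials):
        from kneeload.msk import compute_kcf

        pt = preprocess_trial(small_trials[0], compute_kcf(small_trials[0]))
        tensor = assemble([pt], [detect_stance(pt)])
        filtered, report = drop_low_variance(tensor, 0.0)
        assert filtered.target_names == tensor.target_names
        assert report["outputs_dropped"] == []

    def test_exactly_constant_feature_always_dropped(self, small_trials):
        from kneeload.msk import compute_kcf

        pt = preprocess_trial(small_trials[0], compute_kcf(small_trials[0]))
        tensor = assemble([pt], [detect_stance(pt)])
        for x in tensor.X:
            x[0, :] = 1.234  # freeze one input channel
        filtered, report = drop_low_variance(tensor, 1e-12)
        assert tensor.feature_names[0] in report["inputs_dropped"]


class TestAssembleAndUnfold:
    def test_stance_count_becomes_trial_count(self, one_processed, one_stances):
        tensor = assemble([one_processed, one_processed],
                          [one_stances, one_stances])
        assert tensor.n_trials == 2 * len(one_stances)

    def test_no_grf_gives_13_inputs(self, one_processed, one_stances):
        tensor = assemble([one_processed], [one_stances], use_grf=False)
        assert len(tensor.feature_names) == 13

    def test_metadata_round_trip(self, one_processed, one_stances):
        tensor = assemble([one_processed], [one_stances])
        assert set(tensor.meta["subject_id"]) == {one_processed.subject_id}
        assert set(tensor.meta["speed"]) == {one_processed.speed}

    def test_empty_stance_list_rejected(self, one_processed):
        with pytest.raises(DataError):
            assemble([one_processed], [[]])

    def test_unfold_row_count_and_order(self, small_tensor):
        samples = unfold(small_tensor, [0])
        assert samples.n_samples == small_tensor.lengths[0]
        np.testing.assert_array_equal(
            samples.provenance["time_index"], np.arange(samples.n_samples)
        )

    def test_unfold_partition_property(self, small_tensor):
        full = unfold(small_tensor)
        half_a = unfold(small_tensor, range(0, small_tensor.n_trials, 2))
        half_b = unfold(small_tensor, range(1, small_tensor.n_trials, 2))
        assert half_a.n_samples + half_b.n_samples == full.n_samples

    def test_unfold_regroups_to_original_tensor(self, small_tensor):
        samples = unfold(small_tensor)
        for m in range(small_tensor.n_trials):
            mask = samples.provenance["trial"] == m
            np.testing.assert_array_equal(
                samples.X[mask.to_numpy()], small_tensor.X[m].T
            )

    def test_unfold_empty_subset_rejected(self, small_tensor):
        with pytest.raises(DataError):
            unfold(small_tensor, [])


def test_build_tensor_smoke(small_trials):
    tensor, report = build_tensor(small_trials[:4])
    assert tensor.n_trials >= 4 * 4  # >= 4 stances per 6 s trial
    assert report["outputs_dropped"] == ["lat_x"]
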