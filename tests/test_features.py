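"""Segmentation, grouping, labeling and STFT spectrogram contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguecg import features as ft
from fatiguecg import synthetic as syn
from fatiguecg.errors import InvalidInputError, InvalidParameterError


def stft_oracle(x: np.ndarray, spec: ft.STFTSpec) -> np.ndarray:
    """Literal double-sum evaluation of the windowed DFT magnitude."""
    g = spec.window_values()
    n_frames = (len(x) - spec.n_window) // spec.hop + 1
    out = np.zeros((n_frames, spec.n_window))
    for i in range(n_frames):
        start = i * spec.hop
        for k in range(spec.n_window):
            acc = 0.0 + 0.0j
            for m in range(spec.n_window):
                acc += x[start + m] * g[m] * np.exp(-2j * np.pi * k * m / spec.n_window)
            out[i, k] = abs(acc)
    return out


class TestSegmentation:
    @pytest.mark.parametrize(
        "length,expected", [(1300, 10), (1365, 10), (129, 0), (130, 1), (259, 1)]
    )
    def test_segment_counts(self, length, expected):
        segments = ft.segment_signal(np.zeros(length))
        assert len(segments) == expected
        for i, seg in enumerate(segments):
            assert seg.start == i * 130 and seg.samples.shape == (130,)

    @pytest.mark.parametrize("n_segments,expected", [(60, 6), (9, 0), (25, 2), (10, 1)])
    def test_group_counts(self, n_segments, expected):
        segments = ft.segment_signal(np.zeros(130 * n_segments))
        assert len(ft.group_segments(segments)) == expected

    def test_group_signal_is_1300_samples(self):
        signal = np.arange(1300.0)
        (group,) = ft.group_segments(ft.segment_signal(signal))
        np.testing.assert_array_equal(group.signal, signal)

    def test_non_contiguous_segments_rejected(self):
        segments = ft.segment_signal(np.zeros(130 * 11))
        with pytest.raises(InvalidInputError):
            ft.SegmentGroup(tuple(segments[:5] + segments[6:11]), "N",
                            syn.SubjectProfile("a", 20, "male", "N"))

    @given(st.integers(min_value=0, max_value=20000))
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, length):
        segments = ft.segment_signal(np.zeros(length))
        groups = ft.group_segments(segments)
        assert len(segments) == length // 130
        assert len(groups) == (length // 130) // 10


class TestLabeling:
    @pytest.mark.parametrize("vas,expected", [(85, "F"), (80, "N"), (80.001, "F"), (0, "N"), (100, "F")])
    def test_threshold_rule_strictly_above_80(self, vas, expected):
        assert ft.label_from_vas(vas) == expected

    @pytest.mark.parametrize("vas", [-1, 101])
    def test_out_of_range_rejected(self, vas):
        with pytest.raises(InvalidInputError):
            ft.label_from_vas(vas)


class TestSTFT:
    def test_dc_concentration(self):
        spec = ft.STFTSpec(n_window=8, hop=8, window="rect")
        S = ft.stft(np.ones(8), spec).values
        assert S[0, 0] == pytest.approx(8.0, abs=1e-10)
        np.testing.assert_allclose(S[0, 1:], 0.0, atol=1e-10)

    def test_pure_cosine_two_bins(self):
        m = np.arange(8)
        spec = ft.STFTSpec(n_window=8, hop=8, window="rect")
        S = ft.stft(np.cos(2 * np.pi * 2 * m / 8), spec).values
        expected = np.zeros(8)
        expected[2] = expected[6] = 4.0
        np.testing.assert_allclose(S[0], expected, atol=1e-10)

    def test_matches_double_sum_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        spec = ft.STFTSpec(n_window=16, hop=4, window="hann")
        S = ft.stft(x, spec).values
        np.testing.assert_allclose(S, stft_oracle(x, spec), atol=1e-10)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(InvalidParameterError):
            ft.stft(np.zeros(16), ft.STFTSpec(n_window=32, hop=4))

    def test_invalid_hop_rejected(self):
        with pytest.raises(InvalidParameterError):
            ft.STFTSpec(n_window=8, hop=9)

    def test_parseval_with_rectangular_tiling(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=128)
        spec = ft.STFTSpec(n_window=16, hop=16, window="rect")
        S = ft.stft(x, spec).values
        assert np.sum(S**2) == pytest.approx(16 * np.sum(x**2), rel=1e-6)


class TestSpectrogramImage:
    def test_nonredundant_bins_retained(self):
        spec = ft.STFTSpec(n_window=16, hop=4, log_magnitude=False)
        img = ft.spectrogram_image(ft.stft(np.random.default_rng(2).normal(size=130), spec))
        assert img.shape[0] == 9  # k in [0, 8]

    def test_linear_scaling_of_zero_signal(self):
        spec = ft.STFTSpec(n_window=16, hop=4, log_magnitude=False)
        img = ft.spectrogram_image(ft.stft(np.zeros(130), spec))
        np.testing.assert_array_equal(img, 0.0)

    def test_log_floor_contract(self):
        spec = ft.STFTSpec(n_window=16, hop=4, log_magnitude=True, log_floor=1e-8)
        img = ft.spectrogram_image(ft.stft(np.zeros(130), spec))
        assert img.min() >= np.log(1e-8) - 1e-12

    def test_default_image_shape_from_130_samples(self):
        img = ft.spectrogram_image(ft.stft(np.random.default_rng(3).normal(size=130)))
        assert img.shape == (17, 25)


class TestBuildDataset:
    def test_example_count_from_60s_record(self):
        profile = syn.SubjectProfile("X", 20, "male", "N")
        record = syn.ECGRecord(
            np.random.default_rng(0).normal(size=60 * 130), 130.0, 40.0, profile
        )
        examples = ft.build_dataset([record])
        assert len(examples) == 6

    def test_high_vas_record_labeled_fatigue(self):
        profile = syn.SubjectProfile("X", 20, "male", "F")
        record = syn.ECGRecord(
            np.random.default_rng(1).normal(size=30 * 130), 130.0, 90.0, profile
        )
        examples = ft.build_dataset([record])
        assert examples and all(ex.label == "F" for ex in examples)

    def test_empty_record_list(self):
        assert ft.build_dataset([]) == []

    def test_count_conservation_across_records(self, small_cohort):
        examples = ft.build_dataset(small_cohort)
        expected = sum((len(r.samples) // 130) // 10 for r in small_cohort)
        assert len(examples) == expected

    def test_examples_carry_all_modalities(self, small_cohort):
        ex = ft.build_dataset(small_cohort[:1])[0]
        assert ex.signal.shape == (1300,)
        assert ex.images.shape == (10, 17, 25)
        assert ex.profile.subject_id == small_cohort[0].profile.subject_id


def test_save_load_roundtrip(tmp_path, small_cohort):
    examples = ft.build_dataset(small_cohort[:2])
    ft.save_examples(examples, tmp_path)
    back = ft.load_examples(tmp_path)
    assert len(back) == len(examples)
    for a, b in zip(examples, back):
        np.testing.assert_allclose(a.signal, b.signal)
        np.testing.assert_allclose(a.images, b.images)
        assert a.label == b.label and a.profile == b.profile
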