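"""Segmentation, characteristic samples, thresholds, discrimination, removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsescreen.criteria import chauvenet_coefficient_empirical
from pulsescreen.screening import (
    NoiseCallSet,
    build_thresholds,
    compute_group_stats,
    compute_segment_stats,
    detect_poor_contact_segments,
    detect_spike_segments,
    remove_noise,
    screen,
    segment_record,
    segmentation_shape,
)


def naive_calls(matrix: np.ndarray, group_count: int):
    """Direct elementwise transcription of the adaptive-threshold rules,
    used as an independent oracle for the vectorized pipeline."""
    m, n = matrix.shape
    means = np.array([sum(row) / n for row in matrix])
    stds = np.array(
        [(sum((v - mu) ** 2 for v in row) / (n - 1)) ** 0.5 for row, mu in zip(matrix, means)]
    )
    w_n = 1 + 0.4 * np.log(n)
    p1 = set()
    for i in range(m):
        for j in range(n):
            if abs(matrix[i, j] - means[i]) > w_n * stds[i]:
                p1.add(i)
                break
    base = m // group_count
    p2 = set()
    for g in range(group_count):
        lo = g * base
        hi = (g + 1) * base if g < group_count - 1 else m
        member = stds[lo:hi]
        mg = len(member)
        mean_std = member.mean()
        std_std = (sum((s - mean_std) ** 2 for s in member) / (mg - 1)) ** 0.5
        t_pc = (1 + 0.4 * np.log(mg)) * std_std
        for i in range(lo, hi):
            if abs(stds[i] - mean_std) > t_pc:
                p2.add(i)
    return p1, p2


class TestSegmentation:
    def test_reference_corpus_arithmetic(self):
        m, n = segmentation_shape(81 * 3600 * 250, 250.0, 30.0)
        assert (m, n) == (9720, 7500)

    def test_partial_trailing_window_discarded(self):
        seg = segment_record(np.arange(65.0), sampling_rate=1.0, segment_seconds=30.0)
        assert seg.values.shape == (2, 30)
        assert seg.values[1, -1] == 59.0  # samples 60..64 dropped

    def test_record_shorter_than_one_segment_errors(self):
        with pytest.raises(ValueError, match="shorter than one full segment"):
            segment_record(np.arange(10.0), 1.0, 30.0)


class TestCharacteristicSamples:
    def test_closed_form_means_and_stds(self):
        seg = segment_record([5, 5, 5, 1, 2, 3], 1.0, 3.0)
        stats = compute_segment_stats(seg)
        assert stats.means == pytest.approx([5.0, 2.0])
        assert stats.stds == pytest.approx([0.0, 1.0])

    def test_single_sample_segments_rejected(self):
        seg = segment_record([1.0, 2.0], 1.0, 1.0)
        with pytest.raises(ValueError):
            compute_segment_stats(seg)

    def test_group_stats_closed_form(self):
        seg = segment_record(
            np.repeat([0, 0, 0, 3], 3) + np.tile([-1.0, 0.0, 1.0], 4), 1.0, 3.0
        )
        stats = compute_segment_stats(seg)  # stds all 1.0
        groups = compute_group_stats(stats, 1)
        assert groups.mean_of_stds[0] == pytest.approx(1.0)
        assert groups.std_of_stds[0] == pytest.approx(0.0)

    def test_group_stats_mixed_values(self):
        # stds [1,1,1,3] in one group -> mean 1.5, std 1.0
        rows = np.array(
            [[-1, 0, 1], [-1, 0, 1], [-1, 0, 1], [-3, 0, 3]], dtype=float
        )
        seg = segment_record(rows.ravel(), 1.0, 3.0)
        stats = compute_segment_stats(seg)
        groups = compute_group_stats(stats, 1)
        assert stats.stds == pytest.approx([1, 1, 1, 3])
        assert groups.mean_of_stds[0] == pytest.approx(1.5)
        assert groups.std_of_stds[0] == pytest.approx(1.0)

    def test_equal_blocks_with_remainder_to_last(self):
        seg = segment_record(np.arange(22.0), 1.0, 2.0)  # 11 segments
        groups = compute_group_stats(compute_segment_stats(seg), 3)
        assert groups.member_counts.tolist() == [3, 3, 5]
        assert groups.group_of_segment.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2, 2, 2]

    def test_undersized_groups_rejected(self):
        seg = segment_record(np.arange(6.0), 1.0, 2.0)  # 3 segments
        with pytest.raises(ValueError, match="groups"):
            compute_group_stats(compute_segment_stats(seg), 2)


class TestThresholds:
    def test_coefficients_at_reference_sizes(self):
        assert chauvenet_coefficient_empirical(7500) == pytest.approx(4.569, abs=5e-4)
        assert chauvenet_coefficient_empirical(972) == pytest.approx(3.752, abs=5e-4)

    def test_thresholds_scale_with_std(self, rng):
        seg = segment_record(rng.normal(0, 1, 200), 1.0, 20.0)
        stats = compute_segment_stats(seg)
        groups = compute_group_stats(stats, 2)
        th = build_thresholds(stats, groups)
        np.testing.assert_allclose(
            th.spike_thresholds, th.spike_coefficient * stats.stds
        )
        np.testing.assert_allclose(
            th.poor_contact_thresholds,
            th.poor_contact_coefficients * groups.std_of_stds,
        )

    def test_zero_std_gives_zero_threshold(self):
        seg = segment_record([2.0] * 10, 1.0, 5.0)
        stats = compute_segment_stats(seg)
        th = build_thresholds(stats, None)
        assert th.spike_thresholds.tolist() == [0.0, 0.0]


class TestDetectors:
    def test_pure_sinusoid_never_flagged_as_spike(self):
        t = np.arange(7500) / 250.0
        rows = np.stack([np.sin(2 * np.pi * f * t) * a for f, a in [(1.2, 1), (0.7, 50)]])
        seg = segment_record(rows.ravel(), 250.0, 30.0)
        stats = compute_segment_stats(seg)
        th = build_thresholds(stats, None)
        assert detect_spike_segments(seg, stats, th) == frozenset()

    def test_single_gross_sample_flags_segment(self, rng):
        base = rng.normal(0, 1, 7500 * 3)
        base[7500 + 10] = 1000.0
        seg = segment_record(base, 250.0, 30.0)
        stats = compute_segment_stats(seg)
        th = build_thresholds(stats, None)
        assert detect_spike_segments(seg, stats, th) == frozenset({1})

    def test_constant_segment_not_flagged(self):
        seg = segment_record([3.0] * 20, 1.0, 10.0)
        stats = compute_segment_stats(seg)
        th = build_thresholds(stats, None)
        assert detect_spike_segments(seg, stats, th) == frozenset()

    def test_zero_std_segment_flagged_as_poor_contact(self, rng):
        # 972 segments of matched dispersion, one flat (std 0): the flat one
        # deviates ~0.999 from the group mean against a ~0.12 threshold
        rows = np.tile([-1.0, 0.0, 1.0], (972, 1))
        rows[400] = 0.0
        seg = segment_record(rows.ravel(), 1.0, 3.0)
        stats = compute_segment_stats(seg)
        groups = compute_group_stats(stats, 1)
        assert groups.mean_of_stds[0] == pytest.approx(971 / 972, abs=1e-6)
        assert groups.std_of_stds[0] == pytest.approx(0.032066, abs=1e-5)
        th = build_thresholds(stats, groups)
        assert detect_poor_contact_segments(stats, groups, th) == frozenset({400})

    def test_equal_stds_give_empty_p2(self):
        rows = np.tile([-1.0, 0.0, 1.0], (6, 1))
        seg = segment_record(rows.ravel(), 1.0, 3.0)
        stats = compute_segment_stats(seg)
        groups = compute_group_stats(stats, 2)
        th = build_thresholds(stats, groups)
        assert detect_poor_contact_segments(stats, groups, th) == frozenset()


class TestRemoval:
    def test_identity_on_empty_call_set(self, rng):
        seg = segment_record(rng.normal(0, 1, 60), 1.0, 10.0)
        calls = NoiseCallSet(frozenset(), frozenset(), seg.m)
        clean, _ = remove_noise(seg, calls)
        np.testing.assert_array_equal(clean.values, seg.values)

    def test_union_removed_order_preserved(self, rng):
        seg = segment_record(rng.normal(0, 1, 60), 1.0, 10.0)  # 6 segments
        calls = NoiseCallSet(frozenset({1}), frozenset({1, 4}), 6)
        clean, _ = remove_noise(seg, calls)
        assert clean.m == 4
        np.testing.assert_array_equal(clean.values, seg.values[[0, 2, 3, 5]])

    def test_conservation_property(self, small_labeled_dataset):
        ds = small_labeled_dataset
        result = screen(ds.samples, ds.params.sampling_rate, ds.segment_seconds)
        assert result.clean.m + len(result.calls.removed) == result.segments.m


class TestPipelineComposition:
    def test_clean_synthetic_record_is_all_clean(self, small_clean_params):
        from pulsescreen.synthesis import generate_pulse_record

        samples = generate_pulse_record(small_clean_params)
        result = screen(samples, 250.0, 30.0, group_count=10)
        assert result.calls.spike_segments == frozenset()
        assert result.calls.poor_contact_segments == frozenset()

    def test_injected_noise_recovered(self, small_labeled_dataset):
        ds = small_labeled_dataset
        result = screen(ds.samples, ds.params.sampling_rate, ds.segment_seconds)
        assert result.calls.removed == ds.noisy_segments
        assert result.clean.m == ds.m - len(ds.noisy_segments)

    def test_single_segment_skips_poor_contact_stage(self, rng):
        samples = rng.normal(0, 1, 30)
        with pytest.warns(UserWarning, match="skipped"):
            result = screen(samples, 1.0, 30.0)
        assert result.groups is None
        assert result.calls.poor_contact_segments == frozenset()

    def test_group_count_reduced_with_warning(self, rng):
        samples = rng.normal(0, 1, 80)  # 8 segments, 10 groups requested
        with pytest.warns(UserWarning, match="reduced"):
            result = screen(samples, 1.0, 10.0, group_count=10)
        assert result.groups.group_count == 4

    def test_matches_naive_transcription_oracle(self, rng):
        for _ in range(100):
            matrix = rng.normal(0, 1, (5, 20))
            if rng.random() < 0.3:  # occasionally plant an outlier
                matrix[rng.integers(5), rng.integers(20)] = rng.normal(0, 50)
            seg = segment_record(matrix.ravel(), 1.0, 20.0)
            stats = compute_segment_stats(seg)
            groups = compute_group_stats(stats, 2)
            th = build_thresholds(stats, groups)
            p1 = detect_spike_segments(seg, stats, th)
            p2 = detect_poor_contact_segments(stats, groups, th)
            exp1, exp2 = naive_calls(matrix, 2)
            assert set(p1) == exp1
            assert set(p2) == exp2

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        offset=st.floats(min_value=-1e4, max_value=1e4),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_calls_invariant_under_affine_rescaling(self, scale, offset, seed):
        g = np.random.default_rng(seed)
        samples = g.normal(0, 1, 200)
        samples[g.integers(200)] = g.normal(0, 40)
        a = screen(samples, 1.0, 20.0, group_count=2)
        b = screen(scale * samples + offset, 1.0, 20.0, group_count=2)
        assert a.calls.spike_segments == b.calls.spike_segments
        assert a.calls.poor_contact_segments == b.calls.poor_contact_segments

    def test_labels_consistent_with_membership(self):
        calls = NoiseCallSet(frozenset({0, 2}), frozenset({2, 3}), 5)
        assert calls.labels() == ["spike", "clean", "both", "poor_contact", "clean"]
        assert calls.removed == frozenset({0, 2, 3})
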