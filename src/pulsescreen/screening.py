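"""Adaptive-threshold screening of segmented pulse recordings.

A single-channel pulse (PPG) record is cut into fixed-length segments
(30 s at 250 Hz by default, so 7,500 samples per segment).  Two artifact
classes are discriminated, each with a Chauvenet-criterion threshold that
adapts to the data's own dispersion:

Spike noise
    Transient samples of near-full-scale amplitude.  Within segment ``i``
    with mean ``mean_i`` and standard deviation ``std_i``, the segment is
    flagged when any sample deviates from the segment mean by more than
    ``T_pn,i = W_n * std_i``, where ``W_n`` is the Chauvenet coefficient for
    the per-segment sample count ``n``.

Poor-sensor-contact noise
    Dropout / abrupt amplitude change, visible as an abnormal per-segment
    standard deviation.  Segments are partitioned into contiguous groups
    (10 by default); within a group with mean-of-stds ``mean_std`` and
    std-of-stds ``std_std``, segment ``i`` is flagged when
    ``|std_i - mean_std| > T_pc = W_m * std_std``, with ``W_m`` the
    Chauvenet coefficient for the group's member count.

Both detectors are single-pass: statistics are never re-estimated after an
exclusion.  Flagged index sets P1 (spike) and P2 (poor contact) are unioned
and the corresponding segments removed; the retained segments keep their
original order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .criteria import chauvenet_coefficient

__all__ = [
    "SegmentMatrix",
    "SegmentStatistics",
    "GroupStatistics",
    "ThresholdSet",
    "NoiseCallSet",
    "ScreenResult",
    "segmentation_shape",
    "segment_record",
    "compute_segment_stats",
    "compute_group_stats",
    "build_thresholds",
    "detect_spike_segments",
    "detect_poor_contact_segments",
    "remove_noise",
    "screen",
]


@dataclass(frozen=True)
class SegmentMatrix:
    """An ``m x n`` matrix of segmented samples: row ``i`` is segment ``i``."""

    values: np.ndarray
    sampling_rate: float
    segment_seconds: float

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-d (segments x samples) array")
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SegmentStatistics:
    """Per-segment mean and standard deviation (``n-1`` denominator)."""

    means: np.ndarray
    stds: np.ndarray
    segment_length: int  # samples per segment, n

    @property
    def m(self) -> int:
        return self.means.shape[0]


@dataclass(frozen=True)
class GroupStatistics:
    """Contiguous grouping of segments with per-group stats over ``std_i``.

    ``group_of_segment[i]`` is the 0-based group id of segment ``i``; per
    group the mean and standard deviation (``m_g - 1`` denominator) of the
    member segments' standard deviations are stored.
    """

    group_of_segment: np.ndarray
    member_counts: np.ndarray
    mean_of_stds: np.ndarray
    std_of_stds: np.ndarray

    @property
    def group_count(self) -> int:
        return self.member_counts.shape[0]


@dataclass(frozen=True)
class ThresholdSet:
    """Adaptive thresholds: per-segment spike, per-group poor-contact."""

    method: str
    spike_coefficient: float                  # W_n, from samples-per-segment
    spike_thresholds: np.ndarray              # T_pn,i = W_n * std_i
    poor_contact_coefficients: np.ndarray     # W_m per group, from member count
    poor_contact_thresholds: np.ndarray       # T_pc per group = W_m * std_of_stds


@dataclass(frozen=True)
class NoiseCallSet:
    """Discrimination calls: P1 (spike), P2 (poor contact), and their union."""

    spike_segments: frozenset
    poor_contact_segments: frozenset
    n_segments: int

    @property
    def removed(self) -> frozenset:
        return self.spike_segments | self.poor_contact_segments

    def label(self, segment: int) -> str:
        spike = segment in self.spike_segments
        poor = segment in self.poor_contact_segments
        if spike and poor:
            return "both"
        if spike:
            return "spike"
        if poor:
            return "poor_contact"
        return "clean"

    def labels(self) -> list:
        return [self.label(i) for i in range(self.n_segments)]


@dataclass(frozen=True)
class ScreenResult:
    """Everything the full screen produced, for reporting and auditing."""

    segments: SegmentMatrix
    stats: SegmentStatistics
    groups: Optional[GroupStatistics]
    thresholds: ThresholdSet
    calls: NoiseCallSet
    clean: SegmentMatrix


def segmentation_shape(n_samples: int, sampling_rate: float, segment_seconds: float):
    """Return ``(m, n)``: full segments obtainable and samples per segment.

    ``n = round(segment_seconds * sampling_rate)``; a trailing partial
    segment is discarded, so ``m = n_samples // n``.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if segment_seconds <= 0:
        raise ValueError("segment_seconds must be positive")
    n = int(round(segment_seconds * sampling_rate))
    if n < 1:
        raise ValueError("segment shorter than one sample")
    return int(n_samples) // n, n


def segment_record(samples, sampling_rate: float, segment_seconds: float) -> SegmentMatrix:
    """Cut a sample stream into consecutive, non-overlapping segments.

    A trailing partial segment is discarded.  Raises ``ValueError`` when the
    record is shorter than one full segment.
    """
    x = np.asarray(samples, dtype=float).ravel()
    m, n = segmentation_shape(x.size, sampling_rate, segment_seconds)
    if m < 1:
        raise ValueError(
            f"record of {x.size} samples is shorter than one full segment ({n} samples)"
        )
    return SegmentMatrix(
        values=x[: m * n].reshape(m, n),
        sampling_rate=float(sampling_rate),
        segment_seconds=float(segment_seconds),
    )


def compute_segment_stats(segments: SegmentMatrix) -> SegmentStatistics:
    """Per-segment mean and sample standard deviation (``n-1`` denominator)."""
    if segments.n < 2:
        raise ValueError("segments need at least 2 samples for a standard deviation")
    return SegmentStatistics(
        means=segments.values.mean(axis=1),
        stds=segments.values.std(axis=1, ddof=1),
        segment_length=segments.n,
    )


def compute_group_stats(stats: SegmentStatistics, group_count: int) -> GroupStatistics:
    """Partition segments into contiguous groups and summarise their stds.

    Groups are equal-size blocks in segment order; any remainder is merged
    into the last group.  Every group must receive at least 2 segments.
    """
    if group_count < 1:
        raise ValueError("group_count must be >= 1")
    m = stats.m
    base = m // group_count
    if base < 2:
        raise ValueError(
            f"cannot form {group_count} groups of >= 2 segments from {m} segments"
        )
    group_of_segment = np.minimum(np.arange(m) // base, group_count - 1)
    counts = np.bincount(group_of_segment, minlength=group_count)
    mean_of_stds = np.empty(group_count)
    std_of_stds = np.empty(group_count)
    for g in range(group_count):
        member_stds = stats.stds[group_of_segment == g]
        mean_of_stds[g] = member_stds.mean()
        std_of_stds[g] = member_stds.std(ddof=1)
    return GroupStatistics(
        group_of_segment=group_of_segment,
        member_counts=counts,
        mean_of_stds=mean_of_stds,
        std_of_stds=std_of_stds,
    )


def build_thresholds(
    stats: SegmentStatistics,
    groups: Optional[GroupStatistics],
    method: str = "empirical",
) -> ThresholdSet:
    """Adaptive thresholds from the characteristic samples.

    Spike: ``T_pn,i = W_n * std_i`` with ``W_n`` from the per-segment sample
    count.  Poor contact: per group, ``T_pc = W_m * std_of_stds`` with
    ``W_m`` from that group's member count.  When ``groups`` is ``None`` the
    poor-contact arrays are empty.
    """
    w_n = chauvenet_coefficient(stats.segment_length, method)
    spike_thresholds = w_n * stats.stds
    if groups is None:
        w_m = np.empty(0)
        poor_thresholds = np.empty(0)
    else:
        w_m = np.array(
            [chauvenet_coefficient(int(c), method) for c in groups.member_counts]
        )
        poor_thresholds = w_m * groups.std_of_stds
    return ThresholdSet(
        method=method,
        spike_coefficient=w_n,
        spike_thresholds=spike_thresholds,
        poor_contact_coefficients=w_m,
        poor_contact_thresholds=poor_thresholds,
    )


def detect_spike_segments(
    segments: SegmentMatrix, stats: SegmentStatistics, thresholds: ThresholdSet
) -> frozenset:
    """P1: segments with any sample deviating more than ``T_pn,i`` (strict)."""
    deviations = np.abs(segments.values - stats.means[:, None]).max(axis=1)
    flagged = np.nonzero(deviations > thresholds.spike_thresholds)[0]
    return frozenset(int(i) for i in flagged)


def detect_poor_contact_segments(
    stats: SegmentStatistics, groups: GroupStatistics, thresholds: ThresholdSet
) -> frozenset:
    """P2: segments whose std deviates more than the group ``T_pc`` (strict).

    Two-sided: both abnormally high std (amplitude jumps) and abnormally low
    std (flat-line dropout) are flagged.
    """
    g = groups.group_of_segment
    deviations = np.abs(stats.stds - groups.mean_of_stds[g])
    flagged = np.nonzero(deviations > thresholds.poor_contact_thresholds[g])[0]
    return frozenset(int(i) for i in flagged)


def remove_noise(segments: SegmentMatrix, calls: NoiseCallSet):
    """Drop the segments in P1 ∪ P2, preserving the order of the rest."""
    if calls.n_segments != segments.m:
        raise ValueError("call set was derived from a different segment matrix")
    keep = [i for i in range(segments.m) if i not in calls.removed]
    clean = SegmentMatrix(
        values=segments.values[keep],
        sampling_rate=segments.sampling_rate,
        segment_seconds=segments.segment_seconds,
    )
    return clean, calls


def screen(
    samples,
    sampling_rate: float = 250.0,
    segment_seconds: float = 30.0,
    group_count: int = 10,
    method: str = "empirical",
) -> ScreenResult:
    """Run the full preprocessing pipeline on one record.

    Segmentation -> characteristic samples -> adaptive thresholds ->
    spike / poor-contact discrimination -> removal of P1 ∪ P2.  When the
    record has too few segments to form the requested groups (each needs at
    least 2 members), the group count is reduced; with fewer than 2 segments
    the poor-contact stage is skipped entirely, with a warning either way.
    """
    segments = segment_record(samples, sampling_rate, segment_seconds)
    stats = compute_segment_stats(segments)

    effective_groups = min(group_count, segments.m // 2)
    if effective_groups < 1:
        warnings.warn(
            "too few segments for poor-contact screening; stage skipped",
            stacklevel=2,
        )
        groups = None
    else:
        if effective_groups < group_count:
            warnings.warn(
                f"group_count reduced from {group_count} to {effective_groups} "
                f"so every group has at least 2 segments",
                stacklevel=2,
            )
        groups = compute_group_stats(stats, effective_groups)

    thresholds = build_thresholds(stats, groups, method)
    p1 = detect_spike_segments(segments, stats, thresholds)
    p2 = (
        detect_poor_contact_segments(stats, groups, thresholds)
        if groups is not None
        else frozenset()
    )
    calls = NoiseCallSet(
        spike_segments=p1, poor_contact_segments=p2, n_segments=segments.m
    )
    clean, _ = remove_noise(segments, calls)
    return ScreenResult(
        segments=segments,
        stats=stats,
        groups=groups,
        thresholds=thresholds,
        calls=calls,
        clean=clean,
    )
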