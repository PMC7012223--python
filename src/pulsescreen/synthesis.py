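"""Seeded synthetic pulse records with labeled artifact injection.

The generator emulates the statistical structure the screen relies on rather
than detailed cardiovascular physiology: a quasi-periodic pulse wave (each
beat the sum of a systolic and a dicrotic Gaussian bump, with mild
beat-to-beat period jitter), slow sinusoidal baseline wander, and additive
measurement noise, mapped into ADC counts so that the clean waveform sits in
the middle of a 12-bit converter's range.

Two artifact injectors reproduce the phenomenology the screen targets:

* spike noise — a few isolated samples driven near the converter's full
  scale (default 0.98 of ``adc_max``);
* poor sensor contact — from a start fraction (default 0.5, i.e. the second
  half of the segment) onward the signal drops out, leaving only near-zero
  residual noise.

``build_labeled_dataset`` assembles a whole record with noisy segments
placed uniformly at random without overlap; its default prevalence matches
the rates observed in the 81-hour polysomnographic corpus the method was
developed on: 25 minutes of spike noise and 35 minutes of poor-contact
noise per 81 hours, scaled to the requested duration.  All randomness flows
through one ``numpy`` Generator seeded explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np

from .screening import segmentation_shape

__all__ = [
    "PulseModelParams",
    "SpikeNoiseParams",
    "PoorContactParams",
    "PlanEntry",
    "NoiseInjectionPlan",
    "LabeledDataset",
    "PAPER_SPIKE_MINUTES_PER_81H",
    "PAPER_POOR_CONTACT_MINUTES_PER_81H",
    "generate_pulse_record",
    "inject_spike_noise",
    "inject_poor_contact",
    "build_labeled_dataset",
]

# artifact prevalence of the 81 h reference corpus, used as default rates
PAPER_SPIKE_MINUTES_PER_81H = 25.0
PAPER_POOR_CONTACT_MINUTES_PER_81H = 35.0


@dataclass(frozen=True)
class PulseModelParams:
    """Parameters of the clean pulse-wave model.

    Amplitudes of the beat components are relative to ``adc_scale``; widths
    and centers are fractions of the beat period.  ``adc_offset`` and
    ``adc_scale`` map the dimensionless waveform into converter counts;
    wander amplitude and measurement-noise sd are in counts.
    """

    sampling_rate: float = 250.0
    duration: float = 300.0           # seconds
    heart_rate: float = 70.0          # beats per minute
    rr_jitter: float = 0.03           # sd of relative beat-period jitter
    systolic_amplitude: float = 1.0
    systolic_width: float = 0.07
    dicrotic_amplitude: float = 0.35
    dicrotic_width: float = 0.09
    dicrotic_delay: float = 0.32      # fraction of period after systolic peak
    amplitude_mod_depth: float = 0.10
    amplitude_mod_period: float = 300.0
    baseline_wander_amplitude: float = 60.0
    baseline_wander_period: float = 15.0
    noise_sd: float = 6.0
    adc_offset: float = 1400.0
    adc_scale: float = 1100.0
    adc_max: int = 4095
    seed: int = 0

    def __post_init__(self):
        for name in ("sampling_rate", "duration", "heart_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.adc_max <= 0:
            raise ValueError("adc_max must be positive")


@dataclass(frozen=True)
class SpikeNoiseParams:
    """Isolated near-full-scale samples within one segment."""

    count: int = 2
    amplitude_fraction: float = 0.98
    width: int = 1                    # samples per spike
    adc_max: int = 4095


@dataclass(frozen=True)
class PoorContactParams:
    """Dropout to near-zero residual noise from a start fraction onward."""

    start_fraction: float = 0.5
    residual_sd: float = 4.0


@dataclass(frozen=True)
class PlanEntry:
    segment_index: int
    kind: str                         # "spike" or "poor_contact"
    params: Union[SpikeNoiseParams, PoorContactParams]


@dataclass(frozen=True)
class NoiseInjectionPlan:
    entries: Tuple[PlanEntry, ...] = field(default_factory=tuple)

    def segments_of_kind(self, kind: str) -> frozenset:
        return frozenset(e.segment_index for e in self.entries if e.kind == kind)


@dataclass(frozen=True)
class LabeledDataset:
    """A generated record plus its segment-level ground truth."""

    samples: np.ndarray
    labels: Tuple[str, ...]           # per segment: clean / spike / poor_contact
    plan: NoiseInjectionPlan
    params: PulseModelParams
    segment_seconds: float

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> int:
        return segmentation_shape(
            self.samples.size, self.params.sampling_rate, self.segment_seconds
        )[1]

    @property
    def noisy_segments(self) -> frozenset:
        return frozenset(i for i, lab in enumerate(self.labels) if lab != "clean")


def generate_pulse_record(
    params: PulseModelParams, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Deterministically generate one clean pulse record in ADC counts.

    Raises ``ValueError`` if the assembled waveform would clip against 0 or
    ``adc_max`` (the clean signal must stay strictly inside the converter's
    range; artifacts are injected separately).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n_samples = int(round(params.duration * fs))
    t = np.arange(n_samples) / fs
    period = 60.0 / params.heart_rate

    n_beats = int(np.ceil(params.duration / period)) + 2
    jitter = rng.normal(0.0, params.rr_jitter, n_beats)
    periods = period * np.clip(1.0 + jitter, 0.5, 1.5)
    centers = 0.5 * period + np.concatenate(([0.0], np.cumsum(periods[:-1])))

    pulse = np.zeros(n_samples)
    sig_sys = params.systolic_width * period
    sig_dic = params.dicrotic_width * period
    idx = np.searchsorted(centers, t)
    for off in (-1, 0, 1):
        k = idx + off
        valid = (k >= 0) & (k < n_beats)
        dt = t[valid] - centers[k[valid]]
        pulse[valid] += params.systolic_amplitude * np.exp(-0.5 * (dt / sig_sys) ** 2)
        dt2 = dt - params.dicrotic_delay * period
        pulse[valid] += params.dicrotic_amplitude * np.exp(-0.5 * (dt2 / sig_dic) ** 2)

    # slow bounded amplitude modulation (vasomotor / respiratory envelope):
    # keeps segment-to-segment std variation short-tailed, as in real PPG
    envelope = 1.0 + params.amplitude_mod_depth * np.sin(
        2.0 * np.pi * t / params.amplitude_mod_period + rng.uniform(0, 2 * np.pi)
    )
    wander = params.baseline_wander_amplitude * np.sin(
        2.0 * np.pi * t / params.baseline_wander_period + rng.uniform(0, 2 * np.pi)
    )
    noise = rng.normal(0.0, params.noise_sd, n_samples)
    samples = params.adc_offset + params.adc_scale * envelope * pulse + wander + noise

    if samples.min() <= 0.0 or samples.max() >= params.adc_max:
        raise ValueError(
            "clean waveform clips against the ADC range; adjust offset/scale"
        )
    return samples


def _segment_bounds(samples: np.ndarray, segment_index: int, segment_length: int):
    m = samples.size // segment_length
    if not 0 <= segment_index < m:
        raise ValueError(
            f"segment_index {segment_index} out of range for {m} segments"
        )
    start = segment_index * segment_length
    return start, start + segment_length


def inject_spike_noise(
    samples: np.ndarray,
    segment_index: int,
    segment_length: int,
    params: SpikeNoiseParams = SpikeNoiseParams(),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Return a copy with near-full-scale spikes in the target segment.

    ``params.count`` spikes of ``params.width`` samples are placed at
    positions drawn without replacement; every sample outside the targeted
    positions is untouched.  ``count = 0`` returns an identical copy.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if params.count < 0 or params.width < 1:
        raise ValueError("spike count must be >= 0 and width >= 1")
    out = np.array(samples, dtype=float, copy=True)
    start, stop = _segment_bounds(out, segment_index, segment_length)
    if params.count == 0:
        return out
    n_starts = segment_length - params.width + 1
    positions = rng.choice(n_starts, size=min(params.count, n_starts), replace=False)
    level = params.amplitude_fraction * params.adc_max
    for p in positions:
        out[start + p : start + p + params.width] = level
    return out


def inject_poor_contact(
    samples: np.ndarray,
    segment_index: int,
    segment_length: int,
    params: PoorContactParams = PoorContactParams(),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Return a copy with signal dropout in the target segment.

    From ``start_fraction`` of the segment onward, samples are replaced by
    near-zero residual noise (truncated at 0, the converter's floor); a
    residual sd of 0 produces an exactly constant tail.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not 0.0 <= params.start_fraction < 1.0:
        raise ValueError("start_fraction must be in [0, 1)")
    if params.residual_sd < 0:
        raise ValueError("residual_sd must be >= 0")
    out = np.array(samples, dtype=float, copy=True)
    start, stop = _segment_bounds(out, segment_index, segment_length)
    drop_from = start + int(params.start_fraction * segment_length)
    size = stop - drop_from
    if params.residual_sd > 0:
        residual = np.clip(rng.normal(0.0, params.residual_sd, size), 0.0, None)
    else:
        residual = np.zeros(size)
    out[drop_from:stop] = residual
    return out


def build_labeled_dataset(
    params: PulseModelParams = PulseModelParams(),
    spike_minutes: Optional[float] = None,
    poor_contact_minutes: Optional[float] = None,
    segment_seconds: float = 30.0,
    seed: int = 0,
) -> LabeledDataset:
    """Generate a record and contaminate it according to a random plan.

    ``spike_minutes`` / ``poor_contact_minutes`` give the total duration of
    each artifact class; each contaminated 30-s segment accounts for half a
    minute.  When omitted, the reference corpus rates (25 and 35 minutes per
    81 hours) are scaled to the record's duration.  Noisy segment positions
    are drawn uniformly without overlap; each spike segment receives 1-3
    single-sample spikes.
    """
    rng = np.random.default_rng(seed)
    m, n = segmentation_shape(
        int(round(params.duration * params.sampling_rate)),
        params.sampling_rate,
        segment_seconds,
    )
    if m < 1:
        raise ValueError("duration shorter than one segment")

    hours = params.duration / 3600.0
    if spike_minutes is None:
        spike_minutes = PAPER_SPIKE_MINUTES_PER_81H * hours / 81.0
    if poor_contact_minutes is None:
        poor_contact_minutes = PAPER_POOR_CONTACT_MINUTES_PER_81H * hours / 81.0
    n_spike = int(round(spike_minutes * 60.0 / segment_seconds))
    n_poor = int(round(poor_contact_minutes * 60.0 / segment_seconds))
    if n_spike + n_poor > m:
        raise ValueError(
            f"requested {n_spike + n_poor} noisy segments but record has only {m}"
        )

    samples = generate_pulse_record(params, rng)
    order = rng.permutation(m)
    spike_idx = sorted(int(i) for i in order[:n_spike])
    poor_idx = sorted(int(i) for i in order[n_spike : n_spike + n_poor])

    entries = []
    for i in spike_idx:
        sp = SpikeNoiseParams(count=int(rng.integers(1, 4)), adc_max=params.adc_max)
        samples = inject_spike_noise(samples, i, n, sp, rng)
        entries.append(PlanEntry(segment_index=i, kind="spike", params=sp))
    for i in poor_idx:
        pc = PoorContactParams()
        samples = inject_poor_contact(samples, i, n, pc, rng)
        entries.append(PlanEntry(segment_index=i, kind="poor_contact", params=pc))

    labels = ["clean"] * m
    for i in spike_idx:
        labels[i] = "spike"
    for i in poor_idx:
        labels[i] = "poor_contact"

    return LabeledDataset(
        samples=samples,
        labels=tuple(labels),
        plan=NoiseInjectionPlan(entries=tuple(entries)),
        params=replace(params, seed=seed),
        segment_seconds=segment_seconds,
    )
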