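# Methods

## The screening model

The screen treats artifact detection in segmented pulse recordings as two
gross-error problems at different scales:

1. **Within a segment** the samples of a clean quasi-periodic pulse wave
   scatter around the segment mean with a bounded deviation-to-std ratio
   (a pure sinusoid reaches √2 ≈ 1.41; the pulse waveform used here stays
   below ~3). A near-full-scale spike deviates far more, so the Chauvenet
   rule applied to the raw samples with the per-segment threshold
   `T_pn,i = W_n · std_i` separates the two cleanly: at n = 7,500 samples
   per segment, `W_n = 1 + 0.4 ln 7500 = 4.569`.
2. **Across segments** the per-segment standard deviation `std_i` of clean
   signal varies slowly and boundedly, while both dropout (flat-line, very
   low std when the whole segment is flat; very high std when the segment
   mixes signal and dropout at ADC-floor level) and abrupt contact changes
   displace `std_i` far from its neighbours. The Chauvenet rule applied to
   the `std_i` of a contiguous group, with `T_pc = W_m · std_std`, flags
   those segments two-sidedly.

Key assumptions, made explicit:

* Clean per-segment sample deviations and per-group std deviations are
  short-tailed relative to the Chauvenet multiplier. For exactly normal
  data the criterion by construction tolerates about half a flagged value
  per group (`1/(2t)` tail mass), i.e. a baseline false-positive rate of
  roughly `1/(2 m_g)` per segment; the method's headroom on real pulse data
  comes from the *bounded* (sub-Gaussian-tailed) variation of clean signal.
* Statistics are estimated once, with the contaminated values left in
  (single pass, no re-estimation). Contamination must therefore be sparse
  enough per group not to mask itself: a dropout segment's std is ~3× a
  clean segment's, so with group sizes ≥ ~50 a handful of contaminated
  members still stand out; with very small groups (≲10) two simultaneous
  outliers can mask each other. This motivates the default grouping below.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `sampling_rate` | 250 Hz | rate of the reference polysomnographic corpus |
| `segment_seconds` | 30 s | annotation granularity of that corpus; n = 7,500 |
| `group_count` | 10 | contiguous equal blocks (remainder to the last); per-group `W_m` uses the group's actual member count |
| `method` | `empirical` | `1 + 0.4 ln t`; `exact_tail` gives the normal quantile at `1 − 1/(4t)` |
| Romanovsky `significance` | 0.01 | two-sided Student-t quantile, leave-one-out df; baseline of convenience, only its N×M cost structure is meaningful |

Inequalities are strict, as in the defining rules; a group whose stds are
all equal gives `std_std = 0`, threshold 0, and (strictly) nothing flagged.
Records too short for the requested grouping reduce the group count so that
every group keeps ≥ 2 members, or skip the poor-contact stage entirely
below 2 segments (warning in both cases). Trailing partial segments are
discarded. All comparisons are in double precision; both call sets are
affine-equivariant (every threshold and deviation scales with the data), a
property the test suite checks.

## The synthetic generator

`pulsescreen.synthesis` emulates the statistical structure the screen
relies on, not cardiovascular physiology:

* each beat is a systolic plus a dicrotic Gaussian bump, with 3%
  beat-period jitter (quasi-periodicity);
* a slow bounded amplitude modulation (default 10% depth, 5-min period)
  models vasomotor/respiratory envelope variation. This matters: it makes
  the clean per-segment std distribution short-tailed, which is the regime
  the adaptive threshold exploits on real recordings. Without it the clean
  stds are essentially Gaussian and the criterion's built-in `1/(2m_g)`
  false-flag rate applies;
* sinusoidal baseline wander (60 counts, 15 s) and white measurement noise
  (6 counts);
* mapping into the middle of a 12-bit ADC range (`adc_max = 4095`,
  offset 1400, scale 1100); generation fails loudly if the clean wave would
  clip.

Artifacts: spike segments receive 1–3 isolated samples at 0.98·`adc_max`;
poor-contact segments drop to near-zero residual noise (sd 4 counts,
truncated at the converter floor) from half the segment onward. Default
prevalence scales the reference corpus rates — 25 min spike and 35 min
poor-contact per 81 h, i.e. ~0.6% and ~0.9% of segments. One explicitly
seeded `numpy` Generator drives record synthesis, artifact placement
(uniform, non-overlapping) and injection, so datasets are bit-reproducible.

What passing on this generator does **not** show: robustness to motion
artifact classes other than these two, to baseline/power-line/EMG noise, to
arrhythmic or highly non-stationary rhythms, or to dropout at a non-zero
resting level. Segments are removed, never repaired.

## Evaluation choices

* `Accuracy_D` is a plain segment-level confusion accuracy, reported to two
  decimals; a segment is predicted noisy iff it is in `P1 ∪ P2` (a segment
  flagged by both detectors is counted once, its label recorded as
  `both`).
* The Jaccard similarity between real-valued signals uses the fuzzy-set
  form `Σ min / Σ max` on min-max-normalized inputs (convention: 1 when the
  union sum is 0). After removal the processed record is shorter than the
  reference, so the before/after comparison restricts both signals to the
  retained segments and re-normalizes over the samples actually compared;
  the before/after *direction*, not any particular value, is the meaningful
  quantity.

## Problem sizes used in the checks

The seeded benchmark runs 10 seeds of 500 segments each (15,000 s at
250 Hz, default prevalence: 4 spike + 3 dropout segments per run), chosen
as the smallest scale at which group sizes (50) are safely in the
no-masking regime while keeping the whole suite quick; measured accuracy is
100.00% on each seed. The transcription-equivalence check uses 1,000 random
5×20 matrices against a loop-and-index oracle. Coefficient checks compare
the exact-tail form against bisection on a numerically integrated normal
density to 1e−6 over sample sizes up to 1e5.

## Known limitations

* The poor-contact stage inherits the single-pass criterion's masking
  behaviour in tiny groups (see assumptions); choose `group_count` so that
  groups have ≳ 50 members.
* The Romanovsky baseline's flag set depends on an arbitrary significance
  choice; only its computation count is comparable across implementations.
* WFDB input is a thin optional reader; channel selection and physical
  units are taken from the record header as-is.
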