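"""Chauvenet coefficients for the reference screening configuration.

The adaptive thresholds scale a standard deviation by the Chauvenet
coefficient W_t, a function of the sample size t alone.  At the reference
configuration (30-s segments at 250 Hz, 10 groups of 972 segments) the two
sizes that matter are t = 7,500 (samples per segment, spike threshold) and
t = 972 (segments per group, poor-contact threshold).
"""

from pulsescreen import (
    chauvenet_coefficient_empirical,
    chauvenet_coefficient_exact,
    confidence_probability,
)

for t in (7500, 972):
    w_emp = chauvenet_coefficient_empirical(t)
    w_exact = chauvenet_coefficient_exact(t)
    p = confidence_probability(t)
    print(
        f"t={t:5d}  W_empirical={w_emp:.3f}  W_exact_tail={w_exact:.3f}  "
        f"confidence={p:.6f}"
    )

# W_empirical is the multiplier actually used by the screen: a sample (or a
# segment std) is abnormal when it deviates from its mean by more than
# W * std.  The confidence column is the central probability mass the
# criterion retains, 1 - 1/(2t).
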