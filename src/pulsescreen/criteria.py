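"""Gross-error discrimination coefficients.

The Chauvenet criterion is a single-pass rule for flagging gross errors in a
sample of ``t`` measurements assumed to be normally distributed around their
mean: a value is abnormal when its absolute deviation from the sample mean
exceeds ``W_t`` times the sample standard deviation.  The coefficient ``W_t``
depends only on the sample size.  It retains a central confidence probability
of ``1 - 1/(2t)``, i.e. it tolerates at most half an expected outlier per
sample; the mass left in each tail is ``1/(4t)``.

Two forms of the coefficient are provided:

``empirical``
    The classical approximation ``W_t = 1 + 0.4 ln(t)``, the default used by
    the screening pipeline.
``exact_tail``
    The standard-normal quantile at cumulative probability ``1 - 1/(4t)``,
    i.e. the z-score whose upper-tail mass is ``1/(4t)``.

A Romanovsky-style iterative screen is included purely as a computational
baseline: it re-estimates the mean and standard deviation once per candidate
value (leave-one-out) and applies a Student-t threshold, so screening a
record of ``M`` samples costs ``M`` mean/std computations against the single
computation the Chauvenet screen needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "COEFFICIENT_METHODS",
    "chauvenet_coefficient",
    "chauvenet_coefficient_empirical",
    "chauvenet_coefficient_exact",
    "chauvenet_screen",
    "confidence_probability",
    "romanovsky_screen",
    "ScreenOutcome",
]

COEFFICIENT_METHODS = ("empirical", "exact_tail")


def _validate_sample_size(sample_size: int) -> int:
    if isinstance(sample_size, bool) or not isinstance(sample_size, (int, np.integer)):
        raise ValueError(f"sample_size must be an integer, got {sample_size!r}")
    if sample_size < 1:
        raise ValueError(f"sample_size must be >= 1, got {sample_size}")
    return int(sample_size)


def chauvenet_coefficient_empirical(sample_size: int) -> float:
    """Empirical Chauvenet coefficient ``1 + 0.4 ln(t)``.

    Parameters
    ----------
    sample_size : int
        Number of values under test, ``t >= 1``.

    Returns
    -------
    float
        The maximum allowable deviation in units of the sample standard
        deviation.  ``1.0`` for a single value, strictly increasing in ``t``.

    Examples
    --------
    >>> round(chauvenet_coefficient_empirical(7500), 3)
    4.569
    >>> round(chauvenet_coefficient_empirical(972), 3)
    3.752
    """
    t = _validate_sample_size(sample_size)
    return 1.0 + 0.4 * math.log(t)


def chauvenet_coefficient_exact(sample_size: int) -> float:
    """Exact-tail Chauvenet coefficient.

    The z-score whose upper-tail standard-normal probability is ``1/(4t)``,
    i.e. the quantile of the standard normal at ``1 - 1/(4t)``.  For ``t = 1``
    this is the quantile at 0.75 (~0.6745).
    """
    t = _validate_sample_size(sample_size)
    return float(stats.norm.ppf(1.0 - 1.0 / (4.0 * t)))


def chauvenet_coefficient(sample_size: int, method: str = "empirical") -> float:
    """Chauvenet coefficient by the requested method (see module docstring)."""
    if method == "empirical":
        return chauvenet_coefficient_empirical(sample_size)
    if method == "exact_tail":
        return chauvenet_coefficient_exact(sample_size)
    raise ValueError(f"method must be one of {COEFFICIENT_METHODS}, got {method!r}")


def confidence_probability(sample_size: int) -> float:
    """Central confidence probability retained by the criterion, ``1 - 1/(2t)``."""
    t = _validate_sample_size(sample_size)
    return 1.0 - 1.0 / (2.0 * t)


@dataclass(frozen=True)
class ScreenOutcome:
    """Result of screening one record for gross errors.

    Attributes
    ----------
    flagged : frozenset of int
        0-based indices of values discriminated as gross errors.
    n_stat_computations : int
        How many (mean, standard deviation) pairs were computed while
        screening the record.  One for the Chauvenet screen; one per value
        for the Romanovsky baseline.
    """

    flagged: frozenset
    n_stat_computations: int


def chauvenet_screen(values, method: str = "empirical") -> ScreenOutcome:
    """Single-pass Chauvenet screen of one record.

    Computes the record's mean and standard deviation once and flags every
    value whose absolute deviation exceeds ``W_t`` times the standard
    deviation (strict inequality).  No iteration and no sorting.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("chauvenet_screen requires a 1-d record of at least 2 values")
    w = chauvenet_coefficient(x.size, method)
    mean = x.mean()
    sd = x.std(ddof=1)
    flagged = np.nonzero(np.abs(x - mean) > w * sd)[0]
    return ScreenOutcome(flagged=frozenset(int(i) for i in flagged), n_stat_computations=1)


def romanovsky_screen(values, significance: float = 0.01) -> ScreenOutcome:
    """Leave-one-out iterative gross-error screen (comparison baseline).

    For each candidate value the mean and standard deviation of the *other*
    values are recomputed and the candidate is flagged when its absolute
    deviation from that mean exceeds the two-sided Student-t quantile (at the
    given significance, with the leave-one-out degrees of freedom) times that
    standard deviation.  Screening a record of ``M`` values therefore costs
    ``M`` mean/std computations, the cost structure that makes this family of
    criteria slow on long records.

    This is a baseline of convenience, not a reproduction of any specific
    published Romanovsky table.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("romanovsky_screen requires a 1-d record of at least 3 values")
    if not 0.0 < significance < 1.0:
        raise ValueError(f"significance must be in (0, 1), got {significance}")
    m = x.size
    # df of a std estimated from m-1 leave-one-out values
    t_crit = float(stats.t.ppf(1.0 - significance / 2.0, df=m - 2))
    flagged = []
    n_computations = 0
    for i in range(m):
        rest = np.delete(x, i)
        mean = rest.mean()
        sd = rest.std(ddof=1)
        n_computations += 1
        if abs(x[i] - mean) > t_crit * sd:
            flagged.append(i)
    return ScreenOutcome(flagged=frozenset(flagged), n_stat_computations=n_computations)
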