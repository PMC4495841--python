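"""Exact multinomial outlier probabilities, HWE carrier expectations and
covariate correlations for loss-of-activity frequencies.

The outlier question: how surprising is one small population's 0/1/2-active
carrier composition if its true carrier distribution equalled a reference
population's?  With category probabilities (p2, p1, p0) and observed counts
(k2, k1, k0), the exact multinomial point mass is

    P = n! / (k2! k1! k0!) * p2^k2 * p1^k1 * p0^k0.

A conservative tail companion sums the point masses of all outcomes at most
as probable as the observed one (exact enumeration, small n).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb, factorial, prod
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .activity import AlleleClass


@dataclass(frozen=True)
class CarrierDistribution:
    """Probabilities of carrying two, one or zero active alleles."""

    p_two: float
    p_one: float
    p_zero: float

    def __post_init__(self) -> None:
        probs = (self.p_two, self.p_one, self.p_zero)
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {sum(probs)}, not 1")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.p_two, self.p_one, self.p_zero)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    n: int
    p_value: float


def multinomial_point_probability(counts: Sequence[int],
                                  dist: Sequence[float]) -> float:
    """Exact multinomial point mass of one observed count vector."""
    counts = [int(c) for c in counts]
    probs = list(dist.as_tuple() if isinstance(dist, CarrierDistribution) else dist)
    if len(counts) != len(probs):
        raise ValueError("counts and probabilities differ in length")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    coef = factorial(n) / prod(factorial(c) for c in counts)
    mass = 1.0
    for c, p in zip(counts, probs):
        if c > 0 and p == 0.0:
            return 0.0
        mass *= p ** c
    return coef * mass


MAX_TAIL_N = 20


def multinomial_tail_probability(counts: Sequence[int],
                                 dist: Sequence[float]) -> float:
    """Probability of outcomes at most as probable as the observed one.

    Exhaustive enumeration over all count vectors with the same total;
    bounded at n = 20 to keep the outcome space small.
    """
    counts = [int(c) for c in counts]
    n = sum(counts)
    if n > MAX_TAIL_N:
        raise ValueError(f"total count {n} exceeds enumeration bound {MAX_TAIL_N}")
    k = len(counts)
    p_obs = multinomial_point_probability(counts, dist)
    total = 0.0
    for cut in combinations_with_replacement(range(n + 1), k - 1):
        vec = []
        prev = 0
        for c in cut:
            vec.append(c - prev)
            prev = c
        vec.append(n - prev)
        p = multinomial_point_probability(vec, dist)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def hwe_carrier_distribution(p_active: float) -> CarrierDistribution:
    """Hardy-Weinberg (p^2, 2pq, q^2) carrier distribution from the
    frequency of fully active alleles."""
    if not 0.0 <= p_active <= 1.0:
        raise ValueError(f"allele frequency {p_active} outside [0, 1]")
    q = 1.0 - p_active
    return CarrierDistribution(p_active ** 2, 2.0 * p_active * q, q ** 2)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(r) ** 2, len(x), float(p))


def correlate_with_covariate(metric: pd.Series, covariate: pd.Series,
                             exclude: Sequence[str] = ()) -> CorrelationResult:
    """Correlate a per-population metric with a per-population covariate,
    intersecting indices and optionally excluding populations."""
    common = metric.index.intersection(covariate.index).difference(pd.Index(exclude))
    return pearson_correlation(metric.loc[common].to_numpy(),
                               covariate.loc[common].to_numpy())


def loss_frequency_per_population(freq_pct: pd.DataFrame,
                                  classification: Mapping[str, AlleleClass],
                                  metric: str = "allele") -> pd.Series:
    """Per-population frequency of loss of activity (fraction).

    metric="allele": summed frequency of alleles not in the active set.
    metric="carrier": HWE-expected frequency of individuals with at most one
    active allele, 1 - p_active^2.
    """
    active = [a for a in freq_pct.columns
              if a in classification and classification[a].active_for_phenotype]
    p_active = freq_pct[active].sum(axis=1) / 100.0
    p_active = p_active.clip(0.0, 1.0)
    if metric == "allele":
        out = 1.0 - p_active
    elif metric == "carrier":
        out = 1.0 - p_active ** 2
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out.name = f"loss_{metric}"
    return out
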