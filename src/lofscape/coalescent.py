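"""Neutral-coalescent null sampler for frequency-spectrum statistics.

Simulates Kingman-coalescent genealogies for a sample of n chromosomes and
drops a fixed number S of mutations on the tree, each landing on a branch
with probability proportional to its length (the standard fixed-S null used
for neutrality-test p-values).  A mutation on a branch subtending k leaves
yields a segregating site with derived-allele count k, so each replicate
returns a site-count vector from which Tajima's D (or any other spectrum
statistic) can be evaluated under neutrality.
"""
from __future__ import annotations

from typing import Iterator, Optional

import numpy as np


def sample_tree(n: int, rng: np.random.Generator):
    """One Kingman genealogy: per-branch (subtree size, branch length).

    Returns (sizes, lengths) over the 2n-2 non-root branches.  Time is in
    coalescent units; only relative lengths matter for mutation placement.
    """
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    # slot arrays over active lineages; merged pairs are retired in place
    sizes = np.ones(n, dtype=np.int64)
    birth = np.zeros(n)
    out_sizes = np.empty(2 * n - 2, dtype=np.int64)
    out_lengths = np.empty(2 * n - 2)
    # pre-draw the inter-coalescence waiting times t_k ~ Exp(k(k-1)/2)
    ks = np.arange(n, 1, -1, dtype=float)
    waits = rng.exponential(2.0 / (ks * (ks - 1)))
    times = np.cumsum(waits)
    # pre-draw merge pair indices: at step with k active, pick i<j in [0,k)
    u1 = rng.integers(0, ks.astype(np.int64))
    u2 = rng.integers(0, ks.astype(np.int64) - 1)
    m = 0
    k = n
    for step in range(n - 1):
        t = times[step]
        i = u1[step]
        j = u2[step]
        if j >= i:
            j += 1
        a, b = (i, j) if i < j else (j, i)
        out_sizes[m] = sizes[a]
        out_lengths[m] = t - birth[a]
        out_sizes[m + 1] = sizes[b]
        out_lengths[m + 1] = t - birth[b]
        m += 2
        sizes[a] += sizes[b]
        birth[a] = t
        # move the last active lineage into slot b
        k -= 1
        sizes[b] = sizes[k]
        birth[b] = birth[k]
    return out_sizes[:m], out_lengths[:m]


def simulate_site_counts(n: int, s: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele counts of S mutations dropped on one neutral genealogy."""
    sizes, lengths = sample_tree(n, rng)
    p = lengths / lengths.sum()
    idx = rng.choice(len(sizes), size=s, p=p)
    return sizes[idx]


def null_site_count_samples(n: int, s: int, reps: int,
                            seed: Optional[int] = None) -> Iterator[np.ndarray]:
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        yield simulate_site_counts(n, s, rng)


def expected_total_branch_length(n: int) -> float:
    """E[total tree length] = 2 * sum_{i=1}^{n-1} 1/i (coalescent units)."""
    return 2.0 * np.sum(1.0 / np.arange(1, n))
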