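"""Haplotype-frequency estimation from unphased genotypes by EM.

The model is the classical multinomial Hardy-Weinberg likelihood over
haplotype frequencies f:

    L(f) = prod_i  sum_{(h1,h2) ~ g_i}  c * f_{h1} f_{h2}

where the sum runs over ordered-unordered haplotype pairs consistent with
individual i's genotype vector g_i (c = 2 for heterotypic pairs).  EM
iterates expected pair counts until the log-likelihood gain drops below a
tolerance; the log-likelihood is non-decreasing by construction.  Multiple
random restarts plus a repeated-seed consistency report guard against local
optima, mirroring the seed-consistency protocol used with Bayesian phasing
of the original survey (default seed list 2, 1536, 2936, 3123, 4957, 5283,
6757, 7992, 8633, 9045).

Haplotypes are represented as bitmasks over the panel's variant columns;
individuals with a missing genotype at any site are excluded from the group.
The ambiguous phase space is enumerated per individual, which bounds the
usable number of segregating sites (default cap 25).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import AnalysisConfig, GenotypePanel

MAX_SITES = 25


@dataclass
class PhasingResult:
    variant_ids: List[str]
    haplotype_freqs: Dict[int, float]          # bitmask -> frequency
    log_likelihood: float
    diplotypes: Dict[str, Tuple[int, int]]     # sample -> (hap1, hap2) bitmasks
    posteriors: Dict[str, float]
    tie_flags: Dict[str, bool]
    n_iterations: int
    converged: bool
    seed: Optional[int] = None
    excluded_samples: List[str] = field(default_factory=list)
    ll_history: List[float] = field(default_factory=list)

    def haplotype_variants(self, mask: int) -> frozenset:
        return frozenset(v for i, v in enumerate(self.variant_ids) if mask >> i & 1)

    def named_freqs(self) -> Dict[frozenset, float]:
        return {self.haplotype_variants(m): f
                for m, f in self.haplotype_freqs.items()}


def _compatible_pairs(genotype: np.ndarray) -> List[Tuple[int, int]]:
    """All unordered haplotype-pair bitmasks consistent with one genotype."""
    hom = 0
    het_sites = []
    for j, g in enumerate(genotype):
        if g == 2:
            hom |= 1 << j
        elif g == 1:
            het_sites.append(j)
    if not het_sites:
        return [(hom, hom)]
    pairs = []
    first = het_sites[0]
    # fix the first het site on haplotype 1 to halve the enumeration
    for assign in itertools.product((0, 1), repeat=len(het_sites) - 1):
        h1, h2 = hom | (1 << first), hom
        for bit, j in zip(assign, het_sites[1:]):
            if bit:
                h1 |= 1 << j
            else:
                h2 |= 1 << j
        pairs.append((h1, h2) if h1 <= h2 else (h2, h1))
    return pairs


def _prepare(panel: GenotypePanel, group: Optional[Sequence[str]] = None):
    if group is not None:
        panel = panel.subset(list(group))
    geno = panel.genotypes
    if geno.shape[1] > MAX_SITES:
        raise ValueError(
            f"{geno.shape[1]} sites exceed the enumeration bound ({MAX_SITES}); "
            "filter sites before phasing")
    keep = (geno.to_numpy() >= 0).all(axis=1)
    excluded = list(geno.index[~keep])
    geno = geno.loc[keep]
    if geno.shape[0] == 0:
        raise ValueError("no fully genotyped individuals in group")
    return panel, geno, excluded


def em_haplotype_frequencies(panel: GenotypePanel,
                             group: Optional[Sequence[str]] = None,
                             config: Optional[AnalysisConfig] = None,
                             seed: Optional[int] = None) -> PhasingResult:
    """Maximum-likelihood haplotype frequencies for one population/region.

    With ``seed=None`` a single run starts from the uniform distribution over
    observed compatible haplotypes; otherwise ``config.em_restarts`` random
    Dirichlet starts are tried and the best likelihood kept.
    """
    config = config or AnalysisConfig()
    panel, geno, excluded = _prepare(panel, group)
    variant_ids = list(geno.columns)
    gmat = geno.to_numpy()
    sample_ids = list(geno.index)

    sample_pairs = [_compatible_pairs(g) for g in gmat]
    hap_index: Dict[int, int] = {}
    for pairs in sample_pairs:
        for h1, h2 in pairs:
            for h in (h1, h2):
                hap_index.setdefault(h, len(hap_index))
    H = len(hap_index)
    # flat arrays for vectorized EM
    pair_h1, pair_h2, pair_w, pair_sample = [], [], [], []
    for i, pairs in enumerate(sample_pairs):
        for h1, h2 in pairs:
            pair_h1.append(hap_index[h1])
            pair_h2.append(hap_index[h2])
            pair_w.append(1.0 if h1 == h2 else 2.0)
            pair_sample.append(i)
    pair_h1 = np.array(pair_h1)
    pair_h2 = np.array(pair_h2)
    pair_w = np.array(pair_w)
    pair_sample = np.array(pair_sample)
    n = len(sample_ids)

    def run(f0: np.ndarray):
        f = f0.copy()
        prev_ll = -np.inf
        history = []
        for it in range(1, config.em_max_iter + 1):
            pp = pair_w * f[pair_h1] * f[pair_h2]
            per_sample = np.bincount(pair_sample, weights=pp, minlength=n)
            if (per_sample <= 0).any():
                return f, -np.inf, it, False, history
            ll = float(np.log(per_sample).sum())
            history.append(ll)
            resp = pp / per_sample[pair_sample]
            counts = np.bincount(pair_h1, weights=resp, minlength=H)
            counts += np.bincount(pair_h2, weights=resp, minlength=H)
            f = counts / (2.0 * n)
            if ll - prev_ll < config.em_tol and it > 1:
                return f, ll, it, True, history
            prev_ll = ll
        return f, prev_ll, config.em_max_iter, False, history

    starts = [np.full(H, 1.0 / H)]
    if seed is not None:
        rng = np.random.default_rng(seed)
        for _ in range(max(config.em_restarts - 1, 0)):
            starts.append(rng.dirichlet(np.ones(H)))
    best = None
    for f0 in starts:
        f, ll, its, conv, history = run(f0)
        if best is None or ll > best[1]:
            best = (f, ll, its, conv, history)
    f, ll, its, conv, history = best

    inv = {idx: h for h, idx in hap_index.items()}
    freqs = {inv[i]: float(f[i]) for i in range(H)}
    result = PhasingResult(variant_ids, freqs, ll, {}, {}, {}, its, conv,
                           seed=seed, excluded_samples=excluded,
                           ll_history=history)
    assign_diplotypes(result, sample_ids, sample_pairs, hap_index, f)
    return result


def assign_diplotypes(result: PhasingResult,
                      sample_ids: Optional[List[str]] = None,
                      sample_pairs=None, hap_index=None, f=None) -> PhasingResult:
    """Assign each sample its most probable genotype-consistent pair.

    Posterior is the pair's HWE probability over the sum across compatible
    pairs.  Exact ties are broken lexicographically by haplotype bitmask and
    flagged.  Samples whose every compatible pair has zero probability under
    the estimated frequencies get a uniform tie-break and a flag.
    """
    if sample_ids is None:
        raise ValueError("assign_diplotypes is invoked with the EM internals; "
                         "use em_haplotype_frequencies which calls it")
    for sid, pairs in zip(sample_ids, sample_pairs):
        probs = []
        for h1, h2 in pairs:
            w = 1.0 if h1 == h2 else 2.0
            probs.append(w * f[hap_index[h1]] * f[hap_index[h2]])
        total = float(sum(probs))
        if total <= 0.0:
            # zero-probability genotype: uniform over compatible pairs
            best_pair = min(pairs)
            result.diplotypes[sid] = best_pair
            result.posteriors[sid] = 1.0 / len(pairs)
            result.tie_flags[sid] = True
            continue
        best_p = max(probs)
        winners = [pair for pair, p in zip(pairs, probs)
                   if p >= best_p * (1 - 1e-12)]
        best_pair = min(winners)
        result.diplotypes[sid] = best_pair
        result.posteriors[sid] = best_p / total
        result.tie_flags[sid] = len(winners) > 1
    return result


@dataclass
class MultiSeedReport:
    best: PhasingResult
    seeds: List[int]
    agreement: float                 # fraction of samples identical across runs
    per_seed_loglik: Dict[int, float]
    freq_spread: float               # max abs frequency difference across runs


def multi_seed_run(panel: GenotypePanel,
                   group: Optional[Sequence[str]] = None,
                   seeds: Optional[Sequence[int]] = None,
                   config: Optional[AnalysisConfig] = None) -> MultiSeedReport:
    """Repeat EM from different seeds and report call consistency."""
    config = config or AnalysisConfig()
    seeds = list(seeds if seeds is not None else config.phasing_seeds)
    if len(seeds) < 2:
        raise ValueError("need at least 2 seeds for a consistency report")
    runs = [em_haplotype_frequencies(panel, group, config, seed=s) for s in seeds]
    best = max(runs, key=lambda r: r.log_likelihood)
    samples = list(best.diplotypes)
    agree = 0
    for sid in samples:
        calls = {r.diplotypes[sid] for r in runs}
        agree += len(calls) == 1
    agreement = agree / len(samples) if samples else 1.0
    haps = {h for r in runs for h in r.haplotype_freqs}
    spread = max((max(r.haplotype_freqs.get(h, 0.0) for r in runs)
                  - min(r.haplotype_freqs.get(h, 0.0) for r in runs)
                  for h in haps), default=0.0)
    return MultiSeedReport(best, seeds, agreement,
                           {s: r.log_likelihood for s, r in zip(seeds, runs)},
                           spread)
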