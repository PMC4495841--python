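"""Hierarchical AMOVA, Phi statistics and pairwise Phi_ST matrices.

Molecular variance is decomposed from squared pairwise distances between
chromosomes (or individuals, for phenotype-coded analyses) on up to three
levels: within populations, among populations within regions, and among
regions.  Sums of squared deviations use the identity

    SSD(group) = (1 / 2n) * sum_{i,j in group} d^2(i, j)

so that only a per-group type-count vector and a type x type squared
distance matrix are needed; permutation tests reshuffle counts, never raw
observations.  Variance components for unequal sample sizes follow the
standard hierarchical expectations; negative components are truncated to
zero (with a flag) before percentages are formed.

Distance models
---------------
* ``haplotype_pairwise_difference`` — d = number of variant sites at which
  two haplotypes differ (symmetric set difference of their variant sets);
* ``phenotype_code`` — d = difference between 0/1/2 active-allele codes,
  with individuals (not chromosomes) as the unit.

Permutation schemes (one-sided p-values, fraction of permuted statistics
at or above the observed):
* Phi_ST: chromosomes permuted among populations across the whole sample;
* Phi_SC: chromosomes permuted among populations within their region;
* Phi_CT: whole populations permuted among regions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class DistanceModel:
    """Pairwise squared distances between observation types."""

    mode: str
    types: List                      # type labels (haplotype sets or codes)
    d2: np.ndarray                   # squared distance matrix, zero diagonal

    def __post_init__(self) -> None:
        d2 = np.asarray(self.d2, dtype=float)
        if d2.shape != (len(self.types), len(self.types)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d2, d2.T) or (np.diag(d2) != 0).any() or (d2 < 0).any():
            raise ValueError("squared distances must be symmetric, >= 0, zero on the diagonal")
        self.d2 = d2

    @classmethod
    def haplotype(cls, haplotypes: Sequence[frozenset]) -> "DistanceModel":
        types = list(haplotypes)
        d2 = np.array([[float(len(a ^ b)) ** 2 for b in types] for a in types])
        return cls("haplotype_pairwise_difference", types, d2)

    @classmethod
    def phenotype(cls) -> "DistanceModel":
        codes = [0, 1, 2]
        d2 = np.array([[float(a - b) ** 2 for b in codes] for a in codes])
        return cls("phenotype_code", codes, d2)


@dataclass
class AmovaResult:
    levels: int
    sigma: Dict[str, float]                  # raw variance components
    percentages: Dict[str, float]            # after truncation, sum to 100
    phi: Dict[str, float]
    p_values: Dict[str, float] = field(default_factory=dict)
    df: Dict[str, int] = field(default_factory=dict)
    truncated: bool = False
    undefined: bool = False


def _ssd(counts: np.ndarray, d2: np.ndarray) -> Tuple[float, float]:
    """(sum of ordered-pair squared distances / 2n, n) for one group."""
    n = counts.sum()
    if n == 0:
        return 0.0, 0.0
    return float(counts @ d2 @ counts) / (2.0 * n), float(n)


def _components(counts: np.ndarray, regions: np.ndarray, d2: np.ndarray,
                levels: int):
    """Variance components from a populations x types count matrix.

    ``regions`` assigns each population (row) a region index; ignored for
    levels == 2.
    """
    P = counts.shape[0]
    n_p = counts.sum(axis=1).astype(float)
    N = n_p.sum()
    total_counts = counts.sum(axis=0)
    ssd_tot, _ = _ssd(total_counts, d2)
    q = ((counts @ d2) * counts).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssd_wp = float(np.where(n_p > 0, q / (2.0 * n_p), 0.0).sum())
    if levels == 2:
        df_wp = N - P
        df_ap = P - 1
        ssd_ap = ssd_tot - ssd_wp
        ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
        ms_ap = ssd_ap / df_ap if df_ap > 0 else 0.0
        n_c = (N - float(n_p @ n_p) / N) / df_ap if df_ap > 0 else 0.0
        sigma_c = ms_wp
        sigma_a = (ms_ap - ms_wp) / n_c if n_c > 0 else 0.0
        return {"sigma_a": sigma_a, "sigma_c": sigma_c,
                "df": {"among": int(df_ap), "within": int(df_wp)}}
    # three levels
    G = int(regions.max()) + 1
    n_g = np.array([n_p[regions == g].sum() for g in range(G)])
    ssd_wg = 0.0
    for g in range(G):
        s, _ = _ssd(counts[regions == g].sum(axis=0), d2)
        ssd_wg += s
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_tot - ssd_wg
    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1
    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    ms_ap = ssd_ap / df_ap if df_ap > 0 else 0.0
    ms_ag = ssd_ag / df_ag if df_ag > 0 else 0.0
    sum_np2_over_ng = sum(float(n_p[regions == g] @ n_p[regions == g]) / n_g[g]
                          for g in range(G) if n_g[g] > 0)
    n_c1 = (N - sum_np2_over_ng) / df_ap if df_ap > 0 else 0.0
    n_c2 = (sum_np2_over_ng - float(n_p @ n_p) / N) / df_ag if df_ag > 0 else 0.0
    n_c3 = (N - float(n_g @ n_g) / N) / df_ag if df_ag > 0 else 0.0
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n_c1 if n_c1 > 0 else 0.0
    sigma_a = ((ms_ag - sigma_c - n_c2 * sigma_b) / n_c3) if n_c3 > 0 else 0.0
    return {"sigma_a": sigma_a, "sigma_b": sigma_b, "sigma_c": sigma_c,
            "df": {"among_regions": int(df_ag),
                   "among_populations": int(df_ap),
                   "within": int(df_wp)}}


def _finalize(comp: dict, levels: int) -> AmovaResult:
    if levels == 2:
        raw = {"among": comp["sigma_a"], "within": comp["sigma_c"]}
    else:
        raw = {"among_regions": comp["sigma_a"],
               "among_populations": comp["sigma_b"],
               "within": comp["sigma_c"]}
    truncated = any(v < 0 for v in raw.values())
    trunc = {k: max(v, 0.0) for k, v in raw.items()}
    total = sum(trunc.values())
    undefined = total <= 0
    pct = {k: (100.0 * v / total if total > 0 else np.nan) for k, v in trunc.items()}
    phi: Dict[str, float] = {}
    if total > 0:
        if levels == 2:
            phi["phi_st"] = trunc["among"] / total
        else:
            phi["phi_st"] = (trunc["among_regions"] + trunc["among_populations"]) / total
            phi["phi_ct"] = trunc["among_regions"] / total
            denom = trunc["among_populations"] + trunc["within"]
            phi["phi_sc"] = trunc["among_populations"] / denom if denom > 0 else np.nan
    return AmovaResult(levels, raw, pct, phi, df=comp["df"],
                       truncated=truncated, undefined=undefined)


def _raw_phi(comp: dict, levels: int) -> Dict[str, float]:
    """Untruncated Phi statistics used for permutation comparisons.

    Truncating negative components creates an atom of permuted values equal
    to the observed one; the raw statistics keep the permutation null
    (approximately) continuous, so p-values stay near-uniform under
    exchangeability.  Reported Phi values remain the truncated ones.
    """
    sc = comp["sigma_c"]
    if levels == 2:
        sa = comp["sigma_a"]
        tot = sa + sc
        return {"phi_st": sa / tot if tot != 0 else 0.0}
    sa, sb = comp["sigma_a"], comp["sigma_b"]
    tot = sa + sb + sc
    out = {"phi_st": (sa + sb) / tot if tot != 0 else 0.0,
           "phi_ct": sa / tot if tot != 0 else 0.0}
    denom = sb + sc
    out["phi_sc"] = sb / denom if denom != 0 else 0.0
    return out


def _raw_phi_from_counts(counts: np.ndarray, regions: np.ndarray,
                         d2: np.ndarray, levels: int) -> Dict[str, float]:
    return _raw_phi(_components(counts, regions, d2, levels), levels)


def amova(counts: pd.DataFrame, d2_model: DistanceModel,
          regions: Optional[Mapping[str, str]] = None,
          levels: int = 3,
          permutations: int = 0,
          seed: Optional[int] = None) -> AmovaResult:
    """Hierarchical AMOVA from a population x type count table.

    ``counts`` rows are populations, columns observation types aligned with
    ``d2_model.types``; ``regions`` maps population -> region label (needed
    for three levels).  ``permutations=0`` skips p-values.
    """
    if len(counts) < 2:
        raise ValueError("AMOVA needs at least two populations")
    C = counts.to_numpy(dtype=np.int64)
    if C.shape[1] != len(d2_model.types):
        raise ValueError("count columns must match distance-model types")
    if levels == 3:
        if regions is None:
            raise ValueError("three-level AMOVA needs a population->region map")
        labels = [regions[p] for p in counts.index]
        uniq = list(dict.fromkeys(labels))
        if len(uniq) < 2:
            raise ValueError("three-level AMOVA needs at least two regions")
        reg = np.array([uniq.index(x) for x in labels])
    else:
        reg = np.zeros(len(counts), dtype=int)
    d2 = d2_model.d2
    comp = _components(C, reg, d2, levels)
    result = _finalize(comp, levels)
    if permutations <= 0 or result.undefined:
        return result
    obs = _raw_phi(comp, levels)

    rng = np.random.default_rng(seed)
    T = C.shape[1]
    P = C.shape[0]
    n_p = C.sum(axis=1)
    # flat type array + population ids for chromosome-level shuffles
    types_flat = np.repeat(np.tile(np.arange(T), P), C.ravel())
    pop_ids = np.repeat(np.arange(P), n_p)
    hits = {k: 0 for k in obs}

    def counts_from(types_perm: np.ndarray) -> np.ndarray:
        M = np.zeros((P, T), dtype=np.int64)
        np.add.at(M, (pop_ids, types_perm), 1)
        return M

    # Phi_ST: chromosomes among populations, everywhere
    for _ in range(permutations):
        perm = rng.permutation(types_flat)
        phi = _raw_phi_from_counts(counts_from(perm), reg, d2, levels)
        if phi.get("phi_st", -np.inf) >= obs["phi_st"] - 1e-12:
            hits["phi_st"] += 1
    if levels == 3:
        # Phi_SC: chromosomes among populations within regions
        region_masks = [np.flatnonzero(reg[pop_ids] == g) for g in range(reg.max() + 1)]
        for _ in range(permutations):
            perm = types_flat.copy()
            for idx in region_masks:
                perm[idx] = perm[idx][rng.permutation(len(idx))]
            phi = _raw_phi_from_counts(counts_from(perm), reg, d2, levels)
            if phi.get("phi_sc", -np.inf) >= obs["phi_sc"] - 1e-12:
                hits["phi_sc"] += 1
        # Phi_CT: whole populations among regions
        for _ in range(permutations):
            phi = _raw_phi_from_counts(C, rng.permutation(reg), d2, levels)
            if phi.get("phi_ct", -np.inf) >= obs["phi_ct"] - 1e-12:
                hits["phi_ct"] += 1
    result.p_values = {k: (hits[k] + 1) / (permutations + 1) for k in hits}
    return result


def haplotype_amova(allele_counts: pd.DataFrame,
                    allele_variants: Mapping[str, frozenset],
                    regions: Optional[Mapping[str, str]] = None,
                    levels: int = 3, permutations: int = 0,
                    seed: Optional[int] = None) -> AmovaResult:
    """AMOVA on star-allele counts with pairwise-difference distances."""
    names = [a for a in allele_counts.columns if a in allele_variants]
    model = DistanceModel.haplotype([allele_variants[a] for a in names])
    return amova(allele_counts[names], model, regions=regions, levels=levels,
                 permutations=permutations, seed=seed)


def phenotype_amova(phenotype_counts: pd.DataFrame,
                    regions: Optional[Mapping[str, str]] = None,
                    levels: int = 3, permutations: int = 0,
                    seed: Optional[int] = None) -> AmovaResult:
    """AMOVA on 0/1/2 active-allele codes, individuals as units.

    ``phenotype_counts`` columns must be the number of individuals carrying
    zero, one and two active alleles, in code order (n0, n1, n2).
    """
    model = DistanceModel.phenotype()
    counts = phenotype_counts.copy()
    counts.columns = range(counts.shape[1])
    return amova(counts, model, regions=regions, levels=levels,
                 permutations=permutations, seed=seed)


def pairwise_phi_st(counts: pd.DataFrame, d2_model: DistanceModel,
                    permutations: int = 0,
                    seed: Optional[int] = None):
    """Two-level Phi_ST for every pair of groups (rows of ``counts``).

    Groups with fewer than 2 observations are excluded.  Returns a symmetric
    DataFrame (diagonal 0) and, when permutations > 0, a matching p-value
    DataFrame.
    """
    keep = counts.sum(axis=1) >= 2
    counts = counts.loc[keep]
    groups = list(counts.index)
    if len(groups) < 2:
        raise ValueError("need at least two groups of size >= 2")
    fst = pd.DataFrame(0.0, index=groups, columns=groups)
    pval = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            res = amova(counts.loc[[a, b]], d2_model, levels=2,
                        permutations=permutations, seed=seed)
            v = res.phi.get("phi_st", np.nan)
            fst.loc[a, b] = fst.loc[b, a] = v
            if permutations > 0:
                p = res.p_values.get("phi_st", np.nan)
                pval.loc[a, b] = pval.loc[b, a] = p
    return (fst, pval) if permutations > 0 else (fst, None)
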