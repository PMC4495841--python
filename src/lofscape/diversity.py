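"""Allele-frequency tabulation and functionally stratified diversity.

Statistics follow the standard frequency-spectrum estimators on a sample of
n chromosomes scored at biallelic coding sites, normalized per site by the
coding-region length L:

* nucleotide diversity ``pi = [n/(n-1)] * sum_sites 2 p (1-p) / L`` — the
  unbiased mean pairwise difference per site;
* Watterson's ``theta_W = S / (a1 L)`` with ``a1 = sum_{i<n} 1/i``;
* Tajima's D, the normalized difference between the pairwise and
  segregating-sites estimators, with the 1989 variance constants, and an
  optional p-value from a fixed-S neutral-coalescent null.

Sites are stratified by the functional class (LOF / non-LOF) of the
amino-acid variant they carry, so that selection acting specifically on
activity-destroying variation shows up as a depressed pi_LOF / pi_non-LOF
ratio and negative D in the LOF stratum.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .coalescent import simulate_site_counts
from .model import AlleleTable, AnalysisConfig, PopulationPanel


# ---------------------------------------------------------------------------
# frequency tables

def region_frequency_summary(freq_pct: pd.DataFrame, panel: PopulationPanel,
                             include_admixed: bool = False) -> pd.DataFrame:
    """Unweighted region means of per-population allele percentages.

    Mirrors the survey's summary convention: a region's value is the plain
    arithmetic mean over its member populations (admixed panels excluded),
    and the worldwide row is the unweighted mean over every population.
    """
    rows = {}
    for region in panel.regions(include_admixed=include_admixed):
        pops = panel.members(region, include_admixed=include_admixed)
        if not pops:
            continue
        rows[region] = freq_pct.loc[pops].mean(axis=0)
    rows["Worldwide"] = freq_pct.loc[panel.populations].mean(axis=0)
    return pd.DataFrame(rows).T


def pooled_frequency(freq_pct: pd.DataFrame, panel: PopulationPanel,
                     populations: Sequence[str]) -> pd.Series:
    """Chromosome-weighted pooled allele frequencies (percent) over a subset."""
    counts = None
    total = 0
    for pop in populations:
        nchr = panel.n_chromosomes(pop)
        c = np.round(freq_pct.loc[pop].to_numpy() * nchr / 100.0)
        counts = c if counts is None else counts + c
        total += nchr
    return pd.Series(100.0 * counts / total, index=freq_pct.columns)


def allele_counts_from_percent(freq_pct: pd.DataFrame,
                               panel: PopulationPanel) -> pd.DataFrame:
    """Integer allele counts per population, rounding percent x 2N."""
    rows = {}
    for pop in freq_pct.index:
        nchr = panel.n_chromosomes(pop)
        rows[pop] = np.round(freq_pct.loc[pop].to_numpy() * nchr / 100.0).astype(int)
    return pd.DataFrame.from_dict(rows, orient="index", columns=freq_pct.columns)


def frequency_table_from_assignments(allele_per_chromosome: Mapping[str, List[str]],
                                     panel: PopulationPanel) -> pd.DataFrame:
    """Per-population allele frequencies (percent) from named chromosomes.

    ``allele_per_chromosome`` maps population -> list of allele names, one
    per chromosome (e.g. flattened diplotype calls).
    """
    all_names = sorted({a for names in allele_per_chromosome.values() for a in names})
    rows = {}
    for pop, names in allele_per_chromosome.items():
        nchr = panel.n_chromosomes(pop)
        if len(names) != nchr:
            raise ValueError(f"{pop}: {len(names)} chromosomes, panel says {nchr}")
        s = pd.Series(names).value_counts()
        rows[pop] = [100.0 * s.get(a, 0) / nchr for a in all_names]
    return pd.DataFrame.from_dict(rows, orient="index", columns=all_names)


def pooled_variant_maf(variant_id: str, freq_pct: pd.DataFrame,
                       panel: PopulationPanel, alleles: AlleleTable,
                       populations: Sequence[str]) -> float:
    """Chromosome-weighted pooled frequency (percent) of one variant.

    The variant's carriers are every major allele whose definition includes
    it (e.g. the codon-420 deletion rides on *2, *5, *6 and *14).
    """
    carriers = alleles.carriers_of(variant_id)
    if not carriers:
        known = set()
        for a in alleles:
            known |= a.variants
        if variant_id not in known:
            raise KeyError(f"unknown variant {variant_id!r}")
        return 0.0
    carriers = [c for c in carriers if c in freq_pct.columns]
    count = 0
    total = 0
    for pop in populations:
        nchr = panel.n_chromosomes(pop)
        pct = float(freq_pct.loc[pop, carriers].sum())
        count += round(pct * nchr / 100.0)
        total += nchr
    return 100.0 * count / total


# ---------------------------------------------------------------------------
# diversity statistics

@dataclass
class SiteFrequencyStratum:
    """Segregating-site counts for one (region, functional stratum) cell."""

    region: str
    stratum: str                   # all | LOF | non_LOF
    n: int                         # chromosomes sampled
    counts: List[int] = field(default_factory=list)   # minor/derived counts

    def __post_init__(self) -> None:
        self.counts = [int(c) for c in self.counts if 0 < c < self.n]

    @property
    def S(self) -> int:
        return len(self.counts)


@dataclass
class DiversityStats:
    region: str
    stratum: str
    S: int
    pi_per_site: float
    theta_per_site: float
    tajimas_d: Optional[float]
    d_p_value: Optional[float]
    L: int
    n: int


def harmonic_a1(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def nucleotide_diversity(stratum: SiteFrequencyStratum, L: int) -> float:
    """Unbiased per-site pi from site counts: [n/(n-1)] sum 2p(1-p) / L."""
    n = stratum.n
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if stratum.S == 0:
        return 0.0
    p = np.asarray(stratum.counts, dtype=float) / n
    return float(n / (n - 1) * np.sum(2.0 * p * (1.0 - p)) / L)


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's estimator per site: S / (a1 L)."""
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    if S == 0:
        return 0.0
    return float(S / (harmonic_a1(n) * L))


def _tajima_constants(n: int):
    a1 = harmonic_a1(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d_from_counts(counts: Sequence[int], n: int) -> float:
    """Tajima (1989) D from per-site derived/minor counts."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    S = len(counts)
    if S == 0:
        raise ValueError("Tajima's D undefined with S = 0")
    p = np.asarray(counts, dtype=float) / n
    khat = float(n / (n - 1) * np.sum(2.0 * p * (1.0 - p)))
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (khat - S / a1) / np.sqrt(var)


def tajimas_d(stratum: SiteFrequencyStratum,
              p_value_reps: int = 0,
              seed: Optional[int] = None,
              alternative: str = "two_sided"):
    """Tajima's D with an optional fixed-S neutral-simulation p-value.

    The null is the neutral coalescent at matched n and S.  ``alternative``
    selects the rejection direction: "two_sided" counts replicates with
    |D_sim| >= |D_obs|; "less" counts D_sim <= D_obs (a diversity deficit,
    e.g. purifying selection — the convention under which the survey's
    significance levels are reported); "greater" the opposite tail.
    Returns (D, p) with p None when reps == 0; with S == 0 returns
    (None, None).
    """
    if stratum.S == 0:
        return None, None
    d = tajimas_d_from_counts(stratum.counts, stratum.n)
    if p_value_reps <= 0:
        return d, None
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(p_value_reps):
        sim = simulate_site_counts(stratum.n, stratum.S, rng)
        d_sim = tajimas_d_from_counts(sim, stratum.n)
        if alternative == "two_sided":
            hits += abs(d_sim) >= abs(d)
        elif alternative == "less":
            hits += d_sim <= d
        elif alternative == "greater":
            hits += d_sim >= d
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return d, hits / p_value_reps


# ---------------------------------------------------------------------------
# stratified reconstruction and the region x stratum table

def region_site_counts(freq_pct: pd.DataFrame, panel: PopulationPanel,
                       alleles: AlleleTable,
                       variant_classes: Mapping[str, str],
                       nonlof_site_freqs: Optional[pd.DataFrame] = None
                       ) -> Dict[str, Dict[str, SiteFrequencyStratum]]:
    """Reconstruct per-region site-frequency strata from frequency tables.

    Variant counts carried by major alleles come from the allele-frequency
    table (counts summed over carrier alleles); variants present only on
    sub-alleles may be supplied through ``nonlof_site_freqs`` (population x
    variant fractions).  Admixed populations are excluded.
    """
    counts = allele_counts_from_percent(freq_pct, panel)
    out: Dict[str, Dict[str, SiteFrequencyStratum]] = {}
    variant_ids = [v for a in alleles.majors() for v in sorted(a.variants)]
    variant_ids = list(dict.fromkeys(variant_ids))
    for region in panel.regions():
        pops = panel.members(region)
        n = sum(panel.n_chromosomes(p) for p in pops)
        site_counts: Dict[str, int] = {}
        for v in variant_ids:
            carriers = [c for c in alleles.carriers_of(v) if c in counts.columns]
            site_counts[v] = int(counts.loc[pops, carriers].to_numpy().sum())
        if nonlof_site_freqs is not None:
            for v in nonlof_site_freqs.columns:
                c = sum(round(float(nonlof_site_freqs.loc[p, v]) * panel.n_chromosomes(p))
                        for p in pops if p in nonlof_site_freqs.index)
                site_counts[v] = site_counts.get(v, 0) + int(c)
        strata = {}
        for name, keep in (
                ("all", lambda cls: True),
                ("LOF", lambda cls: cls == "LOF"),
                ("non_LOF", lambda cls: cls == "non_LOF")):
            sel = [c for v, c in site_counts.items()
                   if keep(variant_classes.get(v, "unknown"))]
            strata[name] = SiteFrequencyStratum(region, name, n, sel)
        out[region] = strata
    return out


def stratified_table(strata: Mapping[str, Mapping[str, SiteFrequencyStratum]],
                     config: Optional[AnalysisConfig] = None,
                     p_value_reps: int = 0,
                     seed: Optional[int] = None,
                     alternative: str = "less") -> pd.DataFrame:
    """One row per region: pi, theta, D for all/LOF/non-LOF plus pi ratio.

    Values are on the per-site scale (multiply by 1e4 for display in the
    conventional x10^-4 units).  D is omitted (NaN) when S = 0 or n < 4.
    D p-values default to the "less" alternative (diversity deficit), the
    convention under which the survey's significance levels are quoted.
    """
    config = config or AnalysisConfig()
    L = config.coding_length_L
    rows = []
    for region, cell in strata.items():
        rec: Dict[str, object] = {"region": region}
        for name, st in cell.items():
            rec[f"pi_{name}"] = nucleotide_diversity(st, L)
            rec[f"theta_{name}"] = watterson_theta(st.S, st.n, L)
            rec[f"S_{name}"] = st.S
            if st.S > 0 and st.n >= 4:
                d, p = tajimas_d(st, p_value_reps=p_value_reps, seed=seed,
                                 alternative=alternative)
            else:
                d, p = None, None
            rec[f"D_{name}"] = np.nan if d is None else d
            rec[f"D_p_{name}"] = np.nan if p is None else p
        pi_non = rec.get("pi_non_LOF", 0.0)
        rec["pi_ratio_LOF_nonLOF"] = (rec["pi_LOF"] / pi_non if pi_non > 0
                                      else (0.0 if rec["pi_LOF"] == 0 else np.inf))
        rec["n"] = cell["all"].n
        rec["L"] = L
        rows.append(rec)
    return pd.DataFrame(rows).set_index("region")
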