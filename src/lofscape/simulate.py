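"""Synthetic genotype panels with the structure the analysis assumes.

Sampling operates at the star-allele (haplotype) level: each individual
draws two alleles from its population's allele-frequency vector —
independently with probability 1-F, or identical by descent with
probability F (inbreeding coefficient) — exactly the Hardy-Weinberg
sampling model the frequency-based analyses themselves invoke.  Drawn
alleles are expanded to amino-acid variant sets via the allele definitions
and emitted as unphased 0/1/2 alternate-copy counts; an optional symmetric
per-site flip error is applied after expansion.  A truth set records every
individual's ordered allele pair for downstream recovery scoring.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import AlleleTable, GenotypePanel, PopulationPanel


@dataclass
class PopulationSpec:
    name: str
    region: str
    n_individuals: int
    allele_freqs: Dict[str, float]

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("population size must be >= 1")
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: allele frequencies sum to {total}, not 1")


@dataclass
class SimulationConfig:
    populations: List[PopulationSpec]
    inbreeding_f: float = 0.0
    genotype_error_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding F must lie in [0, 1]")
        if not 0.0 <= self.genotype_error_rate <= 1.0:
            raise ValueError("genotype error rate must lie in [0, 1]")


@dataclass
class TruthSet:
    """True diplotypes and realized allele counts for a simulated panel."""

    diplotypes: Dict[str, Tuple[str, str]]            # sample -> ordered pair
    populations: Dict[str, str]                       # sample -> population
    allele_counts: pd.DataFrame                       # population x allele

    def realized_frequencies(self) -> pd.DataFrame:
        totals = self.allele_counts.sum(axis=1)
        return self.allele_counts.div(totals, axis=0)


def simulate_panel(config: SimulationConfig, alleles: AlleleTable
                   ) -> Tuple[GenotypePanel, TruthSet]:
    """Draw a genotype panel under per-population HWE allele sampling."""
    rng = np.random.default_rng(config.rng_seed)
    for spec in config.populations:
        for name in spec.allele_freqs:
            if name not in alleles:
                raise ValueError(f"allele {name} not in definition table")
            if not alleles[name].composition_known:
                raise ValueError(
                    f"allele {name} has unknown variant composition; drop it "
                    "or supply a composition")
    variant_ids = sorted({v for spec in config.populations
                          for a in spec.allele_freqs
                          for v in alleles[a].variants})
    var_index = {v: i for i, v in enumerate(variant_ids)}
    hap_vec = {}
    for spec in config.populations:
        for a in spec.allele_freqs:
            if a not in hap_vec:
                vec = np.zeros(len(variant_ids), dtype=np.int8)
                for v in alleles[a].variants:
                    vec[var_index[v]] = 1
                hap_vec[a] = vec

    sample_rows = []
    geno_rows = []
    diplotypes: Dict[str, Tuple[str, str]] = {}
    sample_pops: Dict[str, str] = {}
    count_rows = {}
    all_names = sorted({a for spec in config.populations for a in spec.allele_freqs})
    for spec in config.populations:
        names = list(spec.allele_freqs)
        probs = np.array([spec.allele_freqs[a] for a in names], dtype=float)
        probs = probs / probs.sum()
        counts = dict.fromkeys(all_names, 0)
        first = rng.choice(len(names), size=spec.n_individuals, p=probs)
        second = rng.choice(len(names), size=spec.n_individuals, p=probs)
        ibd = rng.random(spec.n_individuals) < config.inbreeding_f
        second = np.where(ibd, first, second)
        for i in range(spec.n_individuals):
            a1, a2 = names[first[i]], names[second[i]]
            sid = f"{spec.name}_{i:04d}"
            counts[a1] += 1
            counts[a2] += 1
            g = hap_vec[a1] + hap_vec[a2]
            if config.genotype_error_rate > 0:
                flips = rng.random(len(variant_ids)) < config.genotype_error_rate
                shift = rng.integers(1, 3, size=len(variant_ids))
                g = np.where(flips, (g + shift) % 3, g).astype(np.int8)
            sample_rows.append({"sample_id": sid, "population": spec.name})
            geno_rows.append(g)
            diplotypes[sid] = (a1, a2)
            sample_pops[sid] = spec.name
        count_rows[spec.name] = counts

    samples = pd.DataFrame(sample_rows)
    geno = pd.DataFrame(np.array(geno_rows, dtype=int) if geno_rows else
                        np.empty((0, len(variant_ids)), dtype=int),
                        index=pd.Index(samples["sample_id"], name="sample_id"),
                        columns=variant_ids)
    panel_meta = PopulationPanel(pd.DataFrame(
        {"population": [s.name for s in config.populations],
         "region": [s.region for s in config.populations],
         "n_individuals": [s.n_individuals for s in config.populations],
         "admixed": [False] * len(config.populations),
         "source": ["simulated"] * len(config.populations)}))
    allele_counts = pd.DataFrame.from_dict(count_rows, orient="index",
                                           columns=all_names).fillna(0).astype(int)
    truth = TruthSet(diplotypes, sample_pops, allele_counts)
    return GenotypePanel(samples, geno, panel=panel_meta), truth


def simulate_from_frequency_table(freq_pct: pd.DataFrame,
                                  panel: PopulationPanel,
                                  alleles: AlleleTable,
                                  n_override: Optional[int] = None,
                                  seed: int = 0,
                                  inbreeding_f: float = 0.0,
                                  error_rate: float = 0.0,
                                  populations: Optional[Sequence[str]] = None
                                  ) -> Tuple[GenotypePanel, TruthSet]:
    """World-scale panel mirroring the survey's sizes and frequencies.

    Alleles of unknown composition (and zero-frequency columns) are dropped
    with renormalization.  ``n_override`` replaces every population's sample
    size, e.g. for large-N recovery checks.
    """
    specs = []
    pops = list(populations) if populations is not None else list(freq_pct.index)
    for pop in pops:
        row = freq_pct.loc[pop]
        freqs = {}
        for name, pct in row.items():
            if pct <= 0:
                continue
            if name not in alleles or not alleles[name].composition_known:
                continue   # dropped with renormalization below
            freqs[name] = float(pct)
        total = sum(freqs.values())
        if total <= 0:
            raise ValueError(f"{pop}: no usable alleles")
        freqs = {k: v / total for k, v in freqs.items()}
        n = n_override if n_override is not None else panel.table.loc[
            panel.table["population"] == pop, "n_individuals"].iloc[0]
        specs.append(PopulationSpec(pop, panel.region_of(pop), int(n), freqs))
    config = SimulationConfig(specs, inbreeding_f=inbreeding_f,
                              genotype_error_rate=error_rate, rng_seed=seed)
    return simulate_panel(config, alleles)


@dataclass
class RecoveryReport:
    diplotype_accuracy: float
    frequency_rmse: float
    confusion: pd.DataFrame       # true n_active x called n_active


def compare_to_truth(called_diplotypes: Mapping[str, Tuple[str, str]],
                     truth: TruthSet,
                     called_freqs: Optional[pd.DataFrame] = None,
                     active_set: Sequence[str] = ("*1", "*8", "*9")
                     ) -> RecoveryReport:
    """Score pipeline output against the simulation truth."""
    if set(called_diplotypes) != set(truth.diplotypes):
        raise ValueError("sample sets differ between calls and truth")
    active = set(active_set)
    correct = 0
    confusion = np.zeros((3, 3), dtype=int)
    for sid, pair in called_diplotypes.items():
        true_pair = truth.diplotypes[sid]
        if tuple(sorted(pair)) == tuple(sorted(true_pair)):
            correct += 1
        t = sum(a in active for a in true_pair)
        c = sum(a in active for a in pair)
        confusion[t, c] += 1
    accuracy = correct / len(called_diplotypes)
    rmse = np.nan
    if called_freqs is not None:
        true_f = truth.realized_frequencies()
        common_pops = true_f.index.intersection(called_freqs.index)
        common_alleles = true_f.columns.intersection(called_freqs.columns)
        a = true_f.loc[common_pops, common_alleles].to_numpy()
        b = called_freqs.loc[common_pops, common_alleles].to_numpy()
        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    conf = pd.DataFrame(confusion,
                        index=pd.Index([0, 1, 2], name="true_n_active"),
                        columns=pd.Index([0, 1, 2], name="called_n_active"))
    return RecoveryReport(accuracy, rmse, conf)
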