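"""Core data model for the loss-of-function landscape pipeline.

The pipeline works at three granularities:

* amino-acid variants (:class:`VariantDef`) — biallelic coding markers, one of
  which is an in-frame single-codon deletion treated as an ordinary biallelic
  site throughout;
* star alleles (:class:`AlleleDefinition`) — named haplotypes defined by the
  set of variants they carry (the reference allele ``*1`` carries none);
* populations (:class:`PopulationPanel`) — sampled groups with a geographic
  region label; admixed panels are excluded from region-level statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FUNCTIONAL_CLASSES = ("LOF", "non_LOF", "unknown")
ALLELE_CATEGORIES = ("reference", "major", "sub", "unknown")

#: seeds used by default for repeated phasing runs
DEFAULT_PHASING_SEEDS = (2, 1536, 2936, 3123, 4957, 5283, 6757, 7992, 8633, 9045)


@dataclass(frozen=True)
class VariantDef:
    """One amino-acid-level coding variant."""

    variant_id: str
    codon: int
    ref_residue: str = ""
    alt_residue: str = ""
    rs_id: Optional[str] = None
    genomic_pos: Optional[int] = None
    functional_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.codon < 1:
            raise ValueError(f"codon must be >= 1, got {self.codon}")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"bad functional class {self.functional_class!r}")

    def with_class(self, functional_class: str) -> "VariantDef":
        return replace(self, functional_class=functional_class)


@dataclass(frozen=True)
class AlleleDefinition:
    """A star allele: a named set of amino-acid variants.

    ``composition_known=False`` marks alleles whose variant content is not
    established; they are excluded from haplotype naming and from activity
    classification unless explicitly overridden.
    """

    name: str
    variants: frozenset = frozenset()
    parent: Optional[str] = None
    category: str = "major"
    composition_known: bool = True

    def __post_init__(self) -> None:
        if self.category not in ALLELE_CATEGORIES:
            raise ValueError(f"bad allele category {self.category!r}")
        object.__setattr__(self, "variants", frozenset(self.variants))
        if self.category == "reference" and self.variants:
            raise ValueError("reference allele must carry no variants")


class AlleleTable:
    """Ordered collection of :class:`AlleleDefinition` with lookups."""

    def __init__(self, alleles: Iterable[AlleleDefinition]):
        self.alleles = list(alleles)
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate allele names")
        self._by_name = {a.name: a for a in self.alleles}
        # exact-match index over known compositions; reference wins ties with
        # any other empty-set allele by insertion order
        self._by_variants: dict = {}
        for a in self.alleles:
            if a.composition_known:
                self._by_variants.setdefault(a.variants, a.name)
        for a in self.alleles:
            if a.parent is not None and a.parent not in self._by_name:
                raise ValueError(f"sub-allele {a.name} has unknown parent {a.parent}")

    def __iter__(self):
        return iter(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> AlleleDefinition:
        return self._by_name[name]

    @property
    def names(self) -> list:
        return [a.name for a in self.alleles]

    def majors(self) -> list:
        return [a for a in self.alleles if a.category in ("reference", "major")]

    def lookup_variants(self, variants: frozenset) -> Optional[str]:
        return self._by_variants.get(frozenset(variants))

    def variant_ids(self) -> list:
        out: list = []
        for a in self.alleles:
            for v in sorted(a.variants):
                if v not in out:
                    out.append(v)
        return out

    def carriers_of(self, variant_id: str, majors_only: bool = True) -> list:
        """Alleles whose definition includes ``variant_id``."""
        pool = self.majors() if majors_only else self.alleles
        return [a.name for a in pool if variant_id in a.variants]


class PopulationPanel:
    """Population metadata: region, sample size, admixture and source flags."""

    REQUIRED = ("population", "region", "n_individuals", "admixed", "source")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"panel table missing columns {missing}")
        table = table.copy()
        table["n_individuals"] = table["n_individuals"].astype(int)
        table["admixed"] = table["admixed"].astype(bool)
        if (table["n_individuals"] <= 0).any():
            raise ValueError("population sizes must be positive")
        if table["population"].duplicated().any():
            raise ValueError("duplicate population names")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, population: str) -> bool:
        return population in set(self.table["population"])

    @property
    def populations(self) -> list:
        return list(self.table["population"])

    def n_chromosomes(self, population: str) -> int:
        row = self.table.loc[self.table["population"] == population]
        if row.empty:
            raise KeyError(population)
        return 2 * int(row["n_individuals"].iloc[0])

    def region_of(self, population: str) -> str:
        row = self.table.loc[self.table["population"] == population]
        if row.empty:
            raise KeyError(population)
        return str(row["region"].iloc[0])

    def non_admixed(self) -> "PopulationPanel":
        return PopulationPanel(self.table.loc[~self.table["admixed"]])

    def regions(self, include_admixed: bool = False) -> list:
        t = self.table if include_admixed else self.table.loc[~self.table["admixed"]]
        return list(dict.fromkeys(t["region"]))

    def members(self, region: str, include_admixed: bool = False) -> list:
        t = self.table if include_admixed else self.table.loc[~self.table["admixed"]]
        return list(t.loc[t["region"] == region, "population"])


class GenotypePanel:
    """Unphased diploid genotypes: samples x variants, alternate-copy counts.

    ``genotypes`` is an int matrix with values in {0, 1, 2} (or -1 for
    missing), indexed by sample_id, with one column per variant_id.
    ``samples`` maps each sample to its population.
    """

    def __init__(self, samples: pd.DataFrame, genotypes: pd.DataFrame,
                 panel: Optional[PopulationPanel] = None):
        if not {"sample_id", "population"}.issubset(samples.columns):
            raise ValueError("samples table needs sample_id and population")
        if samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if list(genotypes.index) != list(samples["sample_id"]):
            genotypes = genotypes.loc[samples["sample_id"]]
        vals = genotypes.to_numpy()
        bad = ~np.isin(vals, (0, 1, 2, -1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype {vals[i, j]!r} for sample "
                f"{genotypes.index[i]!r} at variant {genotypes.columns[j]!r}"
            )
        if panel is not None:
            known = set(panel.populations)
            unknown = set(samples["population"]) - known
            if unknown:
                raise ValueError(f"populations not in panel: {sorted(unknown)}")
        self.samples = samples.reset_index(drop=True)
        self.genotypes = genotypes.astype(int)
        self.panel = panel

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def variant_ids(self) -> list:
        return list(self.genotypes.columns)

    def population_of(self, sample_id: str) -> str:
        row = self.samples.loc[self.samples["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["population"].iloc[0])

    def subset(self, populations: Sequence[str]) -> "GenotypePanel":
        keep = self.samples["population"].isin(populations)
        samples = self.samples.loc[keep]
        return GenotypePanel(samples, self.genotypes.loc[samples["sample_id"]],
                             panel=self.panel)


@dataclass
class AnalysisConfig:
    """Tunable parameters shared across the pipeline.

    coding_length_L
        Length (bp) used to put pi and Watterson's theta on a per-site scale.
        Defaults to 1665 bp: a 554-codon coding sequence plus stop codon.
    active_allele_set
        Star alleles treated as fully active when scoring 0/1/2-active
        phenotypes.
    major_threshold / gain_threshold
        An allele is "major" when some substrate activity drops below 50 % or
        rises above 150 % of reference (strict inequalities).
    inactive_threshold
        An allele loses phenotype activity when some substrate activity falls
        below 35 % of reference (the "more than 65 % reduction" rule).
    complete_loss_floor
        Activities at or below this value (percent) count as complete loss.
    retained_threshold
        Substrate-specific loss requires retention above this value (percent)
        for at least one other substrate.
    """

    coding_length_L: int = 1665
    active_allele_set: tuple = ("*1", "*8", "*9")
    major_threshold: float = 50.0
    gain_threshold: float = 150.0
    inactive_threshold: float = 35.0
    complete_loss_floor: float = 5.0
    retained_threshold: float = 90.0
    permutations: int = 10_000
    d_null_reps: int = 1000
    rng_seed: int = 0
    em_max_iter: int = 2000
    em_tol: float = 1e-10
    em_restarts: int = 3
    phasing_seeds: tuple = DEFAULT_PHASING_SEEDS

    def __post_init__(self) -> None:
        if self.coding_length_L <= 0:
            raise ValueError("coding_length_L must be positive")
        for name in ("major_threshold", "inactive_threshold", "retained_threshold"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must lie strictly between 0 and 100")
        if self.permutations < 0:
            raise ValueError("permutations must be >= 0")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["active_allele_set"] = list(self.active_allele_set)
        d["phasing_seeds"] = list(self.phasing_seeds)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        for key in ("active_allele_set", "phasing_seeds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
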