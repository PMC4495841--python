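"""End-to-end orchestration: from fixtures or a genotype panel to report tables."""
from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__, datasets
from .activity import classify_alleles, classify_variants, name_haplotype, score_phenotypes
from .association import hwe_carrier_distribution, loss_frequency_per_population
from .diversity import (frequency_table_from_assignments, pooled_frequency,
                        region_frequency_summary, region_site_counts,
                        stratified_table)
from .model import AlleleTable, AnalysisConfig, GenotypePanel, PopulationPanel
from .phasing import multi_seed_run
from .structure import DistanceModel, haplotype_amova, pairwise_phi_st, phenotype_amova


@dataclass
class ReportBundle:
    tables: Dict[str, pd.DataFrame]
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t",
                      float_format="%.10g")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _classification_overrides(variant_defs) -> dict:
    return {v.variant_id: v.functional_class for v in variant_defs.values()
            if v.functional_class != "unknown"}


def run_pipeline(config: Optional[AnalysisConfig] = None,
                 genotype_panel: Optional[GenotypePanel] = None,
                 panel: Optional[PopulationPanel] = None,
                 freq_pct: Optional[pd.DataFrame] = None,
                 alleles: Optional[AlleleTable] = None,
                 activity_matrix: Optional[pd.DataFrame] = None,
                 nonlof_site_freqs: Optional[pd.DataFrame] = None) -> ReportBundle:
    """Run the analysis and return every report table plus a manifest.

    Two modes:

    * fixture-only (no ``genotype_panel``): frequency summaries, phenotype
      expectations under HWE, stratified diversity and frequency-based
      structure statistics are produced; diplotype-level outputs are marked
      unavailable;
    * genotype mode: the panel is phased per population, haplotypes are
      named, individuals scored and all downstream tables derive from calls.
    """
    config = config or AnalysisConfig()
    if panel is None:
        panel = datasets.population_panel()
    if alleles is None:
        alleles = datasets.allele_definitions()
    if activity_matrix is None:
        activity_matrix = datasets.activity_matrix()
    if activity_matrix is None:
        raise ValueError("activity matrix required for classification")
    variant_defs = datasets.variant_table()
    classification = classify_alleles(activity_matrix, alleles, config)
    variant_classes = classify_variants(
        activity_matrix, alleles,
        overrides=_classification_overrides(variant_defs), config=config)

    tables: Dict[str, pd.DataFrame] = {}
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "mode": "fixture" if genotype_panel is None else "genotypes",
        "permutations": config.permutations,
    }

    if genotype_panel is None:
        if freq_pct is None:
            freq_pct = datasets.allele_frequency_table()
        if nonlof_site_freqs is None:
            nonlof_site_freqs = datasets.nonlof_site_frequencies()
        manifest["diplotype_outputs"] = "unavailable (fixture-only mode)"
        # HWE expectations for the 0/1/2-active phenotype distribution
        active = [a for a in freq_pct.columns
                  if a in classification and classification[a].active_for_phenotype]
        p_active = (freq_pct[active].sum(axis=1) / 100.0).clip(0, 1)
        phen = pd.DataFrame(
            [hwe_carrier_distribution(p).as_tuple() for p in p_active],
            index=freq_pct.index, columns=["p_two", "p_one", "p_zero"])
        tables["phenotype_distribution"] = phen
    else:
        # per-population phasing, naming, scoring
        assignments: Dict[str, list] = {}
        diplotypes: Dict[str, tuple] = {}
        pops_of: Dict[str, str] = {}
        for pop in dict.fromkeys(genotype_panel.samples["population"]):
            report = multi_seed_run(genotype_panel, [pop], config=config)
            res = report.best
            for sid, (h1, h2) in res.diplotypes.items():
                pair = []
                for mask in (h1, h2):
                    name = name_haplotype(res.haplotype_variants(mask), alleles)
                    pair.append(name if isinstance(name, str) else "novel")
                diplotypes[sid] = tuple(pair)
                pops_of[sid] = pop
                assignments.setdefault(pop, []).extend(pair)
        calls, dist = score_phenotypes(diplotypes, pops_of, classification)
        tables["phenotype_distribution"] = dist
        use_panel = genotype_panel.panel or panel
        freq_pct = frequency_table_from_assignments(assignments, use_panel)
        panel = use_panel
        if nonlof_site_freqs is None:
            nonlof_site_freqs = None  # derived data carries its own sites

    # frequency summaries
    tables["allele_frequencies"] = freq_pct
    tables["region_summary"] = region_frequency_summary(freq_pct, panel)
    non_admixed = [p for p in panel.non_admixed().populations
                   if p in freq_pct.index]
    tables["pooled_frequencies"] = pooled_frequency(
        freq_pct, panel, non_admixed).to_frame("percent")

    # stratified diversity
    strata = region_site_counts(freq_pct, panel, alleles, variant_classes,
                                nonlof_site_freqs=nonlof_site_freqs)
    tables["stratified_diversity"] = stratified_table(
        strata, config,
        p_value_reps=config.d_null_reps if config.permutations > 0 else 0,
        seed=config.rng_seed)

    # structure: region-level AMOVA and pairwise Phi_ST from allele counts
    from .diversity import allele_counts_from_percent
    counts = allele_counts_from_percent(freq_pct, panel).loc[non_admixed]
    known = {a.name: a.variants for a in alleles if a.composition_known
             and a.name in counts.columns}
    counts_known = counts[list(known)]
    region_map = {p: panel.region_of(p) for p in counts.index}
    amova_res = haplotype_amova(counts_known, known, regions=region_map,
                                levels=3, permutations=config.permutations,
                                seed=config.rng_seed)
    rows = [{"level": k, "sigma": amova_res.sigma[k],
             "percent": amova_res.percentages[k]} for k in amova_res.sigma]
    amova_df = pd.DataFrame(rows).set_index("level")
    for k, v in amova_res.phi.items():
        amova_df.loc[k, "sigma"] = v
    tables["amova_haplotype"] = amova_df

    region_counts = counts_known.groupby(
        pd.Series(region_map)[counts_known.index]).sum()
    model = DistanceModel.haplotype([known[a] for a in counts_known.columns])
    fst, _ = pairwise_phi_st(region_counts, model)
    tables["fst_regions"] = fst

    # loss-of-activity metric per population
    tables["loss_frequency"] = loss_frequency_per_population(
        freq_pct, classification).to_frame()

    classification_df = pd.DataFrame(
        [{"allele": c.name, "category": c.category, "mode": c.activity_mode,
          "active": c.active_for_phenotype} for c in classification.values()]
    ).set_index("allele")
    tables["allele_classification"] = classification_df
    tables["variant_classes"] = pd.Series(variant_classes, name="functional_class").to_frame()
    if config.permutations == 0:
        manifest["p_values"] = "not computed (permutations=0)"
    return ReportBundle(tables, manifest)
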