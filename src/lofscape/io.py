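"""Readers and writers for the pipeline's TSV schemas and the JSON config."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model import (AlleleDefinition, AlleleTable, AnalysisConfig,
                    GenotypePanel, PopulationPanel, VariantDef)

PathLike = Union[str, Path]


def read_population_panel(path: PathLike) -> PopulationPanel:
    return PopulationPanel(pd.read_csv(path, sep="\t"))


def write_population_panel(panel: PopulationPanel, path: PathLike) -> None:
    out = panel.table.copy()
    out["admixed"] = out["admixed"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_genotype_table(path: PathLike,
                        panel: Optional[PopulationPanel] = None) -> GenotypePanel:
    """Read a sample x variant table of alternate-copy counts (0/1/2).

    Header: ``sample_id``, ``population``, then one column per variant id.
    A count outside {0, 1, 2} (or -1 for missing) raises, naming the cell.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise ValueError(f"{path}: genotype table needs sample_id and population")
    variant_cols = [c for c in df.columns if c not in ("sample_id", "population")]
    geno = df[variant_cols].copy()
    try:
        geno = geno.astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-integer genotype count: {exc}") from exc
    geno.index = df["sample_id"]
    return GenotypePanel(df[["sample_id", "population"]], geno, panel=panel)


def write_genotype_table(panel: GenotypePanel, path: PathLike) -> None:
    out = panel.samples.copy()
    geno = panel.genotypes.reset_index(drop=True)
    out = pd.concat([out, geno], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_variant_table(path: PathLike) -> dict:
    """Variant definitions keyed by variant_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for _, row in df.iterrows():
        out[row["variant_id"]] = VariantDef(
            variant_id=row["variant_id"],
            codon=int(row["codon"]),
            ref_residue=row.get("ref_residue", ""),
            alt_residue=row.get("alt_residue", ""),
            rs_id=row.get("rs_id") or None,
            genomic_pos=int(row["genomic_pos"]) if row.get("genomic_pos") else None,
            functional_class=row.get("functional_class") or "unknown",
        )
    if len(out) != len(df):
        raise ValueError("duplicate variant ids")
    return out


def read_allele_definitions(path: PathLike) -> AlleleTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    alleles = []
    for _, row in df.iterrows():
        variants = frozenset(v for v in row["variants"].split(",") if v)
        parent = row["parent"] if row["parent"] not in ("", "-") else None
        alleles.append(AlleleDefinition(
            name=row["allele"],
            variants=variants,
            parent=parent,
            category=row["category"],
            composition_known=bool(int(row.get("composition_known", "1") or "1")),
        ))
    return AlleleTable(alleles)


def write_allele_definitions(table: AlleleTable, path: PathLike) -> None:
    rows = []
    for a in table:
        rows.append({
            "allele": a.name,
            "variants": ",".join(sorted(a.variants)),
            "parent": a.parent or "-",
            "category": a.category,
            "composition_known": int(a.composition_known),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_activity_matrix(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="allele")
    if df.isna().any().any():
        cell = df.stack(future_stack=True)
        bad = cell[cell.isna()].index[0]
        raise ValueError(f"missing activity for allele {bad[0]!r}, substrate {bad[1]!r}")
    return df.astype(float)


def read_frequency_table(path: PathLike) -> pd.DataFrame:
    """Population x allele percentages, indexed by population."""
    return pd.read_csv(path, sep="\t", index_col="population").astype(float)


def read_covariate_table(path: PathLike) -> pd.Series:
    """Two-column (population, value) table as a Series."""
    df = pd.read_csv(path, sep="\t")
    pop_col, val_col = df.columns[:2]
    return pd.Series(df[val_col].to_numpy(dtype=float),
                     index=df[pop_col], name=val_col)


def read_config(path: PathLike) -> AnalysisConfig:
    with open(path) as fh:
        return AnalysisConfig.from_dict(json.load(fh))


def write_config(config: AnalysisConfig, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_vcf_genotypes(path: PathLike, id_map: dict,
                       panel: Optional[PopulationPanel] = None,
                       sample_populations: Optional[dict] = None) -> GenotypePanel:
    """Optional VCF reader mapping records to variant ids.

    ``id_map`` maps (CHROM, POS, REF, ALT) tuples to variant ids; records not
    in the map are ignored.  Requires cyvcf2.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict = {}
    for rec in vcf:
        for alt in rec.ALT:
            vid = id_map.get((rec.CHROM, rec.POS, rec.REF, alt))
            if vid is None:
                continue
            counts = []
            for g in rec.genotypes:
                a = [x for x in g[:-1] if x != -1]
                counts.append(sum(1 for x in a if x > 0) if a else -1)
            columns[vid] = counts
    geno = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    pops = [(sample_populations or {}).get(s, "unknown") for s in samples]
    sample_df = pd.DataFrame({"sample_id": samples, "population": pops})
    return GenotypePanel(sample_df, geno, panel=panel)
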