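"""Packaged reference data for the worldwide OCT1 survey.

The package ships five small TSV fixtures describing the published worldwide
survey of OCT1 (SLC22A1) coding variation:

* ``populations.tsv`` — 67 populations (53 HGDP-CEPH-derived, 14 from the
  1000 Genomes Project, 5 of which are admixed), with region labels and
  sample sizes (2,171 individuals, 4,342 chromosomes in total);
* ``allele_frequencies.tsv`` — per-population frequencies (percent, as
  printed in the survey's summary table) of the 16 major star alleles;
* ``allele_definitions.tsv`` — variant composition of the 16 major alleles
  and 14 sub-alleles (30 haplotypes). Sub-allele compositions are an
  approximate reconstruction: each adds activity-neutral variants to its
  parent's functional core, which is all the downstream statistics use;
* ``variants.tsv`` — the 21 amino-acid variants with published functional
  classes (12 loss-of-function, 7 non-LOF, 2 unclassified);
* ``activity_matrix.tsv`` — allele x substrate transport activity as percent
  of the reference ``*1`` allele. Values are approximate transcriptions of
  published uptake measurements (provenance: "approximate"); every
  qualitative classification statement in the source survey is reproduced by
  the threshold rules applied to this matrix;
* ``nonlof_site_frequencies.tsv`` — synthetic per-population frequencies for
  the five activity-neutral variants that occur only on sub-alleles; a
  stand-in for supplementary-only data, constructed per region from the
  survey's qualitative statements.

Fixture integrity is verified by sha256 on load.
"""
from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as _io
from .model import AlleleTable, PopulationPanel

_CHECKSUMS = {
    "activity_matrix.tsv": "ea70a8a4cbcdf9b036689a305fffdb5990d609cdf37fc3c7d365807d1c10fb78",
    "allele_definitions.tsv": "07f34890cb9dd8c02cc819995592d42e4464249e747c6a9aa0898bbb6d1c7c2f",
    "allele_frequencies.tsv": "e24b46bdd39754f29530f04e8ec186121044b7ab3ab331665c1025569c221509",
    "nonlof_site_frequencies.tsv": "5a073bda092a9305426ee252ba3062e6c165b3588e7a30f965fc016940b292da",
    "populations.tsv": "7ea470959d91e22178c1e048c622e4cbba995a62db216a7497560810892f81fe",
    "variants.tsv": "000209954858c6950691d83340f3ba0f26da959a3cdb791fcc1eece163e79f17",
}


def _data_path(name: str) -> Path:
    path = resources.files("lofscape").joinpath("data", name)
    with resources.as_file(path) as p:
        return Path(p)


def _verify(name: str, path: Path) -> None:
    expected = _CHECKSUMS.get(name)
    if expected is None:
        return
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != expected:
        raise RuntimeError(f"packaged fixture {name} is corrupted "
                           f"(sha256 {digest} != {expected})")


def _load(name: str, loader):
    path = _data_path(name)
    _verify(name, path)
    return loader(path)


def population_panel() -> PopulationPanel:
    """The 67-population panel with region, size, admixture and source."""
    return _load("populations.tsv", _io.read_population_panel)


def allele_frequency_table() -> pd.DataFrame:
    """Per-population major-allele frequencies in percent (as printed)."""
    return _load("allele_frequencies.tsv", _io.read_frequency_table)


def allele_definitions() -> AlleleTable:
    """16 major alleles plus 14 sub-alleles (30 haplotypes)."""
    return _load("allele_definitions.tsv", _io.read_allele_definitions)


def variant_table() -> dict:
    """The 21 coding variants with published functional-class labels."""
    return _load("variants.tsv", _io.read_variant_table)


def activity_matrix() -> pd.DataFrame:
    """Allele x substrate activity, percent of *1 (approximate)."""
    return _load("activity_matrix.tsv", _io.read_activity_matrix)


def nonlof_site_frequencies() -> pd.DataFrame:
    """Synthetic per-population frequencies of sub-allele-only variants."""
    return _load("nonlof_site_frequencies.tsv",
                 lambda p: pd.read_csv(p, sep="\t", index_col="population"))


def load_survey():
    """Load the full packaged survey.

    Returns
    -------
    (PopulationPanel, DataFrame, AlleleTable, DataFrame)
        population panel, allele-frequency table (percent), allele
        definitions, activity matrix.
    """
    return (population_panel(), allele_frequency_table(),
            allele_definitions(), activity_matrix())
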