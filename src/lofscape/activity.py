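"""Star-allele naming, activity classification and phenotype scoring.

Classification applies threshold rules to an allele x substrate activity
matrix expressed as percent of the reference allele ``*1``:

* an allele is *major* when at least one substrate activity is below 50 % or
  above 150 % of reference (strict), otherwise it is a *sub* allele of the
  reference background;
* *gain* of function: some activity above 150 % and none below 50 %;
* substrate-wide *complete* loss: all activities at or below a small floor
  (default 5 %, absorbing assay noise);
* substrate-*specific* loss: some activity below 50 % while another substrate
  retains more than 90 %;
* substrate-wide *partial* loss otherwise;
* an allele is inactive for the 0/1/2-active phenotype when some substrate
  activity falls below 35 % of reference (a "more than 65 % reduction"),
  unless it belongs to the configured fully-active set.

Sub-alleles inherit the activity mode of their parent major allele.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .model import AlleleTable, AnalysisConfig

ACTIVITY_MODES = ("normal", "gain", "loss_substrate_wide_complete",
                  "loss_substrate_wide_partial", "loss_substrate_specific")


@dataclass(frozen=True)
class AlleleClass:
    name: str
    category: str            # reference | major | sub
    activity_mode: str       # one of ACTIVITY_MODES
    active_for_phenotype: bool


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    population: str
    allele_pair: Tuple[str, str]
    n_active: int
    flagged: bool = False


def name_haplotype(variants: Iterable[str], alleles: AlleleTable):
    """Name a haplotype (set of variant ids) as a star allele.

    Exact match on the variant set.  Unmatched sets are reported as
    ``("novel", nearest)`` where *nearest* is the known allele with minimum
    symmetric set difference (ties broken by allele order in the table).
    """
    hap = frozenset(variants)
    hit = alleles.lookup_variants(hap)
    if hit is not None:
        return hit
    best, best_d = None, None
    for a in alleles:
        if not a.composition_known:
            continue
        d = len(hap ^ a.variants)
        if best_d is None or d < best_d:
            best, best_d = a.name, d
    return ("novel", best)


def classify_alleles(matrix: pd.DataFrame, alleles: Optional[AlleleTable] = None,
                     config: Optional[AnalysisConfig] = None) -> Dict[str, AlleleClass]:
    """Classify every allele in the activity matrix (plus sub-alleles).

    The reference row ``*1`` must be present and identically 100.  Sub-alleles
    known from ``alleles`` inherit their parent's activity mode even when the
    matrix carries a row for them (their own row determines nothing beyond a
    consistency check performed by the caller's tests).
    """
    config = config or AnalysisConfig()
    if "*1" not in matrix.index:
        raise ValueError("activity matrix lacks the reference allele *1")
    if not np.allclose(matrix.loc["*1"].to_numpy(dtype=float), 100.0):
        raise ValueError("reference *1 activity must be 100 for every substrate")
    if matrix.isna().any().any():
        cell = matrix.stack(future_stack=True)
        bad = cell[cell.isna()].index[0]
        raise ValueError(f"missing activity for allele {bad[0]!r} / substrate {bad[1]!r}")

    lo, hi = config.major_threshold, config.gain_threshold
    out: Dict[str, AlleleClass] = {}

    def mode_of(values: np.ndarray) -> Tuple[str, str]:
        below = values < lo
        above = values > hi
        if not below.any() and not above.any():
            return ("sub", "normal")
        if above.any() and not below.any():
            return ("major", "gain")
        if (values <= config.complete_loss_floor).all():
            return ("major", "loss_substrate_wide_complete")
        if below.any() and (values > config.retained_threshold).any():
            return ("major", "loss_substrate_specific")
        return ("major", "loss_substrate_wide_partial")

    active_set = set(config.active_allele_set)
    parent_of: Dict[str, Optional[str]] = {}
    category_of: Dict[str, str] = {}
    if alleles is not None:
        for a in alleles:
            parent_of[a.name] = a.parent
            category_of[a.name] = a.category

    # majors (and unknown-parent rows) first
    for name in matrix.index:
        if parent_of.get(name):
            continue
        values = matrix.loc[name].to_numpy(dtype=float)
        if name == "*1":
            out[name] = AlleleClass(name, "reference", "normal", True)
            continue
        derived_cat, mode = mode_of(values)
        cat = category_of.get(name, derived_cat)
        if cat == "reference":
            cat = derived_cat
        active = name in active_set or not (values < config.inactive_threshold).any()
        out[name] = AlleleClass(name, cat, mode, active)

    # sub-alleles inherit from their parent
    if alleles is not None:
        for a in alleles:
            if a.parent is None or a.name in out:
                continue
            parent = out.get(a.parent)
            if parent is None:
                continue
            out[a.name] = AlleleClass(a.name, "sub", parent.activity_mode,
                                      parent.active_for_phenotype)
    # matrix rows that are subs of classified parents but were skipped above
    for name in matrix.index:
        if name in out and parent_of.get(name):
            parent = out.get(parent_of[name])
            if parent is not None:
                out[name] = AlleleClass(name, "sub", parent.activity_mode,
                                        parent.active_for_phenotype)
    return out


def derived_active_set(classification: Mapping[str, AlleleClass]) -> set:
    """Alleles with no substrate activity below the inactivity threshold."""
    return {name for name, c in classification.items() if c.active_for_phenotype}


def classify_variants(matrix: pd.DataFrame, alleles: AlleleTable,
                      overrides: Optional[Mapping[str, str]] = None,
                      config: Optional[AnalysisConfig] = None) -> Dict[str, str]:
    """Assign LOF / non_LOF to each variant from single-variant alleles.

    A variant is LOF when the single-variant allele carrying it shows a more
    than 50 % reduction for at least one substrate.  Variants never observed
    alone (they ride in combination with another variant) need an entry in
    ``overrides``; without one they raise.
    """
    config = config or AnalysisConfig()
    if matrix.empty or len(matrix.index) == 0:
        raise ValueError("empty activity matrix")
    overrides = dict(overrides or {})
    single: Dict[str, str] = {}
    for a in alleles:
        if a.composition_known and len(a.variants) == 1:
            (v,) = a.variants
            single.setdefault(v, a.name)
    out: Dict[str, str] = {}
    unattributable = []
    for v in sorted(set(alleles.variant_ids())):
        if v in overrides:
            out[v] = overrides[v]
            continue
        carrier = single.get(v)
        if carrier is None or carrier not in matrix.index:
            unattributable.append(v)
            continue
        values = matrix.loc[carrier].to_numpy(dtype=float)
        out[v] = "LOF" if (values < config.major_threshold).any() else "non_LOF"
    if unattributable:
        raise ValueError(
            "variants not attributable to a single-variant allele and lacking "
            f"overrides: {unattributable}")
    return out


def score_phenotypes(diplotypes: Mapping[str, Tuple[str, str]],
                     populations: Mapping[str, str],
                     classification: Mapping[str, AlleleClass],
                     novel_active: bool = False):
    """Count active alleles (0/1/2) per individual and tabulate per population.

    ``diplotypes`` maps sample_id -> (allele, allele); names not present in
    the classification (novel haplotypes) are scored inactive by default and
    the call is flagged.

    Returns (calls, distribution) where distribution is a population x
    {n2, n1, n0} count table.
    """
    calls = []
    for sample_id, pair in diplotypes.items():
        flagged = False
        n_active = 0
        for name in pair:
            cls = classification.get(name)
            if cls is None:
                flagged = True
                n_active += int(novel_active)
            else:
                n_active += int(cls.active_for_phenotype)
        calls.append(PhenotypeCall(sample_id, populations[sample_id],
                                   tuple(pair), n_active, flagged))
    rows = {}
    for call in calls:
        rec = rows.setdefault(call.population, {"n2": 0, "n1": 0, "n0": 0})
        rec[f"n{call.n_active}"] += 1
    dist = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    dist.index.name = "population"
    return calls, dist
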