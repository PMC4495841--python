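import numpy as np
import pandas as pd
import pytest

from lofscape import datasets
from lofscape.model import AlleleTable, GenotypePanel, PopulationPanel


@pytest.fixture(scope="session")
def survey():
    panel, freq, alleles, act = datasets.load_survey()
    return {"panel": panel, "freq": freq, "alleles": alleles, "activity": act}


@pytest.fixture(scope="session")
def variant_classes():
    return {v.variant_id: v.functional_class
            for v in datasets.variant_table().values()}


@pytest.fixture
def tiny_panel():
    """Two populations, three variant sites, hand-written genotypes."""
    meta = PopulationPanel(pd.DataFrame({
        "population": ["A", "B"],
        "region": ["R1", "R2"],
        "n_individuals": [3, 2],
        "admixed": [False, False],
        "source": ["test", "test"],
    }))
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(5)],
        "population": ["A", "A", "A", "B", "B"],
    })
    geno = pd.DataFrame(
        [[0, 0, 0],
         [1, 0, 0],
         [2, 0, 0],
         [1, 1, 0],
         [0, 0, 2]],
        index=samples["sample_id"], columns=["v1", "v2", "v3"])
    return GenotypePanel(samples, geno, panel=meta)


def hwe_likelihood(freqs, sample_pair_lists):
    """Multinomial-HWE likelihood of genotype data given haplotype freqs.

    ``sample_pair_lists``: per sample, the list of compatible unordered
    haplotype pairs (indices into ``freqs``).  Independent oracle used by
    the EM tests.
    """
    ll = 0.0
    for pairs in sample_pair_lists:
        p = 0.0
        for i, j in pairs:
            w = 1.0 if i == j else 2.0
            p += w * freqs[i] * freqs[j]
        if p <= 0:
            return -np.inf
        ll += np.log(p)
    return ll
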