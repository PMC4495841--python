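import itertools

import numpy as np
import pandas as pd
import pytest

from lofscape import datasets
from lofscape.coalescent import (expected_total_branch_length, sample_tree,
                                 simulate_site_counts)
from lofscape.diversity import (SiteFrequencyStratum, harmonic_a1,
                                nucleotide_diversity, pooled_variant_maf,
                                region_frequency_summary, region_site_counts,
                                stratified_table, tajimas_d,
                                tajimas_d_from_counts, watterson_theta)
from lofscape.model import AnalysisConfig


def brute_force_pi(haplotypes, L):
    """Mean pairwise Hamming difference per site over all C(n,2) pairs."""
    n = len(haplotypes)
    total = sum(np.sum(a != b) for a, b in itertools.combinations(haplotypes, 2))
    return total / (n * (n - 1) / 2) / L


class TestPi:
    def test_monomorphic_is_zero(self):
        st = SiteFrequencyStratum("r", "all", n=10, counts=[])
        assert nucleotide_diversity(st, 1000) == 0.0

    def test_two_haplotypes_one_difference(self):
        st = SiteFrequencyStratum("r", "all", n=2, counts=[1])
        assert nucleotide_diversity(st, 1000) == pytest.approx(1.0e-3)

    def test_needs_two_chromosomes(self):
        with pytest.raises(ValueError):
            nucleotide_diversity(SiteFrequencyStratum("r", "all", n=1, counts=[]), 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_bruteforce_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        sites = int(rng.integers(1, 8))
        haps = rng.integers(0, 2, size=(n, sites))
        counts = haps.sum(axis=0)
        st = SiteFrequencyStratum("r", "all", n=n, counts=list(counts))
        L = 500
        assert nucleotide_diversity(st, L) == pytest.approx(
            brute_force_pi(haps, L), rel=1e-12)

    def test_invariant_to_site_order(self):
        counts = [3, 7, 1]
        a = SiteFrequencyStratum("r", "all", 20, counts)
        b = SiteFrequencyStratum("r", "all", 20, counts[::-1])
        assert nucleotide_diversity(a, 100) == nucleotide_diversity(b, 100)


class TestTheta:
    def test_zero_sites(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_forced_small_case(self):
        assert watterson_theta(1, 2, 1000) == pytest.approx(1.0e-3)

    def test_harmonic_oracle(self):
        # n=10, S=3, L=1662: direct harmonic evaluation
        a1 = sum(1.0 / i for i in range(1, 10))
        assert watterson_theta(3, 10, 1662) == pytest.approx(3 / (a1 * 1662))
        assert harmonic_a1(10) == pytest.approx(a1)

    def test_needs_two_chromosomes(self):
        with pytest.raises(ValueError):
            watterson_theta(1, 1, 100)


class TestTajimasD:
    def test_hand_value_n4_singleton(self):
        # n=4, one singleton: a1=11/6, b1=5/9, b2=23/54 -> D ~= -0.6124
        d = tajimas_d_from_counts([1], 4)
        assert d == pytest.approx(-0.6124, abs=5e-4)

    def test_invariant_to_L(self):
        # D never references L; pi/theta at two L values give the same D
        st = SiteFrequencyStratum("r", "all", 30, [2, 5, 9])
        d1, _ = tajimas_d(st)
        pi_a = nucleotide_diversity(st, 1000)
        pi_b = nucleotide_diversity(st, 2000)
        th_a = watterson_theta(st.S, st.n, 1000)
        th_b = watterson_theta(st.S, st.n, 2000)
        assert (pi_a - th_a) * 2000 == pytest.approx((pi_b - th_b) * 2000 * 2, rel=1e-9)
        assert d1 == pytest.approx(tajimas_d_from_counts(st.counts, st.n))

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError):
            tajimas_d_from_counts([1], 3)
        with pytest.raises(ValueError):
            tajimas_d_from_counts([], 10)
        st = SiteFrequencyStratum("r", "all", 10, [])
        assert tajimas_d(st) == (None, None)

    def test_neutral_null_centred(self):
        """Mean D over neutral replicates (theta=5, n=100) is near zero and
        the 1st-99th percentile range brackets zero."""
        rng = np.random.default_rng(11)
        n, theta = 100, 5.0
        ds = []
        for _ in range(1000):
            sizes, lengths = sample_tree(n, rng)
            s = rng.poisson(theta / 2.0 * lengths.sum())
            if s == 0:
                continue
            idx = rng.choice(len(sizes), size=s, p=lengths / lengths.sum())
            ds.append(tajimas_d_from_counts(sizes[idx], n))
        ds = np.array(ds)
        assert -0.25 < ds.mean() < 0.1
        assert np.quantile(ds, 0.01) < 0 < np.quantile(ds, 0.99)


class TestCoalescentNull:
    def test_expected_total_length(self):
        rng = np.random.default_rng(5)
        sims = [sample_tree(40, rng)[1].sum() for _ in range(2000)]
        assert np.mean(sims) == pytest.approx(expected_total_branch_length(40),
                                              rel=0.05)

    def test_site_count_spectrum(self):
        """With Poisson(theta L/2) mutations per tree the aggregate frequency
        spectrum is exactly proportional to 1/i (E[xi_i] = theta/i)."""
        rng = np.random.default_rng(6)
        n, theta = 12, 2.0
        sfs = np.zeros(n)
        reps = 4000
        for _ in range(reps):
            sizes, lengths = sample_tree(n, rng)
            s = rng.poisson(theta / 2.0 * lengths.sum())
            if s:
                idx = rng.choice(len(sizes), size=s, p=lengths / lengths.sum())
                np.add.at(sfs, sizes[idx], 1)
        sfs /= reps
        assert sfs[1] == pytest.approx(theta / 1, rel=0.05)
        assert sfs[2] == pytest.approx(theta / 2, rel=0.08)
        assert sfs[5] == pytest.approx(theta / 5, rel=0.15)

    def test_against_msprime_oracle(self):
        """Distribution of D under the fixed-S null agrees with an msprime
        genealogy simulation at matched n and S."""
        msprime = pytest.importorskip("msprime")
        n, S, reps = 25, 6, 800
        rng = np.random.default_rng(7)
        ours = [tajimas_d_from_counts(simulate_site_counts(n, S, rng), n)
                for _ in range(reps)]
        other = []
        for ts in msprime.sim_ancestry(samples=n, ploidy=1, num_replicates=reps,
                                       random_seed=8):
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            lengths = np.array([tree.branch_length(u) for u in nodes])
            sizes = np.array([tree.num_samples(u) for u in nodes])
            idx = rng.choice(len(nodes), size=S, p=lengths / lengths.sum())
            other.append(tajimas_d_from_counts(sizes[idx], n))
        from scipy.stats import ks_2samp
        assert ks_2samp(ours, other).pvalue > 0.01


class TestFrequencyTables:
    def test_region_unweighted_means_match_printed(self, survey):
        summary = region_frequency_summary(survey["freq"], survey["panel"])
        assert summary.loc["East Asia and Oceania", "*1"] == pytest.approx(97.8, abs=0.05)
        assert summary.loc["America", "*2"] == pytest.approx(49.7, abs=0.05)
        assert summary.loc["Worldwide", "*2"] == pytest.approx(12.2, abs=0.1)

    def test_single_population_region_mean(self, survey):
        panel = survey["panel"]
        sub = panel.table[panel.table["population"].isin(["Surui"])]
        from lofscape.model import PopulationPanel
        one = PopulationPanel(sub)
        out = region_frequency_summary(survey["freq"].loc[["Surui"]], one)
        assert out.loc["America", "*2"] == survey["freq"].loc["Surui", "*2"]

    def test_pooled_variant_mafs(self, survey):
        panel, freq, alleles = survey["panel"], survey["freq"], survey["alleles"]
        hgdp = list(panel.table.loc[panel.table["source"] == "HGDP", "population"])
        assert sum(panel.n_chromosomes(p) for p in hgdp) == 2158
        m420 = pooled_variant_maf("Met420del", freq, panel, alleles, hgdp)
        r61 = pooled_variant_maf("Arg61Cys", freq, panel, alleles, hgdp)
        assert m420 == pytest.approx(14.1, abs=0.3)
        assert r61 == pytest.approx(3.2, abs=0.3)
        assert pooled_variant_maf("Glu284Lys", freq, panel, alleles,
                                  ["Surui"]) == 0.0
        with pytest.raises(KeyError):
            pooled_variant_maf("NotAVariant", freq, panel, alleles, hgdp)


class TestStratifiedTable:
    def test_identical_site_sets_give_ratio_one(self):
        strata = {"R": {
            "all": SiteFrequencyStratum("R", "all", 50, [5, 9]),
            "LOF": SiteFrequencyStratum("R", "LOF", 50, [5, 9]),
            "non_LOF": SiteFrequencyStratum("R", "non_LOF", 50, [5, 9])}}
        t = stratified_table(strata)
        assert t.loc["R", "pi_ratio_LOF_nonLOF"] == pytest.approx(1.0)

    def test_no_lof_sites_gives_zero_ratio(self):
        strata = {"R": {
            "all": SiteFrequencyStratum("R", "all", 50, [5]),
            "LOF": SiteFrequencyStratum("R", "LOF", 50, []),
            "non_LOF": SiteFrequencyStratum("R", "non_LOF", 50, [5])}}
        t = stratified_table(strata)
        assert t.loc["R", "pi_LOF"] == 0.0
        assert t.loc["R", "pi_ratio_LOF_nonLOF"] == 0.0
        assert np.isnan(t.loc["R", "D_LOF"])

    def test_fixture_reconstruction_regions(self, survey, variant_classes):
        strata = region_site_counts(survey["freq"], survey["panel"],
                                    survey["alleles"], variant_classes,
                                    datasets.nonlof_site_frequencies())
        assert set(strata) == {"Sub-Saharan Africa", "North Africa and Middle East",
                               "Europe", "Central Asia", "East Asia and Oceania",
                               "America"}
        eao = strata["East Asia and Oceania"]
        assert eao["all"].n == 1052
        assert strata["America"]["LOF"].S == 1  # only the codon-420 deletion
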