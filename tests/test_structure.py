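import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from lofscape.structure import (AmovaResult, DistanceModel, amova,
                                haplotype_amova, pairwise_phi_st,
                                phenotype_amova)


def expand(counts_row, d2):
    """Observation-level squared distance matrix for one group (oracle)."""
    types = np.repeat(np.arange(len(counts_row)), counts_row)
    return d2[np.ix_(types, types)], types


def brute_force_components(counts, region_idx, d2):
    """Direct SSD evaluation from the full observation-level distance matrix,
    followed by the textbook unequal-size expectations (independent oracle)."""
    all_types = np.concatenate([np.repeat(np.arange(counts.shape[1]), row)
                                for row in counts])
    pop_of = np.concatenate([np.full(row.sum(), p)
                             for p, row in enumerate(counts)])
    D = d2[np.ix_(all_types, all_types)]
    N = len(all_types)
    P = counts.shape[0]
    G = region_idx.max() + 1
    reg_of = region_idx[pop_of]

    def ssd(mask):
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return 0.0
        return D[np.ix_(idx, idx)].sum() / (2 * len(idx))

    ssd_tot = ssd(np.ones(N, bool))
    ssd_wp = sum(ssd(pop_of == p) for p in range(P))
    ssd_wg = sum(ssd(reg_of == g) for g in range(G))
    ms_wp = ssd_wp / (N - P)
    ms_ap = (ssd_wg - ssd_wp) / (P - G)
    ms_ag = (ssd_tot - ssd_wg) / (G - 1)
    n_p = counts.sum(axis=1).astype(float)
    n_g = np.array([n_p[region_idx == g].sum() for g in range(G)])
    sum_np2_over_ng = sum((n_p[region_idx == g] ** 2).sum() / n_g[g]
                          for g in range(G))
    n1 = (N - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - (n_p ** 2).sum() / N) / (G - 1)
    n3 = (N - (n_g ** 2).sum() / N) / (G - 1)
    sc = ms_wp
    sb = (ms_ap - sc) / n1
    sa = (ms_ag - sc - n2 * sb) / n3
    return sa, sb, sc, ssd_tot


def test_identical_populations_no_structure():
    counts = pd.DataFrame([[10, 10], [10, 10], [10, 10]],
                          index=list("abc"), columns=["h0", "h1"])
    model = DistanceModel.haplotype([frozenset(), frozenset({"x"})])
    res = amova(counts, model, levels=2)
    assert res.percentages["among"] == pytest.approx(0.0, abs=1e-9) or res.truncated
    assert res.phi["phi_st"] <= 0.01


def test_fixed_divergent_populations_phi_one():
    counts = pd.DataFrame([[20, 0], [0, 20]], index=["a", "b"],
                          columns=["h0", "h1"])
    model = DistanceModel.haplotype([frozenset(), frozenset({"x"})])
    res = amova(counts, model, levels=2)
    assert res.phi["phi_st"] == pytest.approx(1.0)


def test_all_identical_observations_flagged_undefined():
    counts = pd.DataFrame([[15, 0], [12, 0]], index=["a", "b"],
                          columns=["h0", "h1"])
    model = DistanceModel.haplotype([frozenset(), frozenset({"x"})])
    res = amova(counts, model, levels=2)
    assert res.undefined


@pytest.mark.parametrize("seed", range(6))
def test_three_population_toys_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    T = 4
    counts = pd.DataFrame(rng.integers(1, 12, size=(3, T)),
                          index=["p0", "p1", "p2"],
                          columns=[f"h{t}" for t in range(T)])
    haps = [frozenset(), frozenset("a"), frozenset("ab"), frozenset("abc")]
    model = DistanceModel.haplotype(haps)
    regions = {"p0": "r0", "p1": "r0", "p2": "r1"}
    res = amova(counts, model, regions=regions, levels=3)
    sa, sb, sc, _ = brute_force_components(
        counts.to_numpy(), np.array([0, 0, 1]), model.d2)
    assert res.sigma["among_regions"] == pytest.approx(sa, rel=1e-9, abs=1e-12)
    assert res.sigma["among_populations"] == pytest.approx(sb, rel=1e-9, abs=1e-12)
    assert res.sigma["within"] == pytest.approx(sc, rel=1e-9, abs=1e-12)


def test_total_variance_identity():
    """SSD_total equals the mean squared pairwise distance identity."""
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(rng.integers(0, 9, size=(4, 3)) + 1,
                          index=list("abcd"), columns=["x", "y", "z"])
    d2 = np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], dtype=float)
    model = DistanceModel("custom", ["x", "y", "z"], d2)
    total = counts.to_numpy().sum(axis=0)
    N = total.sum()
    ssd_tot = float(total @ d2 @ total) / (2 * N)
    _, _, _, oracle = brute_force_components(
        counts.to_numpy(), np.array([0, 0, 1, 1]), d2)
    assert ssd_tot == pytest.approx(oracle, rel=1e-12)


def test_percentages_stable_under_duplication():
    """Duplicating every chromosome leaves the decomposition essentially
    unchanged (exact only asymptotically: degrees of freedom shift)."""
    base = np.array([[80, 20, 10], [10, 90, 30], [40, 40, 40]])
    counts = pd.DataFrame(base, index=list("abc"), columns=["x", "y", "z"])
    haps = [frozenset(), frozenset("a"), frozenset("b")]
    model = DistanceModel.haplotype(haps)
    regions = {"a": "r0", "b": "r0", "c": "r1"}
    res1 = amova(counts, model, regions=regions, levels=3)
    res2 = amova(counts * 2, model, regions=regions, levels=3)
    for k in res1.percentages:
        assert res1.percentages[k] == pytest.approx(res2.percentages[k], abs=1.0)


def test_percentages_sum_to_100():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(1, 20, size=(5, 3)),
                          index=list("abcde"), columns=["x", "y", "z"])
    model = DistanceModel.haplotype([frozenset(), frozenset("a"), frozenset("ab")])
    regions = dict(zip("abcde", ["r0", "r0", "r1", "r1", "r1"]))
    res = amova(counts, model, regions=regions, levels=3,
                permutations=50, seed=0)
    assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)
    assert set(res.p_values) == {"phi_st", "phi_sc", "phi_ct"}
    assert all(0 < p <= 1 for p in res.p_values.values())


def test_permutation_p_uniform_under_null():
    """Permutation p-values on exchangeable (null) data are ~Uniform(0,1)."""
    rng = np.random.default_rng(9)
    haps = [frozenset(), frozenset("a"), frozenset("ab"), frozenset("c")]
    model = DistanceModel.haplotype(haps)
    sizes = [20, 30, 50]
    base_freq = np.array([0.4, 0.3, 0.2, 0.1])
    pvals = []
    for _ in range(400):
        flat = rng.choice(4, size=sum(sizes), p=base_freq)
        rows, i = [], 0
        for s in sizes:
            rows.append(np.bincount(flat[i:i + s], minlength=4))
            i += s
        counts = pd.DataFrame(rows, index=list("abc"), columns=list("wxyz"))
        res = amova(counts, model, levels=2, permutations=99,
                    seed=int(rng.integers(2 ** 31)))
        if not res.undefined:
            pvals.append(res.p_values["phi_st"])
    pvals = np.array(pvals)
    # validity: no excess of small p-values at any conventional level
    for alpha in (0.01, 0.05, 0.25):
        assert (pvals <= alpha).mean() < alpha + 3 * np.sqrt(alpha / len(pvals))
    # near-uniform overall (discrete lattice of (hits+1)/(perms+1) values)
    assert kstest(pvals, "uniform").pvalue > 1e-4


def test_phenotype_amova_extremes():
    regions = {"a": "r0", "b": "r1"}
    same = pd.DataFrame([[0, 0, 25], [0, 0, 30]], index=["a", "b"],
                        columns=[0, 1, 2])
    res = phenotype_amova(same, regions=regions, levels=3)
    assert res.undefined
    fixed = pd.DataFrame([[0, 0, 25], [30, 0, 0]], index=["a", "b"],
                         columns=[0, 1, 2])
    res = phenotype_amova(fixed, regions=regions, levels=3)
    assert res.percentages["among_regions"] == pytest.approx(100.0, abs=1e-6)


def test_pairwise_matrix_properties():
    counts = pd.DataFrame([[20, 0], [0, 20], [10, 10], [1, 0]],
                          index=list("abcd"), columns=["h0", "h1"])
    model = DistanceModel.haplotype([frozenset(), frozenset("x")])
    fst, _ = pairwise_phi_st(counts, model)
    assert "d" not in fst.index            # size-1 group excluded
    assert np.allclose(fst, fst.T)
    assert np.allclose(np.diag(fst), 0.0)
    assert fst.loc["a", "b"] == pytest.approx(1.0)
    identical = pd.DataFrame([[10, 10], [10, 10]], index=["a", "b"],
                             columns=["h0", "h1"])
    f2, _ = pairwise_phi_st(identical, model)
    assert f2.loc["a", "b"] == pytest.approx(0.0, abs=1e-9)


def test_distance_model_validation():
    with pytest.raises(ValueError):
        DistanceModel("bad", ["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceModel("bad", ["a", "b"], np.array([[1.0, 0.0], [0.0, 0.0]]))
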