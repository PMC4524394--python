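import itertools
import math

import numpy as np
import pytest

from ssrkit.amova import (
    amova_phipt,
    distance_matrix,
    genotype_distance,
    pairwise_phipt,
)
from ssrkit.simulate import GenotypeSimSpec, simulate_genotypes
from tests.conftest import make_matrix

# ---------------------------------------------------------------------------
# genotype_distance
# ---------------------------------------------------------------------------


def _d(a, b, metric="shared_allele"):
    return genotype_distance(np.array([a]), np.array([b]), metric)


def test_identical_genotypes_zero():
    G = make_matrix({"P": [[(1, 2), (3, 3)], [(1, 2), (3, 3)]]})
    assert genotype_distance(G.calls[0], G.calls[1]) == 0.0


def test_shared_allele_counting():
    assert _d((1, 1), (2, 2)) == 2  # AA vs BB
    assert _d((1, 2), (1, 1)) == 1  # AB vs AA
    assert _d((1, 2), (1, 2)) == 0  # AB vs AB
    assert _d((1, 2), (2, 3)) == 1  # one shared
    assert _d((2, 1), (1, 2)) == 0  # unordered


def test_distance_symmetric_and_skips_missing():
    a = np.array([(1, 2), (0, 0), (3, 3)])
    b = np.array([(1, 1), (5, 5), (4, 4)])
    assert genotype_distance(a, b) == genotype_distance(b, a) == 1 + 2


def test_no_cotyped_loci_is_nan():
    a = np.array([(0, 0)])
    b = np.array([(1, 1)])
    assert math.isnan(genotype_distance(a, b))


def test_clone_pairs_distance_zero():
    G, _ = simulate_genotypes(GenotypeSimSpec(clone_pairs=2, seed=31))
    D = distance_matrix(G)
    for i, name in enumerate(G.ids):
        if "_clone" in name:
            j = G.ids.index(name.rsplit("_clone", 1)[0])
            assert D[i, j] == 0.0


def test_vectorized_matrix_matches_scalar():
    G, _ = simulate_genotypes(
        GenotypeSimSpec(sizes=(6, 6), n_loci=8, missing_rate=0.1, seed=2)
    )
    D = distance_matrix(G)
    for i in range(G.n_individuals):
        for j in range(i + 1, G.n_individuals):
            assert D[i, j] == genotype_distance(G.calls[i], G.calls[j])


def test_allele_count_sq_metric():
    # twice the Smouse-Peakall genotypic distances
    assert _d((1, 1), (2, 2), "allele_count_sq") == 8.0
    assert _d((1, 2), (1, 1), "allele_count_sq") == 2.0
    assert _d((1, 1), (2, 3), "allele_count_sq") == 6.0
    assert _d((1, 2), (3, 4), "allele_count_sq") == 4.0
    assert _d((1, 2), (1, 2), "allele_count_sq") == 0.0


def test_allele_count_sq_vectorized_matches_scalar():
    G, _ = simulate_genotypes(
        GenotypeSimSpec(sizes=(5, 5), n_loci=6, missing_rate=0.1, seed=12)
    )
    D = distance_matrix(G, "allele_count_sq")
    for i in range(G.n_individuals):
        for j in range(i + 1, G.n_individuals):
            assert D[i, j] == genotype_distance(G.calls[i], G.calls[j], "allele_count_sq")


# ---------------------------------------------------------------------------
# amova_phipt
# ---------------------------------------------------------------------------

# Hand-computed 4-individual oracle (worked out before implementation):
#   groups X = {0, 1}, Y = {2, 3}
#   d2: d01 = 2, d23 = 4, all cross pairs = 10
#   SS_total = (2 + 4 + 4*10) / 4 = 11.5
#   SS_within = 2/2 + 4/2 = 3          -> SS_among = 8.5
#   Vw = 3 / (4 - 2) = 1.5
#   n0 = (4 - (4 + 4)/4) / 1 = 2
#   Va = (8.5/1 - 1.5) / 2 = 3.5
#   PhiPT = 3.5 / 5 = 0.7
HAND_D = np.array(
    [
        [0, 2, 10, 10],
        [2, 0, 10, 10],
        [10, 10, 0, 4],
        [10, 10, 4, 0],
    ],
    dtype=float,
)


def test_hand_oracle_four_individuals():
    res = amova_phipt(HAND_D, ["X", "X", "Y", "Y"], n_perm=99, seed=0)
    assert res.ss_among == pytest.approx(8.5)
    assert res.ss_within == pytest.approx(3.0)
    assert res.va == pytest.approx(3.5)
    assert res.vw == pytest.approx(1.5)
    assert res.phipt == pytest.approx(0.7)
    assert res.df_among == 1 and res.df_within == 2
    assert res.pct_among + res.pct_within == pytest.approx(100.0)


def test_fixed_difference_populations_phipt_one(two_pop_matrix):
    D = distance_matrix(two_pop_matrix)
    res = amova_phipt(D, two_pop_matrix.pops, n_perm=99, seed=1)
    assert res.ss_within == 0.0
    assert res.phipt == pytest.approx(1.0)


def test_degenerate_all_zero_distances():
    D = np.zeros((6, 6))
    res = amova_phipt(D, ["A"] * 3 + ["B"] * 3, n_perm=99, seed=0)
    assert res.phipt == 0.0 and res.p_value == 1.0


def test_scale_invariance():
    res1 = amova_phipt(HAND_D, ["X", "X", "Y", "Y"], n_perm=0)
    res2 = amova_phipt(HAND_D * 7.3, ["X", "X", "Y", "Y"], n_perm=0)
    assert res1.phipt == pytest.approx(res2.phipt)


def test_seed_reproducible_and_label_invariant():
    rng = np.random.default_rng(3)
    X = rng.random((8, 3))
    D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    groups = ["a"] * 4 + ["b"] * 4
    r1 = amova_phipt(D, groups, n_perm=199, seed=5)
    r2 = amova_phipt(D, groups, n_perm=199, seed=5)
    relabeled = ["zz" if g == "a" else "qq" for g in groups]
    r3 = amova_phipt(D, relabeled, n_perm=199, seed=5)
    assert r1.p_value == r2.p_value == r3.p_value
    assert r1.phipt == pytest.approx(r3.phipt)


def brute_exact_p(D, groups):
    """Enumerate every split of individuals into groups of the given sizes."""
    groups = np.asarray(groups)
    n = len(groups)
    labels, counts = np.unique(groups, return_counts=True)

    def phi(assign):
        res = amova_phipt(D, assign, n_perm=0)
        return res.phipt

    obs = phi(groups)
    all_assignments = set(itertools.permutations(groups))
    phis = [phi(np.array(a)) for a in all_assignments]
    return sum(p >= obs - 1e-12 for p in phis) / len(phis)


def test_exact_permutation_equivalence_small_n():
    rng = np.random.default_rng(7)
    X = rng.random((8, 2))
    D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    groups = ["a"] * 4 + ["b"] * 4
    res = amova_phipt(D, groups, exact=True)
    assert res.p_value == pytest.approx(brute_exact_p(D, groups))
    # and on the hand-built matrix with its strong structure
    res2 = amova_phipt(HAND_D, ["X", "X", "Y", "Y"], exact=True)
    assert res2.p_value == pytest.approx(brute_exact_p(HAND_D, ["X", "X", "Y", "Y"]))


def test_validation_errors():
    with pytest.raises(ValueError):
        amova_phipt(HAND_D, ["X"] * 4, n_perm=10)
    with pytest.raises(ValueError):
        amova_phipt(HAND_D, ["X", "Y", "Y", "Y"], n_perm=10)


# ---------------------------------------------------------------------------
# null calibration / parameter recovery
# ---------------------------------------------------------------------------


def test_null_phipt_near_zero():
    spec = GenotypeSimSpec(
        n_populations=2, sizes=(40, 40), n_loci=20, differentiation=0.0, seed=101
    )
    G, _ = simulate_genotypes(spec)
    D = distance_matrix(G)
    res = amova_phipt(D, G.pops, n_perm=199, seed=1)
    assert abs(res.phipt) < 0.05


def wc_theta_oracle(pop_freqs: dict[str, np.ndarray]) -> float:
    """Weir-Cockerham-style theta from the generator's truth frequencies:
    ratio of summed among-population allele-frequency variance to summed
    total variance p(1-p) (no sampling correction needed — frequencies
    are exact)."""
    arr = np.stack(list(pop_freqs.values()))  # (r, L, A)
    r = arr.shape[0]
    s2 = arr.var(axis=0, ddof=1)
    pbar = arr.mean(axis=0)
    num = float(s2.sum())
    den = float((pbar * (1 - pbar) + s2 * (r - 1) / r).sum())
    return num / den


def test_phipt_tracks_truth_theta():
    # One-level AMOVA on diploid genotypic distances measures differentiation
    # on the genotype scale: under Hardy-Weinberg its expectation is
    # 2*theta / (1 + theta), not theta itself (within-individual variance is
    # part of the within-group stratum).  The oracle maps theta accordingly.
    phis, oracles = [], []
    for rep in range(20):
        spec = GenotypeSimSpec(
            n_populations=2, sizes=(50, 50), n_loci=50, alleles_per_locus=5,
            differentiation=0.25, seed=500 + rep,
        )
        G, truth = simulate_genotypes(spec)
        D = distance_matrix(G, metric="allele_count_sq")
        phis.append(amova_phipt(D, G.pops, n_perm=0).phipt)
        theta = wc_theta_oracle(truth["pop_freqs"])
        oracles.append(2 * theta / (1 + theta))
    assert abs(np.mean(phis) - np.mean(oracles)) < 0.05


# ---------------------------------------------------------------------------
# pairwise_phipt
# ---------------------------------------------------------------------------


def test_duplicated_population_near_zero():
    spec = GenotypeSimSpec(
        n_populations=1, sizes=(20,), n_loci=15, differentiation=0.0, seed=8
    )
    G, _ = simulate_genotypes(spec)
    pops = ["A" if i < 10 else "B" for i in range(20)]
    G2 = make_matrix(
        {
            "A": [list(map(tuple, G.calls[i])) for i in range(10)],
            "B": [list(map(tuple, G.calls[i])) for i in range(10, 20)],
        }
    )
    phi, _ = pairwise_phipt(G2, n_perm=49, seed=2)
    assert abs(phi.loc["A", "B"]) < 0.08


def test_pairwise_matches_two_group_amova(two_pop_matrix):
    phi, pval = pairwise_phipt(two_pop_matrix, n_perm=99, seed=3)
    D = distance_matrix(two_pop_matrix)
    res = amova_phipt(D, two_pop_matrix.pops, n_perm=99, seed=3)
    assert phi.loc["A", "B"] == pytest.approx(res.phipt)
    assert phi.values.diagonal().sum() == 0.0
    assert (phi.values == phi.values.T).all()


def test_ordered_divergence():
    # three populations at increasing differentiation from a common base
    base = GenotypeSimSpec(
        n_populations=2, sizes=(25, 25), n_loci=40, alleles_per_locus=4,
        differentiation=0.05, seed=61,
    )
    G_low, _ = simulate_genotypes(base)
    far = GenotypeSimSpec(
        n_populations=2, sizes=(25, 25), n_loci=40, alleles_per_locus=4,
        differentiation=0.45, seed=61,
    )
    G_far, _ = simulate_genotypes(far)
    D_low = distance_matrix(G_low)
    D_far = distance_matrix(G_far)
    phi_low = amova_phipt(D_low, G_low.pops, n_perm=0).phipt
    phi_far = amova_phipt(D_far, G_far.pops, n_perm=0).phipt
    assert phi_far > phi_low
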