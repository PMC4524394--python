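import itertools
import math
from math import comb, log

import numpy as np
import pytest

from ssrkit.diversity import (
    allele_copy_counts,
    allele_frequencies,
    frequency_classes,
    locus_diversity,
    population_summary,
    private_rarefied_richness,
    rarefied_richness,
)
from ssrkit.simulate import GenotypeSimSpec, simulate_genotypes
from tests.conftest import make_matrix

# ---------------------------------------------------------------------------
# allele_frequencies
# ---------------------------------------------------------------------------


def test_frequency_counting():
    G = make_matrix({"P": [[(1, 1)], [(1, 1)], [(1, 2)], [(2, 2)]]})
    freqs = allele_frequencies(G)
    assert freqs["L1"] == {1: 5 / 8, 2: 3 / 8}


def test_missing_reduces_denominator():
    G = make_matrix({"P": [[(1, 1)], [(1, 1)], [(1, 2)], [(0, 0)]]})
    freqs = allele_frequencies(G)
    assert freqs["L1"] == {1: 5 / 6, 2: 1 / 6}


def test_frequencies_converge_to_truth():
    spec = GenotypeSimSpec(
        n_populations=1, sizes=(400,), n_loci=5, alleles_per_locus=4,
        differentiation=0.0, seed=17,
    )
    G, truth = simulate_genotypes(spec)
    freqs = allele_frequencies(G)
    n_copies = 2 * 400
    for l, locus in enumerate(G.loci):
        for a, size in enumerate(truth["allele_sizes"][l]):
            p = truth["ancestral_freqs"][l][a]
            se = math.sqrt(p * (1 - p) / n_copies)
            assert abs(freqs[locus].get(int(size), 0.0) - p) < 3 * se + 1e-9


def test_per_population_tables():
    G = make_matrix({"A": [[(1, 1)]] * 3, "B": [[(2, 2)]] * 3})
    freqs = allele_frequencies(G, by_population=True)
    assert freqs["A"]["L1"] == {1: 1.0}
    assert freqs["B"]["L1"] == {2: 1.0}


# ---------------------------------------------------------------------------
# locus_diversity closed forms
# ---------------------------------------------------------------------------


def test_two_equal_alleles():
    G = make_matrix({"P": [[(1, 2)], [(1, 2)], [(1, 2)], [(1, 2)]]})
    (d,) = locus_diversity(G)
    assert d.he == pytest.approx(0.5)
    assert d.pic == pytest.approx(0.375)
    assert d.ne == pytest.approx(2.0)
    assert d.shannon == pytest.approx(log(2))
    assert d.ho == 1.0


def test_monomorphic_locus():
    G = make_matrix({"P": [[(5, 5)], [(5, 5)]]})
    (d,) = locus_diversity(G)
    assert (d.na, d.he, d.pic, d.shannon) == (1, 0.0, 0.0, 0.0)
    assert d.ne == pytest.approx(1.0)


def test_four_equal_alleles():
    G = make_matrix(
        {"P": [[(1, 2)], [(3, 4)], [(1, 3)], [(2, 4)]]}
    )
    (d,) = locus_diversity(G)
    assert d.he == pytest.approx(0.75)
    assert d.pic == pytest.approx(0.703125)


def test_ho_excludes_missing():
    G = make_matrix({"P": [[(1, 2)], [(1, 1)], [(0, 0)]]})
    (d,) = locus_diversity(G)
    assert d.ho == pytest.approx(0.5)
    assert d.n_typed == 2


def test_pic_le_he_over_random_vectors():
    rng = np.random.default_rng(3)
    for _ in range(10_000):
        k = int(rng.integers(2, 8))
        p = rng.dirichlet(np.ones(k))
        he = 1 - np.sum(p**2)
        pic = he - sum(
            2 * p[i] ** 2 * p[j] ** 2 for i in range(k) for j in range(i + 1, k)
        )
        assert 0.0 <= pic <= he <= 1.0


def test_ne_he_identity():
    rng = np.random.default_rng(4)
    calls = [[(int(a), int(b))] for a, b in rng.integers(1, 6, size=(30, 2))]
    G = make_matrix({"P": calls})
    (d,) = locus_diversity(G)
    assert d.ne == pytest.approx(1.0 / (1.0 - d.he), abs=1e-12)


def test_hwe_ho_matches_he_on_average():
    diffs = []
    for rep in range(50):
        spec = GenotypeSimSpec(
            n_populations=1, sizes=(60,), n_loci=10, alleles_per_locus=4,
            differentiation=0.0, seed=1000 + rep,
        )
        G, _ = simulate_genotypes(spec)
        stats = locus_diversity(G)
        diffs.append(np.mean([d.ho - d.he for d in stats]))
    se = np.std(diffs, ddof=1) / math.sqrt(len(diffs))
    assert abs(np.mean(diffs)) < 3 * se + 0.01


# ---------------------------------------------------------------------------
# frequency_classes
# ---------------------------------------------------------------------------


def test_frequency_class_proportions():
    freqs = {"L1": {1: 0.6, 2: 0.3, 3: 0.06, 4: 0.04}}
    classes = frequency_classes(freqs)
    assert classes == {"abundant": 0.25, "intermediate": 0.5, "rare": 0.25}


def test_boundary_is_intermediate():
    freqs = {"L1": {i: 0.05 for i in range(20)}}
    classes = frequency_classes(freqs)
    assert classes["intermediate"] == 1.0


def test_classes_match_direct_recount():
    rng = np.random.default_rng(5)
    freqs = {
        f"L{l}": {i: float(p) for i, p in enumerate(rng.dirichlet(np.ones(6)))}
        for l in range(20)
    }
    classes = frequency_classes(freqs)
    allp = [p for d in freqs.values() for p in d.values()]
    assert classes["rare"] == pytest.approx(sum(p < 0.05 for p in allp) / len(allp))
    assert classes["abundant"] == pytest.approx(sum(p > 0.50 for p in allp) / len(allp))


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------


def exhaustive_ar(counts, g):
    """Average distinct-allele count over every g-subset of the gene copies."""
    copies = [a for a, c in counts.items() for _ in range(c)]
    subs = list(itertools.combinations(range(len(copies)), g))
    return sum(len({copies[i] for i in sub}) for sub in subs) / len(subs)


def test_ar_at_full_sample_is_na():
    counts = {1: 5, 2: 3, 3: 2}
    assert rarefied_richness(counts, 10) == pytest.approx(3.0)


def test_ar_at_one_copy_is_one():
    assert rarefied_richness({1: 7, 2: 4}, 1) == pytest.approx(1.0)


def test_worked_example_8_2():
    val = rarefied_richness({1: 8, 2: 2}, 2)
    assert val == pytest.approx(61 / 45)
    assert val == pytest.approx(exhaustive_ar({1: 8, 2: 2}, 2))


def test_ar_equals_exhaustive_enumeration_small_n():
    rng = np.random.default_rng(6)
    for _ in range(40):
        k = int(rng.integers(1, 5))
        counts = {}
        remaining = int(rng.integers(k, 13))
        for a in range(k):
            c = int(rng.integers(1, remaining - (k - a - 1) + 1)) if a < k - 1 else remaining
            counts[a] = c
            remaining -= c
            if remaining <= 0:
                break
        N = sum(counts.values())
        if N > 12:
            continue
        g = int(rng.integers(1, N + 1))
        assert rarefied_richness(counts, g) == pytest.approx(exhaustive_ar(counts, g))


def test_ar_nondecreasing_in_g():
    counts = {1: 6, 2: 3, 3: 2, 4: 1}
    N = sum(counts.values())
    values = [rarefied_richness(counts, g) for g in range(1, N + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


def test_g_out_of_range():
    with pytest.raises(ValueError):
        rarefied_richness({1: 3}, 4)
    with pytest.raises(ValueError):
        rarefied_richness({1: 3}, 0)


# ---------------------------------------------------------------------------
# private rarefied richness
# ---------------------------------------------------------------------------


def test_single_population_private_equals_ar():
    counts = {"only": {1: 5, 2: 3}}
    out = private_rarefied_richness(counts, 4)
    assert out["only"] == pytest.approx(rarefied_richness(counts["only"], 4))


def test_shared_fixed_allele_contributes_zero():
    counts = {"A": {1: 6}, "B": {1: 6}}
    out = private_rarefied_richness(counts, 2)
    assert out["A"] == pytest.approx(0.0)
    assert out["B"] == pytest.approx(0.0)


def test_private_rarefaction_against_monte_carlo():
    counts = {"A": {1: 4, 2: 3, 3: 1}, "B": {1: 5, 4: 3}}
    g = 2
    exact = private_rarefied_richness(counts, g)
    rng = np.random.default_rng(11)
    n_draws = 100_000
    copies = {p: [a for a, c in cc.items() for _ in range(c)] for p, cc in counts.items()}
    hits = {p: [] for p in counts}
    for _ in range(n_draws):
        sampled = {
            p: set(rng.choice(copies[p], size=g, replace=False)) for p in counts
        }
        for p in counts:
            others = set().union(*(sampled[q] for q in counts if q != p))
            hits[p].append(len(sampled[p] - others))
    for p in counts:
        mc = np.mean(hits[p])
        se = np.std(hits[p], ddof=1) / math.sqrt(n_draws)
        assert abs(exact[p] - mc) < 3 * se + 1e-6


def test_common_g_rule_error():
    counts = {"A": {1: 10}, "B": {1: 2}}
    with pytest.raises(ValueError):
        private_rarefied_richness(counts, 4)


# ---------------------------------------------------------------------------
# population_summary
# ---------------------------------------------------------------------------


def test_fixed_population_ppl_zero():
    G = make_matrix(
        {"fix": [[(1, 1), (2, 2)]] * 5, "var": [[(1, 2), (2, 3)], [(2, 2), (3, 3)], [(1, 1), (2, 3)]]}
    )
    table = population_summary(G, g=2)
    fix = table.set_index("population").loc["fix"]
    assert fix["PPL_pct"] == 0.0
    assert fix["He"] == pytest.approx(0.0)


def test_ppl_percentage_three_monomorphic_of_34():
    # 34 loci, 3 monomorphic in a 6-individual group
    rng = np.random.default_rng(19)
    rows = []
    for _ in range(6):
        calls = []
        for l in range(34):
            if l < 3:
                calls.append((100, 100))
            else:
                a, b = rng.integers(100, 104, size=2) * 2
                calls.append((int(a), int(b)))
        rows.append(calls)
    G = make_matrix({"wild": rows})
    # guarantee the 31 remaining loci really are polymorphic
    poly = sum(
        1 for l in range(34) if len(np.unique(G.calls[:, l, :])) >= 2
    )
    assert poly == 31  # construction sanity
    table = population_summary(G, g=2)
    assert table["PPL_pct"].iloc[0] == pytest.approx(100 * 31 / 34)
    assert round(table["PPL_pct"].iloc[0]) == 91


def test_private_alleles_counted():
    G = make_matrix({"A": [[(1, 2)]] * 3, "B": [[(2, 2)]] * 3})
    table = population_summary(G, g=2).set_index("population")
    assert table.loc["A", "private_Na"] == 1.0  # allele 1 only in A
    assert table.loc["B", "private_Na"] == 0.0


def test_clone_removal_recount_consistency():
    spec = GenotypeSimSpec(
        n_populations=2, sizes=(10, 10), n_loci=6, alleles_per_locus=4,
        clone_pairs=1, seed=23,
    )
    G, _ = simulate_genotypes(spec)
    clone_idx = next(i for i, x in enumerate(G.ids) if "_clone" in x)
    src_id = G.ids[clone_idx].rsplit("_clone", 1)[0]
    kept = [i for i in range(G.n_individuals) if i != clone_idx]
    G2 = G.subset_individuals(kept)
    f_with = allele_frequencies(G, by_population=True)
    f_without = allele_frequencies(G2, by_population=True)
    pop = G.pops[clone_idx]
    # frequencies change unless recomputed from the reduced copy counts;
    # the recount oracle is the copy-count table itself
    cc = allele_copy_counts(G2, by_population=True)[pop]
    for locus, freqs in f_without[pop].items():
        total = sum(cc[locus].values())
        for a, p in freqs.items():
            assert p == pytest.approx(cc[locus][a] / total)


def test_ar_bounded_by_na_and_exact_at_full_g():
    G = make_matrix({"P": [[(1, 2)], [(2, 3)], [(1, 3)]]})
    table = population_summary(G, g=6)
    assert table["Ar"].iloc[0] == pytest.approx(table["Na"].iloc[0])
    table2 = population_summary(G, g=3)
    assert table2["Ar"].iloc[0] <= table2["Na"].iloc[0]
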