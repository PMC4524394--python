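"""Per-locus and per-population diversity statistics for codominant SSRs.

Covers allele frequencies, Na/Ne/Ho/He(GD)/PIC/Shannon I, allele
frequency classes, percentage of polymorphic loci, private alleles, and
exact hypergeometric rarefaction of allelic richness (total and
private).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log, sqrt
from typing import Mapping

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "LocusDiversity",
    "allele_frequencies",
    "allele_copy_counts",
    "locus_diversity",
    "frequency_classes",
    "rarefied_richness",
    "private_rarefied_richness",
    "population_summary",
]


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    n_typed: int  # non-missing diploid calls
    na: int
    ne: float
    ho: float
    he: float
    pic: float
    shannon: float


def allele_copy_counts(
    G: GenotypeMatrix, by_population: bool = False
) -> dict:
    """Allele copy counts per locus: {locus: {allele: count}}.

    With ``by_population`` the outer key is the population:
    {pop: {locus: {allele: count}}}.  Missing calls contribute nothing.
    """

    def _counts(calls: np.ndarray) -> dict[str, dict[int, int]]:
        out: dict[str, dict[int, int]] = {}
        for l, locus in enumerate(G.loci):
            alleles = calls[:, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            vals, cnts = np.unique(alleles, return_counts=True)
            out[locus] = {int(v): int(c) for v, c in zip(vals, cnts)}
        return out

    if not by_population:
        return _counts(G.calls)
    result: dict[str, dict] = {}
    for pop in G.populations():
        idx = [i for i, p in enumerate(G.pops) if p == pop]
        result[pop] = _counts(G.calls[idx])
    return result


def allele_frequencies(
    G: GenotypeMatrix, by_population: bool = False
) -> dict:
    """Allele frequencies from non-missing gene copies (2 per call)."""

    def _freq(counts: dict[str, dict[int, int]]) -> dict[str, dict[int, float]]:
        out = {}
        for locus, cc in counts.items():
            total = sum(cc.values())
            out[locus] = (
                {a: c / total for a, c in cc.items()} if total else {}
            )
        return out

    counts = allele_copy_counts(G, by_population=by_population)
    if not by_population:
        return _freq(counts)
    return {pop: _freq(cc) for pop, cc in counts.items()}


def _stats_from_freqs(freqs: Mapping[int, float]) -> tuple[int, float, float, float, float]:
    p = np.array(list(freqs.values()), dtype=float)
    na = len(p)
    sum_p2 = float(np.sum(p**2))
    he = 1.0 - sum_p2
    ne = 1.0 / sum_p2 if sum_p2 > 0 else float("nan")
    pic = he - float(sum(2 * p[i] ** 2 * p[j] ** 2 for i in range(na) for j in range(i + 1, na)))
    shannon = float(-np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p))))
    return na, ne, he, pic, shannon


def locus_diversity(G: GenotypeMatrix) -> list[LocusDiversity]:
    """All per-locus statistics over the pooled sample.

    He is the plain gene diversity 1 - sum(p^2); Ho excludes missing
    calls from its denominator.  PIC follows Botstein:
    1 - sum(p^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    freqs = allele_frequencies(G)
    out: list[LocusDiversity] = []
    for l, locus in enumerate(G.loci):
        calls = G.calls[:, l, :]
        typed = calls[(calls != MISSING).all(axis=1)]
        n_typed = typed.shape[0]
        if n_typed == 0:
            continue
        het = int(np.sum(typed[:, 0] != typed[:, 1]))
        ho = het / n_typed
        na, ne, he, pic, shannon = _stats_from_freqs(freqs[locus])
        out.append(
            LocusDiversity(
                locus=locus, n_typed=n_typed, na=na, ne=ne, ho=ho, he=he,
                pic=pic, shannon=shannon,
            )
        )
    return out


def frequency_classes(
    freqs: Mapping[str, Mapping[int, float]],
    rare_below: float = 0.05,
    abundant_above: float = 0.50,
) -> dict[str, float]:
    """Proportions of rare / intermediate / abundant alleles.

    Rare: p < ``rare_below``; abundant: p > ``abundant_above``;
    intermediate: the closed band in between.
    """
    n_rare = n_int = n_ab = 0
    for locus_freqs in freqs.values():
        for p in locus_freqs.values():
            if p < rare_below:
                n_rare += 1
            elif p > abundant_above:
                n_ab += 1
            else:
                n_int += 1
    total = n_rare + n_int + n_ab
    if total == 0:
        return {"rare": 0.0, "intermediate": 0.0, "abundant": 0.0}
    return {
        "rare": n_rare / total,
        "intermediate": n_int / total,
        "abundant": n_ab / total,
    }


def rarefied_richness(copy_counts: Mapping[int, int], g: int) -> float:
    """Expected distinct alleles in a random subsample of g gene copies.

    Exact hypergeometric form: Ar(g) = sum_i [1 - C(N-N_i, g)/C(N, g)].
    """
    counts = [c for c in copy_counts.values() if c > 0]
    N = sum(counts)
    if not 1 <= g <= N:
        raise ValueError(f"g must be in [1, {N}], got {g}")
    denom = comb(N, g)
    return float(sum(1.0 - comb(N - ni, g) / denom for ni in counts))


def private_rarefied_richness(
    pop_copy_counts: Mapping[str, Mapping[int, int]], g: int
) -> dict[str, float]:
    """Rarefied private allelic richness per population at one locus.

    With Q_ij(g) the probability allele i shows up in a g-copy subsample
    from population j, the private richness of j is
    sum_i Q_ij(g) * prod_{k != j} (1 - Q_ik(g)).
    """
    pops = list(pop_copy_counts)
    alleles = sorted({a for cc in pop_copy_counts.values() for a in cc})
    totals = {p: sum(pop_copy_counts[p].values()) for p in pops}
    for p in pops:
        if g > totals[p]:
            raise ValueError(f"g={g} exceeds gene copies ({totals[p]}) in {p}")
    q = {
        (a, p): 1.0
        - comb(totals[p] - pop_copy_counts[p].get(a, 0), g) / comb(totals[p], g)
        for a in alleles
        for p in pops
    }
    out: dict[str, float] = {}
    for p in pops:
        total = 0.0
        for a in alleles:
            prod = 1.0
            for k in pops:
                if k != p:
                    prod *= 1.0 - q[(a, k)]
            total += q[(a, p)] * prod
        out[p] = total
    return out


def _mean_se(values: list[float]) -> tuple[float, float]:
    arr = np.array(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    se = float(arr.std(ddof=1) / sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), se


def population_summary(G: GenotypeMatrix, g: int | None = None) -> pd.DataFrame:
    """Per-population diversity table (one row per population).

    Columns: n, PPL_pct, mean Na/Ne/I/Ho/He (each with SE), private Na,
    Ar(g) and private Ar(g).  ``g`` defaults to twice the smallest
    per-population diploid sample size over loci complete in every
    population; loci where any population has fewer than g typed gene
    copies are skipped for rarefaction (common-g rule).
    """
    pops = G.populations()
    by_pop_counts = allele_copy_counts(G, by_population=True)
    pooled_counts = allele_copy_counts(G)

    if g is None:
        min_copies = min(
            min(sum(cc.values()) for cc in by_pop_counts[p].values()) for p in pops
        )
        g = max(min_copies, 1)

    rows = []
    # rarefaction over loci passing the common-g rule
    rarefiable = [
        locus
        for locus in G.loci
        if all(sum(by_pop_counts[p][locus].values()) >= g for p in pops)
    ]
    ar: dict[str, list[float]] = {p: [] for p in pops}
    par: dict[str, list[float]] = {p: [] for p in pops}
    for locus in rarefiable:
        per_locus = {p: by_pop_counts[p][locus] for p in pops}
        priv = private_rarefied_richness(per_locus, g)
        for p in pops:
            ar[p].append(rarefied_richness(per_locus[p], g))
            par[p].append(priv[p])

    for pop in pops:
        counts = by_pop_counts[pop]
        sub = G.subset_populations([pop])
        per_locus = locus_diversity(sub)
        scored = [d.locus for d in per_locus]
        n_poly = sum(1 for d in per_locus if d.na >= 2)
        ppl = 100.0 * n_poly / len(scored) if scored else float("nan")
        # private alleles: observed here, absent from every other population
        private_na = []
        for locus in G.loci:
            others = {
                a
                for q in pops
                if q != pop
                for a in by_pop_counts[q][locus]
            }
            private_na.append(len([a for a in counts[locus] if a not in others]))
        na_m, na_se = _mean_se([float(d.na) for d in per_locus])
        ne_m, ne_se = _mean_se([d.ne for d in per_locus])
        i_m, i_se = _mean_se([d.shannon for d in per_locus])
        ho_m, ho_se = _mean_se([d.ho for d in per_locus])
        he_m, he_se = _mean_se([d.he for d in per_locus])
        ar_m, ar_se = _mean_se(ar[pop])
        par_m, par_se = _mean_se(par[pop])
        rows.append(
            {
                "population": pop,
                "n": G.population_sizes()[pop],
                "g": g,
                "PPL_pct": ppl,
                "Na": na_m, "Na_se": na_se,
                "Ar": ar_m, "Ar_se": ar_se,
                "Ne": ne_m, "Ne_se": ne_se,
                "I": i_m, "I_se": i_se,
                "Ho": ho_m, "Ho_se": ho_se,
                "He": he_m, "He_se": he_se,
                "private_Na": float(np.mean(private_na)),
                "private_Ar": par_m, "private_Ar_se": par_se,
            }
        )
    return pd.DataFrame(rows)
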