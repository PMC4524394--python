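import numpy as np
import pytest

from ssrkit.genotypes import GenotypeMatrix


def make_matrix(pop_calls: dict[str, list[list[tuple[int, int]]]], loci=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {pop: [per-individual list of (a1, a2)]}."""
    ids, pops, rows = [], [], []
    i = 0
    for pop, individuals in pop_calls.items():
        for calls in individuals:
            ids.append(f"ind{i}")
            pops.append(pop)
            rows.append(calls)
            i += 1
    arr = np.array(rows, dtype=np.int64)
    n_loci = arr.shape[1]
    return GenotypeMatrix(
        ids=ids,
        pops=pops,
        loci=loci or [f"L{j + 1}" for j in range(n_loci)],
        calls=arr,
    )


@pytest.fixture
def two_pop_matrix() -> GenotypeMatrix:
    """Two populations fixed for disjoint alleles at every locus."""
    return make_matrix(
        {
            "A": [[(100, 100), (200, 200)]] * 4,
            "B": [[(110, 110), (210, 210)]] * 4,
        }
    )
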