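"""Diploid codominant genotype matrix (allele sizes in bp, 0 = missing)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "MISSING"]

#: Missing-allele code (GenAlEx convention: both alleles 0).
MISSING = 0


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid allele-size calls with population labels.

    ``calls`` has shape (n_individuals, n_loci, 2); alleles are unordered
    fragment sizes in bp and 0 codes a missing allele.  Half-missing calls
    are normalized to fully missing on construction.
    """

    ids: list[str]
    pops: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.pops) != n:
            raise ValueError("one population label per individual required")
        # half-missing -> missing
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        if any(s == 0 for s in self.population_sizes().values()):
            raise ValueError("every population must be nonempty")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pops:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.pops:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean mask of missing calls."""
        return (self.calls == MISSING).all(axis=2)

    def subset_populations(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [i for i, p in enumerate(self.pops) if p in set(keep)]
        return self.subset_individuals(idx)

    def subset_individuals(self, idx: list[int]) -> "GenotypeMatrix":
        return GenotypeMatrix(
            ids=[self.ids[i] for i in idx],
            pops=[self.pops[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
        )
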