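"""Synthetic inputs with known ground truth.

Three generators cover the pipeline's input surface: SSR-bearing reads
(with a controllable fraction of short rejects), pairs of template
genomes differing in repeat copy number at marker loci, and structured
multi-population diploid genotype matrices.  Background sequence is
rejection-sampled to be free of Class I SSRs so that miner recall and
precision are exactly scoreable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .mining import DEFAULT_THRESHOLDS, MIN_TRACT_BP, find_ssrs

__all__ = [
    "PlantedLocus",
    "ReadSimSpec",
    "LocusPolymorphism",
    "GenotypeSimSpec",
    "simulate_reads",
    "simulate_template_pair",
    "simulate_genotypes",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedLocus:
    """A perfect SSR to plant on one read."""

    motif: str
    repeat_count: int
    left_flank: int = 60
    right_flank: int = 60


@dataclass(frozen=True)
class ReadSimSpec:
    n_reads: int = 200
    length_range: tuple[int, int] = (80, 500)
    mean_length: int = 214
    planted_loci: tuple[PlantedLocus, ...] = ()
    short_read_fraction: float = 0.0
    interruption_gap: int | None = None
    gc_background: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid length_range")
        if not 0.0 <= self.short_read_fraction < 1.0:
            raise ValueError("short_read_fraction must be in [0, 1)")
        for pl in self.planted_loci:
            span = len(pl.motif) * pl.repeat_count + pl.left_flank + pl.right_flank
            if span > hi:
                raise ValueError(
                    f"planted SSR + flanks ({span} bp) exceed max read length {hi}"
                )


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _ssr_free_seq(
    rng: np.random.Generator, length: int, gc: float, max_tries: int = 200
) -> str:
    """Random background guaranteed to contain no Class I SSR."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length, gc)
        if not find_ssrs(seq, DEFAULT_THRESHOLDS, MIN_TRACT_BP):
            return seq
    raise RuntimeError("could not sample SSR-free background")


def _planted_read(
    rng: np.random.Generator,
    loci: Sequence[PlantedLocus],
    gap: int,
    gc: float,
    max_tries: int = 500,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Assemble one read carrying the given SSRs; rejection-sample flanks
    until the miner recovers exactly the planted tracts."""
    for _ in range(max_tries):
        parts: list[str] = [_ssr_free_seq(rng, loci[0].left_flank, gc)]
        expected: list[tuple[str, int, int]] = []
        pos = len(parts[0])
        for i, pl in enumerate(loci):
            tract = pl.motif * pl.repeat_count
            expected.append((pl.motif, pl.repeat_count, pos))
            parts.append(tract)
            pos += len(tract)
            if i < len(loci) - 1:
                spacer = _ssr_free_seq(rng, gap, gc)
                parts.append(spacer)
                pos += gap
        parts.append(_ssr_free_seq(rng, loci[-1].right_flank, gc))
        seq = "".join(parts)
        found = find_ssrs(seq, DEFAULT_THRESHOLDS, MIN_TRACT_BP)
        if [(m.motif, m.repeat_count, m.start) for m in found] == expected:
            return seq, expected
    raise RuntimeError("could not assemble clean planted read")


def simulate_reads(spec: ReadSimSpec) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate a read set and a truth table of planted SSRs.

    Returns ``(reads, truth)`` where reads are (id, sequence) pairs and
    the truth table has one row per planted SSR with columns
    ``read_id, motif, repeat_count, start, end``.  The number of reads
    shorter than 80 bp is exactly ``round(short_read_fraction * n_reads)``.
    Background reads contain no run meeting Class I thresholds.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    planted = list(spec.planted_loci)
    if spec.interruption_gap is not None and len(planted) >= 2:
        groups: list[list[PlantedLocus]] = [
            planted[i : i + 2] for i in range(0, len(planted), 2)
        ]
    else:
        groups = [[pl] for pl in planted]

    for gi, grp in enumerate(groups):
        seq, expected = _planted_read(
            rng, grp, spec.interruption_gap or 0, spec.gc_background
        )
        rid = f"read_ssr_{gi:05d}"
        reads.append((rid, seq))
        for motif, count, start in expected:
            truth_rows.append(
                {
                    "read_id": rid,
                    "motif": motif,
                    "repeat_count": count,
                    "start": start,
                    "end": start + len(motif) * count,
                }
            )

    n_background = spec.n_reads - len(groups)
    if n_background < 0:
        raise ValueError("n_reads smaller than number of planted reads")
    n_short = round(spec.short_read_fraction * spec.n_reads)
    if n_short > n_background:
        raise ValueError("short_read_fraction incompatible with planted reads")

    sd = max((hi - spec.mean_length, spec.mean_length - lo)) / 3 or 1.0
    for bi in range(n_background):
        if bi < n_short:
            length = int(rng.integers(20, 80))
        else:
            length = int(np.clip(round(rng.normal(spec.mean_length, sd)), lo, hi))
        reads.append((f"read_bg_{bi:05d}", _ssr_free_seq(rng, length, spec.gc_background)))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "motif", "repeat_count", "start", "end"]
    )
    return reads, truth


@dataclass(frozen=True)
class LocusPolymorphism:
    """How genome B differs from genome A at one marker locus."""

    delta: int = 0  # repeat copies gained (+) or lost (-)
    absent: bool = False
    mutate_primer_3prime: bool = False


def _mutate_base(b: str) -> str:
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[b]


def simulate_template_pair(
    loci: pd.DataFrame,
    reads: Mapping[str, str],
    polymorphisms: Mapping[str, LocusPolymorphism],
    primer_pairs: Mapping[str, "object"] | None = None,
    spacer: int = 120,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Build two template genomes differing at marker loci.

    ``loci`` is a truth table (read_id, motif, repeat_count, start, end);
    each read hosts one locus here.  Genome A embeds the source reads
    verbatim between SSR-free spacers; genome B applies per-locus
    polymorphisms: a repeat-count ``delta`` (size shift of period x delta
    bp), ``absent`` (locus omitted), or ``mutate_primer_3prime`` (one
    substitution inside the terminal 9-mer of the forward primer site,
    which requires ``primer_pairs``).

    Returns (genome_a records, genome_b records, expectation table with
    per-locus size_shift and status).
    """
    rng = np.random.default_rng(seed)
    a_parts: list[str] = []
    b_parts: list[str] = []
    rows: list[dict] = []
    for _, row in loci.iterrows():
        rid = row["read_id"]
        seq = reads[rid]
        pol = polymorphisms.get(rid, LocusPolymorphism())
        period = len(row["motif"])
        a_parts.append(_ssr_free_seq(rng, spacer, gc))
        a_parts.append(seq)
        status = "conserved"
        shift = 0
        if pol.absent:
            status = "absent"
        else:
            b_seq = seq
            if pol.delta:
                new_count = row["repeat_count"] + pol.delta
                if new_count < 1:
                    raise ValueError(f"delta removes locus {rid} entirely")
                b_seq = (
                    seq[: row["start"]]
                    + row["motif"] * new_count
                    + seq[row["end"] :]
                )
                shift = period * pol.delta
                status = "polymorphic"
            if pol.mutate_primer_3prime:
                if primer_pairs is None or rid not in primer_pairs:
                    raise ValueError(
                        f"mutate_primer_3prime for {rid} requires its primer pair"
                    )
                fwd = primer_pairs[rid].forward
                site = b_seq.find(fwd)
                if site < 0:
                    raise ValueError(f"forward primer site not found on {rid}")
                # hit the middle of the terminal (3') 9-mer
                pos = site + len(fwd) - 5
                b_seq = b_seq[:pos] + _mutate_base(b_seq[pos]) + b_seq[pos + 1 :]
                status = "site_mutated"
            b_parts.append(_ssr_free_seq(rng, spacer, gc))
            b_parts.append(b_seq)
        rows.append(
            {
                "read_id": rid,
                "motif": row["motif"],
                "size_shift": shift,
                "status": status,
            }
        )
    a_parts.append(_ssr_free_seq(rng, spacer, gc))
    b_parts.append(_ssr_free_seq(rng, spacer, gc))
    genome_a = [("genomeA_scaffold1", "".join(a_parts))]
    genome_b = [("genomeB_scaffold1", "".join(b_parts))]
    table = pd.DataFrame(rows, columns=["read_id", "motif", "size_shift", "status"])
    return genome_a, genome_b, table


@dataclass(frozen=True)
class GenotypeSimSpec:
    n_populations: int = 2
    sizes: tuple[int, ...] = (30, 30)
    n_loci: int = 20
    alleles_per_locus: int = 5
    differentiation: float = 0.1  # Balding-Nichols F
    missing_rate: float = 0.0
    clone_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sizes) != self.n_populations:
            raise ValueError("one size per population required")
        if any(s < 1 for s in self.sizes):
            raise ValueError("population sizes must be >= 1")
        if not 0.0 <= self.differentiation < 1.0:
            raise ValueError("differentiation F must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_genotypes(
    spec: GenotypeSimSpec,
) -> tuple[GenotypeMatrix, dict]:
    """Structured diploid genotypes under a Balding-Nichols model.

    Ancestral allele frequencies are Dirichlet(1,..,1); each population's
    frequencies are Dirichlet(p * (1-F)/F) around the ancestral vector
    (shared frequencies when F = 0).  Genotypes are drawn under
    Hardy-Weinberg within populations; clone pairs are exact row copies
    appended to their source population; missing calls are coded 0/0.

    Returns the matrix and a truth dict with ``ancestral_freqs`` (L x A),
    ``pop_freqs`` (pop -> L x A) and ``allele_sizes`` (L x A bp labels).
    """
    rng = np.random.default_rng(spec.seed)
    L, A = spec.n_loci, spec.alleles_per_locus
    F = spec.differentiation

    ancestral = rng.dirichlet(np.ones(A), size=L)  # (L, A)
    allele_sizes = np.empty((L, A), dtype=np.int64)
    for l in range(L):
        base = int(rng.integers(100, 260))
        allele_sizes[l] = base + 2 * np.arange(A)

    pop_names = [f"pop{k + 1}" for k in range(spec.n_populations)]
    pop_freqs: dict[str, np.ndarray] = {}
    for name in pop_names:
        if F == 0.0:
            pop_freqs[name] = ancestral.copy()
        else:
            scale = (1.0 - F) / F
            freqs = np.empty_like(ancestral)
            for l in range(L):
                alpha = np.maximum(ancestral[l] * scale, 1e-9)
                freqs[l] = rng.dirichlet(alpha)
            pop_freqs[name] = freqs

    ids: list[str] = []
    pops: list[str] = []
    calls = np.zeros((sum(spec.sizes), L, 2), dtype=np.int64)
    i = 0
    for name, size in zip(pop_names, spec.sizes):
        freqs = pop_freqs[name]
        for _ in range(size):
            for l in range(L):
                pair = rng.choice(A, size=2, p=freqs[l])
                calls[i, l] = allele_sizes[l][pair]
            ids.append(f"{name}_ind{i:04d}")
            pops.append(name)
            i += 1

    if spec.missing_rate > 0:
        mask = rng.random((calls.shape[0], L)) < spec.missing_rate
        calls[mask] = 0

    if spec.clone_pairs:
        n = calls.shape[0]
        src = rng.choice(n, size=spec.clone_pairs, replace=False)
        clone_calls = calls[src].copy()
        calls = np.concatenate([calls, clone_calls], axis=0)
        for j, s in enumerate(src):
            ids.append(f"{ids[s]}_clone{j}")
            pops.append(pops[s])

    matrix = GenotypeMatrix(ids=ids, pops=pops, loci=[f"loc{l + 1:03d}" for l in range(L)], calls=calls)
    truth = {
        "ancestral_freqs": ancestral,
        "pop_freqs": pop_freqs,
        "allele_sizes": allele_sizes,
    }
    return matrix, truth
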