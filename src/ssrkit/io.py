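"""File formats: FASTA/FASTQ and the GenAlEx-style genotype CSV.

The genotype dialect is: row 1 = n_loci, n_individuals, n_populations,
then per-population sizes; row 2 = title, blank, population names;
row 3 = header with two columns per locus; data rows = individual id,
population label, two allele sizes (bp) per locus, 0 = missing.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .genotypes import GenotypeMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_genalex",
    "write_genalex",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_genalex(G: GenotypeMatrix, path: str | Path, title: str = "ssrkit export") -> None:
    pops = G.populations()
    sizes = G.population_sizes()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [G.n_loci, G.n_individuals, len(pops)] + [sizes[p] for p in pops]
        )
        w.writerow([title, ""] + pops)
        header = ["Ind", "Pop"]
        for locus in G.loci:
            header += [locus, ""]
        w.writerow(header)
        for i, (ind, pop) in enumerate(zip(G.ids, G.pops)):
            row: list = [ind, pop]
            for l in range(G.n_loci):
                row += [int(G.calls[i, l, 0]), int(G.calls[i, l, 1])]
            w.writerow(row)


def read_genalex(path: str | Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError("truncated genotype file")
    n_loci = int(rows[0][0])
    n_ind = int(rows[0][1])
    header = rows[2]
    loci = [header[2 + 2 * l] for l in range(n_loci)]
    ids: list[str] = []
    pops: list[str] = []
    calls = np.zeros((n_ind, n_loci, 2), dtype=np.int64)
    data = [r for r in rows[3:] if any(field.strip() for field in r)]
    if len(data) != n_ind:
        raise ValueError(
            f"header declares {n_ind} individuals but {len(data)} data rows found"
        )
    for i, row in enumerate(data):
        ids.append(row[0])
        pops.append(row[1])
        for l in range(n_loci):
            calls[i, l, 0] = int(row[2 + 2 * l] or 0)
            calls[i, l, 1] = int(row[3 + 2 * l] or 0)
    return GenotypeMatrix(ids=ids, pops=pops, loci=loci, calls=calls)
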