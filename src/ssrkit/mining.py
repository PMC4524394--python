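"""Detection of Class I di-/tri-/tetra-nucleotide microsatellites in reads.

The miner reports maximal perfect tandem runs at their smallest period,
merges nearby runs into compound loci, and flags loci whose flanks are
long enough for primer placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SSRMotif",
    "SSRLocus",
    "DEFAULT_THRESHOLDS",
    "MIN_TRACT_BP",
    "filter_reads",
    "find_ssrs",
    "canonical_motif",
    "build_loci",
    "summarize_catalog",
]

#: Minimum whole repeat counts per motif period (di, tri, tetra).
DEFAULT_THRESHOLDS: Mapping[int, int] = {2: 11, 3: 7, 4: 6}

#: Minimum total tract length in bp for a Class I call.
MIN_TRACT_BP = 21

_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRMotif:
    """One maximal perfect tandem repeat on a read."""

    motif: str
    canonical_class: str
    repeat_count: int
    start: int
    end: int  # half-open

    @property
    def tract_length(self) -> int:
        return self.end - self.start

    @property
    def period(self) -> int:
        return len(self.motif)


@dataclass
class SSRLocus:
    """A perfect or compound SSR locus with flank accounting."""

    read_id: str
    motifs: list[SSRMotif]
    structure: str  # "perfect" | "compound"
    left_flank: int
    right_flank: int
    primer_designable: bool = False

    @property
    def start(self) -> int:
        return self.motifs[0].start

    @property
    def end(self) -> int:
        return self.motifs[-1].end


def filter_reads(
    reads: Iterable[tuple[str, str]], min_length: int = 80
) -> tuple[list[tuple[str, str]], int]:
    """Drop reads shorter than ``min_length`` bp.

    Parameters
    ----------
    reads : iterable of (id, sequence)
    min_length : retention boundary; a read of exactly ``min_length`` is kept.

    Returns
    -------
    (retained reads, rejection count)
    """
    retained: list[tuple[str, str]] = []
    rejected = 0
    for rid, seq in reads:
        if len(seq) >= min_length:
            retained.append((rid, seq))
        else:
            rejected += 1
    return retained, rejected


def _minimal_period(unit: str) -> int:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str, strand_collapse: bool = False) -> str:
    """Canonical class representative of a repeat unit.

    Lexicographically smallest cyclic rotation; with ``strand_collapse``
    the rotations of the reverse complement compete as well.
    """
    if not (2 <= len(motif) <= 4):
        raise ValueError(f"motif length must be 2-4, got {motif!r}")
    if not set(motif) <= _ACGT:
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    candidates = {motif[i:] + motif[:i] for i in range(len(motif))}
    if strand_collapse:
        rc = reverse_complement(motif)
        candidates |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return min(candidates)


def find_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    min_tract: int = MIN_TRACT_BP,
    strand_collapse: bool = False,
) -> list[SSRMotif]:
    """Find maximal perfect tandem runs meeting Class I thresholds.

    A run is reported at the smallest period of its repeat unit
    (``ATATAT`` is a di- run, never a tetra- run; homopolymers are never
    reported). The tract is anchored at the leftmost character of the
    maximal run and covers whole repeat units only — a trailing partial
    unit does not increment the count. ``N`` breaks runs.
    """
    seq = sequence.upper()
    n = len(seq)
    out: list[SSRMotif] = []
    for period, min_count in sorted(thresholds.items()):
        i = 0
        while i + 2 * period <= n:
            if seq[i] not in _ACGT:
                i += 1
                continue
            # extend the run: maximal j with seq[k] == seq[k+period] on [i, j)
            j = i
            while j + period < n and seq[j + period] in _ACGT and seq[j] == seq[j + period]:
                j += 1
            run_len = j + period - i  # chars covered by the repetition
            count = run_len // period
            if count >= 2:
                unit = seq[i : i + period]
                if (
                    _minimal_period(unit) == period
                    and count >= min_count
                    and count * period >= min_tract
                ):
                    end = i + count * period
                    out.append(
                        SSRMotif(
                            motif=unit,
                            canonical_class=canonical_motif(unit, strand_collapse),
                            repeat_count=count,
                            start=i,
                            end=end,
                        )
                    )
                # skip past this repetitive stretch for this period
                i = j + 1 if count >= 2 else i + 1
            else:
                i += 1
    out.sort(key=lambda m: (m.start, m.end, m.period))
    return out


def build_loci(
    motifs: Sequence[SSRMotif],
    read_id: str,
    read_length: int,
    max_interruption: int = 100,
    min_flank: int = 20,
) -> list[SSRLocus]:
    """Merge nearby motifs into compound loci and assess flanks.

    Motifs whose inter-motif gap is at most ``max_interruption`` bp merge
    into one compound locus; a locus is primer-designable iff both flanks
    are at least ``min_flank`` bp.
    """
    if not motifs:
        return []
    motifs = sorted(motifs, key=lambda m: m.start)
    groups: list[list[SSRMotif]] = [[motifs[0]]]
    for m in motifs[1:]:
        if m.start - groups[-1][-1].end <= max_interruption:
            groups[-1].append(m)
        else:
            groups.append([m])
    loci = []
    for grp in groups:
        left = grp[0].start
        right = read_length - grp[-1].end
        locus = SSRLocus(
            read_id=read_id,
            motifs=list(grp),
            structure="perfect" if len(grp) == 1 else "compound",
            left_flank=left,
            right_flank=right,
            primer_designable=(left >= min_flank and right >= min_flank),
        )
        loci.append(locus)
    return loci


def summarize_catalog(loci: Sequence[SSRLocus]) -> dict:
    """Counts by structure, motif period and repeat-count bin.

    ``perfect + compound == total``; the per-period breakdown partitions
    the perfect loci.
    """
    summary = {
        "total": len(loci),
        "perfect": 0,
        "compound": 0,
        "di": 0,
        "tri": 0,
        "tetra": 0,
        "by_class": {},
        "by_repeat_count": {},
    }
    period_name = {2: "di", 3: "tri", 4: "tetra"}
    for locus in loci:
        if locus.structure == "perfect":
            summary["perfect"] += 1
            m = locus.motifs[0]
            summary[period_name[m.period]] += 1
            summary["by_class"][m.canonical_class] = (
                summary["by_class"].get(m.canonical_class, 0) + 1
            )
            summary["by_repeat_count"][m.repeat_count] = (
                summary["by_repeat_count"].get(m.repeat_count, 0) + 1
            )
        else:
            summary["compound"] += 1
    return summary
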