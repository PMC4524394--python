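"""Primer-pair selection in SSR flanks and validation verdicts.

The picker applies length / GC / Tm-difference / product-size
constraints only; thermodynamic secondary-structure screening is out of
scope.  Melting temperatures come from unified nearest-neighbor
thermodynamics with monovalent-salt correction (Biopython's Tm_NN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .mining import SSRLocus, reverse_complement

__all__ = [
    "PrimerPair",
    "PickerParams",
    "TemplateEvidence",
    "ValidationVerdict",
    "compute_tm",
    "pick_primers",
    "classify_validation",
]

DEFAULT_SALT_MM = 50.0
DEFAULT_PRIMER_NM = 200.0

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class PrimerPair:
    marker_name: str
    forward: str
    reverse: str
    tm_forward: float
    tm_reverse: float
    ta_opt: float
    expected_size: int
    # 0-based position of the forward primer 5' start on the source read
    forward_start: int = -1

    @property
    def tm_difference(self) -> float:
        return abs(self.tm_forward - self.tm_reverse)


@dataclass(frozen=True)
class PickerParams:
    product_range: tuple[int, int] = (100, 250)
    max_tm_diff: float = 1.0
    length_range: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (0.40, 0.60)
    salt_mM: float = DEFAULT_SALT_MM
    primer_nM: float = DEFAULT_PRIMER_NM


def compute_tm(
    oligo: str,
    salt_mM: float = DEFAULT_SALT_MM,
    primer_nM: float = DEFAULT_PRIMER_NM,
) -> float:
    """Nearest-neighbor melting temperature in deg C, rounded to 0.01.

    Unified NN parameters with a monovalent-salt correction; by duplex
    symmetry an oligo and its reverse complement share one Tm.
    """
    oligo = oligo.upper()
    if len(oligo) < 8:
        raise ValueError("oligo must be at least 8 nt")
    if not set(oligo) <= _ACGT:
        raise ValueError(f"oligo must be over ACGT: {oligo!r}")
    tm = _mt.Tm_NN(
        oligo,
        nn_table=_mt.DNA_NN3,
        Na=salt_mM,
        K=0,
        Tris=0,
        Mg=0,
        dnac1=primer_nM,
        dnac2=primer_nM,
        saltcorr=5,
    )
    return round(float(tm), 2)


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def ta_from_tms(tm_forward: float, tm_reverse: float) -> float:
    """Recommended annealing temperature: min(Tm) - 3, clamped to 30-80."""
    return round(min(max(min(tm_forward, tm_reverse) - 3.0, 30.0), 80.0), 2)


def pick_primers(
    locus: SSRLocus,
    read_seq: str,
    marker_name: str,
    params: PickerParams = PickerParams(),
) -> PrimerPair | None:
    """Best primer pair flanking ``locus`` on ``read_seq``, or None.

    The forward primer is a left-flank substring; the reverse primer is
    the reverse complement of a right-flank substring.  Expected product
    size spans 5' start of the forward to the 5' start of the reverse
    site (both primers included).  Ties break by smallest Tm difference,
    then mean Tm closest to 60 deg C, then leftmost forward.
    """
    read_seq = read_seq.upper()
    lo_len, hi_len = params.length_range
    lo_prod, hi_prod = params.product_range
    ssr_start, ssr_end = locus.start, locus.end

    def candidates(lo: int, hi: int):
        out = []
        for length in range(lo_len, hi_len + 1):
            for start in range(lo, hi - length + 1):
                sub = read_seq[start : start + length]
                if not set(sub) <= _ACGT:
                    continue
                if not params.gc_range[0] <= _gc_fraction(sub) <= params.gc_range[1]:
                    continue
                out.append((start, sub))
        return out

    fwd_cands = candidates(0, ssr_start)
    rev_cands = candidates(ssr_end, len(read_seq))
    if not fwd_cands or not rev_cands:
        return None

    fwd_tms = {s: compute_tm(s, params.salt_mM, params.primer_nM) for _, s in fwd_cands}
    rev_tms = {
        sub: compute_tm(sub, params.salt_mM, params.primer_nM) for _, sub in rev_cands
    }

    best = None
    best_key = None
    for f_start, f_sub in fwd_cands:
        for r_start, r_sub in rev_cands:
            size = r_start + len(r_sub) - f_start
            if not lo_prod <= size <= hi_prod:
                continue
            tm_f, tm_r = fwd_tms[f_sub], rev_tms[r_sub]
            diff = abs(tm_f - tm_r)
            if diff > params.max_tm_diff:
                continue
            key = (diff, abs((tm_f + tm_r) / 2 - 60.0), f_start)
            if best_key is None or key < best_key:
                best_key = key
                best = (f_start, f_sub, r_sub, tm_f, tm_r, size)
    if best is None:
        return None
    f_start, f_sub, r_sub, tm_f, tm_r, size = best
    return PrimerPair(
        marker_name=marker_name,
        forward=f_sub,
        reverse=reverse_complement(r_sub),
        tm_forward=tm_f,
        tm_reverse=tm_r,
        ta_opt=ta_from_tms(tm_f, tm_r),
        expected_size=size,
        forward_start=f_start,
    )


@dataclass(frozen=True)
class TemplateEvidence:
    """Virtual-PCR outcome of one primer pair on one template genome."""

    template_id: str
    amplicon_sizes: tuple[int, ...]  # all predicted products
    annealing_estimate: float | None  # of the unique product, if unique
    tm_forward: float
    tm_reverse: float

    @property
    def unique(self) -> bool:
        return len(self.amplicon_sizes) == 1


@dataclass(frozen=True)
class ValidationVerdict:
    marker_name: str
    unique_amplicon: bool
    ta_ok: bool
    tm_diff_ok: bool
    size_deltas: tuple[int, ...]  # unique-product size minus expected, per template
    verdict: str  # working | putatively_polymorphic | failed


def classify_validation(
    marker_name: str,
    evidence: Sequence[TemplateEvidence],
    expected_size: int,
    min_ta: float = 50.0,
    max_tm_diff: float = 3.0,
) -> ValidationVerdict:
    """Working / putatively-polymorphic / failed verdict.

    A pair is *working* iff on at least one template it (i) yields a
    putative unique amplicon, (ii) anneals at >= ``min_ta`` deg C and
    (iii) its primers differ by <= ``max_tm_diff`` deg C.  A working
    pair whose unique product on some template differs in size from
    ``expected_size`` is *putatively polymorphic*; anything else fails.
    """
    if not evidence:
        raise ValueError("evidence from at least one template required")
    passing: list[TemplateEvidence] = []
    any_unique = False
    any_ta = False
    any_tmdiff = False
    for ev in evidence:
        tm_diff_ok = abs(ev.tm_forward - ev.tm_reverse) <= max_tm_diff
        ta_ok = ev.annealing_estimate is not None and ev.annealing_estimate >= min_ta
        any_unique |= ev.unique
        any_ta |= ta_ok
        any_tmdiff |= tm_diff_ok
        if ev.unique and ta_ok and tm_diff_ok:
            passing.append(ev)
    deltas = tuple(
        ev.amplicon_sizes[0] - expected_size for ev in passing
    )
    working = bool(passing)
    polymorphic = working and any(d != 0 for d in deltas)
    verdict = (
        "putatively_polymorphic" if polymorphic else "working" if working else "failed"
    )
    return ValidationVerdict(
        marker_name=marker_name,
        unique_amplicon=any_unique,
        ta_ok=any_ta,
        tm_diff_ok=any_tmdiff,
        size_deltas=deltas,
        verdict=verdict,
    )
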