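"""Virtual PCR: 3'-anchored k-mer primer binding and amplicon prediction.

Binding requires an exact match of the primer's terminal k-mer (default
k = 9); the duplex is then extended 5'-ward while bases keep matching,
and the duplex Tm is computed on the matched stretch only.  Amplicons
are enumerated from convergent plus/minus site pairs up to a maximum
product size, keeping those whose annealing estimate (the smaller of
the two site Tms) falls inside the scanned temperature window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .design import PrimerPair, compute_tm
from .mining import canonical_motif, reverse_complement

__all__ = [
    "BindingSite",
    "AmpliconPrediction",
    "TemplateIndex",
    "index_template",
    "predict_amplicons",
    "assess_transferability",
]

DEFAULT_K = 9
DEFAULT_MAX_PRODUCT = 2000
DEFAULT_TA_WINDOW = (30.0, 80.0)


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    strand: str  # "+" or "-"
    three_prime_pos: int  # 0-based, plus-strand coordinate
    matched_length: int
    duplex_tm: float
    primer: str
    five_prime_pos: int  # plus-strand coordinate of the primer 5' base


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    start: int
    end: int  # half-open, plus strand
    size: int
    forward_site: BindingSite
    reverse_site: BindingSite
    annealing_estimate: float

    def sequence(self, templates: Mapping[str, str]) -> str:
        return templates[self.template_id][self.start : self.end]


class TemplateIndex:
    """k-mer position index over both strands of a multi-record FASTA."""

    def __init__(self, records: Iterable[tuple[str, str]], k: int = DEFAULT_K):
        if k < 6:
            raise ValueError("k must be >= 6")
        self.k = k
        self.seqs: dict[str, str] = {}
        self.skipped: list[str] = []
        # kmer -> list of (seq_id, strand, plus-strand start of the k-mer footprint)
        self._index: dict[str, list[tuple[str, str, int]]] = {}
        for sid, seq in records:
            seq = seq.upper()
            if len(seq) < k:
                self.skipped.append(sid)
                continue
            self.seqs[sid] = seq
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                self._index.setdefault(kmer, []).append((sid, "+", i))
                self._index.setdefault(reverse_complement(kmer), []).append(
                    (sid, "-", i)
                )

    def lookup(self, kmer: str) -> list[tuple[str, str, int]]:
        """All (seq_id, strand, plus-strand footprint start) for ``kmer``.

        A "-" hit means the k-mer occurs reading the minus strand 5'->3';
        the recorded position is where its reverse complement sits on the
        plus strand.
        """
        if len(kmer) != self.k:
            raise ValueError(f"expected {self.k}-mer, got {len(kmer)}-mer")
        return list(self._index.get(kmer.upper(), []))


def index_template(
    records: Iterable[tuple[str, str]], k: int = DEFAULT_K
) -> TemplateIndex:
    return TemplateIndex(records, k=k)


def _sites_for_primer(primer: str, index: TemplateIndex) -> list[BindingSite]:
    k = index.k
    primer = primer.upper()
    if len(primer) < k:
        return []
    anchor = primer[-k:]
    sites: list[BindingSite] = []
    for sid, strand, pos in index.lookup(anchor):
        seq = index.seqs[sid]
        n = len(seq)
        if strand == "+":
            # primer lies along the plus strand; anchor footprint [pos, pos+k)
            three_prime = pos + k - 1
            five_prime = pos + k - len(primer)
            if five_prime < 0:
                continue
            matched = k
            while matched < len(primer) and seq[three_prime - matched] == primer[
                -(matched + 1)
            ]:
                matched += 1
        else:
            # anchor's reverse complement at [pos, pos+k); primer 3' end at pos
            three_prime = pos
            five_prime = pos + len(primer) - 1
            if five_prime >= n:
                continue
            comp = reverse_complement(primer)
            # comp aligns to plus strand ending at pos+k-1 going right
            matched = k
            while matched < len(primer) and seq[pos + matched] == comp[matched]:
                matched += 1
        duplex = primer[-matched:]
        sites.append(
            BindingSite(
                template_id=sid,
                strand=strand,
                three_prime_pos=three_prime,
                matched_length=matched,
                duplex_tm=compute_tm(duplex),
                primer=primer,
                five_prime_pos=five_prime,
            )
        )
    return sites


def predict_amplicons(
    pair: PrimerPair,
    index: TemplateIndex,
    max_product: int = DEFAULT_MAX_PRODUCT,
    ta_window: tuple[float, float] = DEFAULT_TA_WINDOW,
) -> list[AmpliconPrediction]:
    """Enumerate predicted products of a primer pair on indexed templates.

    Both oligos are searched on both strands, so orientation of the
    template does not matter.  Product size runs from the 5' start of
    the plus-strand site to the 5' start of the minus-strand site,
    inclusive of both primers.
    """
    sites = _sites_for_primer(pair.forward, index) + _sites_for_primer(
        pair.reverse, index
    )
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    out: list[AmpliconPrediction] = []
    for f in plus:
        for r in minus:
            if f.template_id != r.template_id:
                continue
            if r.three_prime_pos <= f.three_prime_pos:
                continue
            size = r.five_prime_pos - f.five_prime_pos + 1
            if size <= 0 or size > max_product:
                continue
            ta = min(f.duplex_tm, r.duplex_tm)
            if not ta_window[0] <= ta <= ta_window[1]:
                continue
            out.append(
                AmpliconPrediction(
                    template_id=f.template_id,
                    start=f.five_prime_pos,
                    end=r.five_prime_pos + 1,
                    size=size,
                    forward_site=f,
                    reverse_site=r,
                    annealing_estimate=ta,
                )
            )
    out.sort(key=lambda a: (a.template_id, a.start, a.end))
    return out


def _contains_tandem(seq: str, motif_class: str, min_copies: int = 3) -> bool:
    period = len(motif_class)
    rotations = {motif_class[i:] + motif_class[:i] for i in range(period)}
    rc = reverse_complement(motif_class)
    rotations |= {rc[i:] + rc[:i] for i in range(period)}
    return any(rot * min_copies in seq for rot in rotations)


def assess_transferability(
    pairs: Sequence[PrimerPair],
    target_records: Sequence[tuple[str, str]],
    motif_classes: Mapping[str, str],
    k: int = DEFAULT_K,
    max_product: int = DEFAULT_MAX_PRODUCT,
    ta_window: tuple[float, float] = DEFAULT_TA_WINDOW,
) -> tuple[dict[str, dict], dict[str, float]]:
    """Cross-genome transfer assessment of a marker panel.

    A marker transfers (*amplified*) iff its pair predicts exactly one
    product on the target; it is *motif_verified* iff that product's
    sequence contains at least three tandem copies of the marker's
    canonical motif class (either strand).  Rates are percentages of the
    panel size.
    """
    index = index_template(target_records, k=k)
    templates = index.seqs
    per_pair: dict[str, dict] = {}
    n_amp = 0
    n_ver = 0
    for pair in pairs:
        amps = predict_amplicons(pair, index, max_product=max_product, ta_window=ta_window)
        amplified = len(amps) == 1
        verified = False
        if amplified:
            motif = canonical_motif(motif_classes[pair.marker_name])
            verified = _contains_tandem(amps[0].sequence(templates), motif)
        n_amp += amplified
        n_ver += verified
        per_pair[pair.marker_name] = {
            "amplified": amplified,
            "motif_verified": verified,
            "n_products": len(amps),
        }
    total = len(pairs) or 1
    rates = {
        "amplified_pct": 100.0 * n_amp / total,
        "motif_verified_pct": 100.0 * n_ver / total,
    }
    return per_pair, rates
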