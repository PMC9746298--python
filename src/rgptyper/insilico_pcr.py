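"""In-silico PCR: primer binding-site search and amplicon prediction.

Primer annealing is modelled as approximate string matching: a primer binds
wherever it aligns (ungapped) with at most ``max_mismatch`` mismatches, with
its 3'-terminal ``exact_3prime`` bases matching exactly — the 3' end is what
a polymerase extends from, so mismatches there abolish amplification far more
reliably than internal ones.  IUPAC degeneracy codes are honoured on both
sides: a primer base matches a template base iff their expansion sets
intersect (permissive on ambiguous assembly bases).

An amplicon is any convergent placement of the two primers of a pair on
opposite strands, measured inclusively from the first base of the upstream
binding site through the last base of the downstream one — the convention in
which the published expected product sizes are stated.

Positions are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import InputError
from .scheme_db import Primer, PrimerPair, TypingScheme

#: bitmask encoding of the IUPAC DNA alphabet (A=1 C=2 G=4 T=8)
IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_TABLE[ord(_c)] = _m
    _MASK_TABLE[ord(_c.lower())] = _m

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as IUPAC bitmasks; non-IUPAC characters raise."""
    arr = _MASK_TABLE[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = sorted({c for c in seq if IUPAC_MASK.get(c.upper()) is None})
        raise InputError(f"non-IUPAC characters in sequence: {bad}")
    return arr


@dataclass(frozen=True)
class BindingSite:
    """One primer annealing site on a template (0-based half-open)."""

    start: int
    end: int
    strand: str  # "+" | "-"
    mismatches: int


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product (0-based half-open span on the contig)."""

    pair_name: str
    start: int
    end: int
    length: int
    fwd_mismatches: int
    rev_mismatches: int
    contig: str = ""


@dataclass
class PanelResult:
    """Outcome of evaluating one PCR panel on a genome."""

    panel: str
    per_pair: dict[str, list[AmpliconHit]]
    control_ok: bool
    #: non-control pairs with >=1 size-concordant product
    amplified: frozenset[str]
    #: amplified pairs whose size-concordant products map to >1 locus
    ambiguous: frozenset[str]


def _window_mismatches(enc_seq: np.ndarray, enc_pat: np.ndarray) -> np.ndarray:
    """Mismatch count of the pattern at every window start (vectorized)."""
    n, k = len(enc_seq), len(enc_pat)
    nwin = n - k + 1
    mm = np.zeros(nwin, dtype=np.int32)
    for j in range(k):
        mm += (enc_seq[j : j + nwin] & enc_pat[j]) == 0
    return mm


def find_binding_sites(
    seq: str,
    primer: Primer | str,
    max_mismatch: int = 0,
    exact_3prime: int = 3,
) -> list[BindingSite]:
    """All annealing sites of *primer* on both strands of *seq*.

    A site on the ``+`` strand is an occurrence of the primer itself; a site
    on the ``-`` strand is an occurrence of its reverse complement (the
    primer anneals to the minus strand and extends leftwards in plus-strand
    coordinates).  The 3'-terminal ``exact_3prime`` primer bases must match
    with zero mismatches.
    """
    if max_mismatch < 0 or exact_3prime < 0:
        raise InputError("max_mismatch and exact_3prime must be >= 0")
    pseq = primer.sequence if isinstance(primer, Primer) else primer
    k = len(pseq)
    if k == 0:
        raise InputError("empty primer sequence")
    if k > len(seq):
        return []
    enc_seq = encode(seq)
    three = min(exact_3prime, k)
    sites: list[BindingSite] = []
    for strand, pattern in (("+", pseq), ("-", reverse_complement(pseq))):
        enc_pat = encode(pattern)
        mm = _window_mismatches(enc_seq, enc_pat)
        if three:
            # primer 3' end sits rightmost on "+", leftmost on "-"
            pat3 = enc_pat[-three:] if strand == "+" else enc_pat[:three]
            off = k - three if strand == "+" else 0
            nwin = len(mm)
            mm3 = np.zeros(nwin, dtype=np.int32)
            for j in range(three):
                mm3 += (enc_seq[off + j : off + j + nwin] & pat3[j]) == 0
            ok = (mm <= max_mismatch) & (mm3 == 0)
        else:
            ok = mm <= max_mismatch
        for pos in np.flatnonzero(ok):
            sites.append(BindingSite(int(pos), int(pos) + k, strand, int(mm[pos])))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    seq: str,
    pair: PrimerPair,
    max_mismatch: int = 0,
    min_len: int | None = None,
    max_len: int = 5000,
    exact_3prime: int = 3,
    contig: str = "",
) -> list[AmpliconHit]:
    """Enumerate convergent products of *pair* on *seq*.

    Both orientations are considered: forward primer on ``+`` with reverse on
    ``-`` downstream, and reverse primer on ``+`` with forward on ``-``
    downstream.  Product length is the inclusive span from the first base of
    the upstream site through the last base of the downstream site.
    """
    flen, rlen = len(pair.forward), len(pair.reverse)
    if min_len is None:
        min_len = flen + rlen
    if min_len > max_len:
        raise InputError(f"min_len {min_len} exceeds max_len {max_len}")
    fsites = find_binding_sites(seq, pair.forward, max_mismatch, exact_3prime)
    rsites = find_binding_sites(seq, pair.reverse, max_mismatch, exact_3prime)
    hits: list[AmpliconHit] = []
    for up, down in ((pair.forward, pair.reverse), (pair.reverse, pair.forward)):
        ups = fsites if up is pair.forward else rsites
        downs = rsites if up is pair.forward else fsites
        for u in ups:
            if u.strand != "+":
                continue
            for d in downs:
                if d.strand != "-":
                    continue
                length = d.end - u.start
                if length < max(min_len, len(up) + len(down)) or length > max_len:
                    continue
                fwd_mm = u.mismatches if up is pair.forward else d.mismatches
                rev_mm = d.mismatches if up is pair.forward else u.mismatches
                hits.append(
                    AmpliconHit(
                        pair_name=pair.name,
                        start=u.start,
                        end=d.end,
                        length=length,
                        fwd_mismatches=fwd_mm,
                        rev_mismatches=rev_mm,
                        contig=contig,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _as_contigs(genome: str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(genome, str):
        return {"": genome}
    return dict(genome)


def size_concordant(hit: AmpliconHit, expected: int, tolerance: float) -> bool:
    return abs(hit.length - expected) <= tolerance * expected


def run_panel(
    genome: str | Mapping[str, str],
    scheme: TypingScheme,
    panel: str,
    size_tolerance: float = 0.10,
    max_mismatch: int = 0,
    exact_3prime: int = 3,
) -> PanelResult:
    """Evaluate every pair of *panel* (control included) on *genome*.

    A pair counts as amplified iff at least one product lies within
    ``expected_amplicon * (1 +/- size_tolerance)``; the panel is valid
    (``control_ok``) iff its control pair is amplified.  Amplicons never span
    contigs.
    """
    contigs = _as_contigs(genome)
    per_pair: dict[str, list[AmpliconHit]] = {}
    amplified: set[str] = set()
    ambiguous: set[str] = set()
    control_ok = False
    for pair in scheme.panel_pairs(panel):
        expected = pair.expected_amplicon
        hits: list[AmpliconHit] = []
        for name, seq in contigs.items():
            hits.extend(
                predict_amplicons(
                    seq,
                    pair,
                    max_mismatch=max_mismatch,
                    max_len=max(int(expected * 2), len(pair.forward) + len(pair.reverse) + 1),
                    exact_3prime=exact_3prime,
                    contig=name,
                )
            )
        per_pair[pair.name] = hits
        concordant = [h for h in hits if size_concordant(h, expected, size_tolerance)]
        if pair.is_control:
            control_ok = bool(concordant)
        elif concordant:
            amplified.add(pair.name)
            loci = {(h.contig, h.start, h.end) for h in concordant}
            if len(loci) > 1:
                ambiguous.add(pair.name)
    return PanelResult(
        panel=panel,
        per_pair=per_pair,
        control_ok=control_ok,
        amplified=frozenset(amplified),
        ambiguous=frozenset(ambiguous),
    )


def hits_to_tsv(hits: Iterable[AmpliconHit]) -> str:
    """Render amplicon hits as TSV (1-based inclusive coordinates)."""
    lines = ["pair\tcontig\tstart\tend\tlength\tfwd_mismatches\trev_mismatches"]
    for h in hits:
        lines.append(
            f"{h.pair_name}\t{h.contig}\t{h.start + 1}\t{h.end}\t{h.length}"
            f"\t{h.fwd_mismatches}\t{h.rev_mismatches}"
        )
    return "\n".join(lines) + "\n"
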