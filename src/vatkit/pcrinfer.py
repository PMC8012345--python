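"""In-silico PCR and band-pattern decoding into homolog/repeat-count calls.

A gel lane from a repeat-spanning primer pair is an arithmetic code: each
intact homolog with k repeat units yields one product of length f + 195*k
(f the repeat-free flank constant of the pair).  Decoding the observed band
lengths gives one digit per band (the homolog's repeat count); dedicated
pairs detect single-repeat homologs (467-bp exon-2 product, 1502-bp
exon1-exon2 product), the reverse-strand homolog (933 bp) and the
insertion pseudo-class (a +2345 nt shift of the exon1-exon2 product).
Because co-migrating bands collapse, the homolog count is a minimum: two
homologs with the same repeat count are seen as one band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import encode, revcomp

VALID_BASES = set("ACGT")


class BandDecodeError(ValueError):
    """A band length is inconsistent with the amplicon arithmetic."""


@dataclass
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_product: int
    class_: str   # repeat_spanning | exon2_internal | exon1_exon2 | reverse_strand_exon1

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if set(p.upper()) - VALID_BASES:
                raise ValueError(
                    f"primer {self.name!r} contains degenerate bases "
                    "(IUPAC codes are unsupported)"
                )
        if self.max_product <= max(len(self.forward), len(self.reverse)):
            raise ValueError("max_product must exceed the primer lengths")


@dataclass
class Amplicon:
    start: int
    end: int           # half-open; length == end - start
    length: int
    f_strand: str      # strand the forward primer annealed on


@dataclass
class BandSet:
    accession: str
    primer_name: str
    lengths: list      # strictly increasing after dedup

    def __post_init__(self):
        if any(x <= 0 for x in self.lengths):
            raise ValueError("band lengths must be positive")
        self.lengths = sorted(set(self.lengths))


@dataclass
class AccessionInference:
    accession: str
    digits: str                      # sorted ascending, one digit per homolog
    has_single_repeat_homolog: bool = False
    has_reverse_homolog: bool = False
    has_insertion_pseudo: bool = False

    @property
    def homolog_count(self) -> int:
        return len(self.digits)


# ---------------------------------------------------------------------------
# primer matching
# ---------------------------------------------------------------------------


def _match_positions(tarr: np.ndarray, primer: str, max_mismatch: int,
                     exact_3prime_at: int) -> np.ndarray:
    """Start positions where ``primer`` matches with <= max_mismatch
    mismatches and an exact match at primer offset ``exact_3prime_at``."""
    parr = encode(primer)
    m = len(parr)
    n = len(tarr) - m + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    mism = np.zeros(n, dtype=np.int32)
    for j, pb in enumerate(parr):
        mism += tarr[j: j + n] != pb
    ok = mism <= max_mismatch
    ok &= tarr[exact_3prime_at: exact_3prime_at + n] == parr[exact_3prime_at]
    return np.flatnonzero(ok)


def find_binding_sites(template: str, primer: str, max_mismatch: int = 1):
    """All primer binding sites on both strands of ``template``.

    Returns a list of ``(position, strand)``: for '+' sites the primer 3' end
    points downstream from ``position`` (primer equals template[pos:pos+m]);
    for '-' sites the reverse complement of the primer equals the slice and
    the 3' end points upstream.  The 3'-terminal base must match exactly.
    """
    primer = primer.upper()
    if set(primer) - VALID_BASES:
        raise ValueError("degenerate bases in primer (IUPAC codes unsupported)")
    if len(primer) < 10:
        raise ValueError("primer length must be >= 10")
    tarr = encode(template)
    m = len(primer)
    fwd = _match_positions(tarr, primer, max_mismatch, exact_3prime_at=m - 1)
    rev = _match_positions(tarr, revcomp(primer), max_mismatch, exact_3prime_at=0)
    sites = [(int(p), "+") for p in fwd] + [(int(p), "-") for p in rev]
    sites.sort()
    return sites


def predict_amplicons(template: str, pair: PrimerPair, max_mismatch: int = 1):
    """All products of a primer pair on ``template`` (both orientations).

    A product pairs a '+'-strand site of one primer with a downstream
    '-'-strand site of the other; its length includes both primers.
    """
    sites_f = find_binding_sites(template, pair.forward, max_mismatch)
    sites_r = find_binding_sites(template, pair.reverse, max_mismatch)
    lf, lr = len(pair.forward), len(pair.reverse)
    out = []
    for (plus_sites, plus_len, minus_sites, minus_len, strand) in (
        (sites_f, lf, sites_r, lr, "+"),
        (sites_r, lr, sites_f, lf, "-"),
    ):
        for p, s in plus_sites:
            if s != "+":
                continue
            for q, s2 in minus_sites:
                if s2 != "-" or q < p:
                    continue
                end = q + minus_len
                if end - p <= pair.max_product:
                    out.append(Amplicon(p, end, end - p, strand))
    out.sort(key=lambda a: (a.start, a.end))
    # a palindromic coincidence can produce the same interval twice
    dedup, seen = [], set()
    for a in out:
        if (a.start, a.end) not in seen:
            seen.add((a.start, a.end))
            dedup.append(a)
    return dedup


# ---------------------------------------------------------------------------
# band decoding
# ---------------------------------------------------------------------------


def _decode_k(length: float, flank: int, unit_nt: int, tol: float) -> int | None:
    k = round((length - flank) / unit_nt)
    if 1 <= k <= 7 and abs(length - (flank + unit_nt * k)) <= tol:
        return int(k)
    return None


def infer_accession(
    bands: dict[str, BandSet],
    unit_nt: int = 195,
    flank_constants: dict | None = None,
    tol: float = 5.0,
) -> AccessionInference:
    """Decode one accession's band sets (keyed by primer class) into a
    digit string: one digit per inferred homolog, each digit the homolog's
    repeat count, sorted ascending.

    Decoding rules:

    * each repeat-spanning band of length L contributes digit
      round((L - f) / unit_nt); a band not within ``tol`` of any k in 1..7
      raises :class:`BandDecodeError`;
    * a reverse-strand product marks the reverse homolog and contributes
      one digit-1 homolog (it is invisible to the intron-anchored pair);
    * an exon1-exon2 band at f + unit_nt (1502 bp with defaults) marks a
      single-repeat forward homolog; a band at f + insertion_offset +
      unit_nt*k marks an insertion pseudogene (flagged, never a digit);
    * a 467-bp exon-2-internal product (or a 1502-bp exon1-exon2 product)
      appends a digit 1 when no digit 1 is already implied by other bands.
    """
    fc = dict(flank_constants or {})
    fc.setdefault("repeat_spanning", 572)
    fc.setdefault("exon2_internal", 272)
    fc.setdefault("exon1_exon2", 1307)
    fc.setdefault("reverse_strand_exon1", 933)
    fc.setdefault("insertion_offset", 2345)

    accession = next((b.accession for b in bands.values()), "?")
    digits: list[int] = []

    rs = bands.get("repeat_spanning")
    if rs is not None:
        for L in rs.lengths:
            k = _decode_k(L, fc["repeat_spanning"], unit_nt, tol)
            if k is None:
                raise BandDecodeError(
                    f"repeat-spanning band of {L} nt is not within {tol} nt of "
                    f"{fc['repeat_spanning']} + {unit_nt}*k for k in 1..7"
                )
            digits.append(k)

    has_reverse = False
    rev = bands.get("reverse_strand_exon1")
    if rev is not None and any(
        abs(L - fc["reverse_strand_exon1"]) <= tol for L in rev.lengths
    ):
        has_reverse = True
        digits.append(1)

    has_insertion = False
    single_fwd_1502 = False
    e12 = bands.get("exon1_exon2")
    if e12 is not None:
        base = fc["exon1_exon2"]
        for L in e12.lengths:
            k = _decode_k(L, base, unit_nt, tol)
            if k is not None:
                if k == 1:
                    single_fwd_1502 = True
                continue
            k_ins = _decode_k(L, base + fc["insertion_offset"], unit_nt, tol)
            if k_ins is not None:
                has_insertion = True
                continue
            raise BandDecodeError(
                f"exon1-exon2 band of {L} nt matches neither {base} + {unit_nt}*k "
                f"nor the insertion class {base + fc['insertion_offset']} + {unit_nt}*k"
            )

    e2i = bands.get("exon2_internal")
    internal_467 = e2i is not None and any(
        abs(L - (fc["exon2_internal"] + unit_nt)) <= tol for L in e2i.lengths
    )
    if (single_fwd_1502 or internal_467) and 1 not in digits:
        digits.append(1)

    digits.sort()
    return AccessionInference(
        accession=accession,
        digits="".join(str(d) for d in digits),
        has_single_repeat_homolog=1 in digits,
        has_reverse_homolog=has_reverse,
        has_insertion_pseudo=has_insertion,
    )


def bands_from_amplicons(
    accession: str, pairs: list, template: str, max_mismatch: int = 1
) -> dict[str, BandSet]:
    """Run every primer pair on a template and bin products into band sets
    keyed by primer class (gel lanes; co-migrating products collapse)."""
    out = {}
    for pair in pairs:
        amps = predict_amplicons(template, pair, max_mismatch)
        if amps:
            out[pair.class_] = BandSet(
                accession=accession,
                primer_name=pair.name,
                lengths=[a.length for a in amps],
            )
    return out


# ---------------------------------------------------------------------------
# panel summary
# ---------------------------------------------------------------------------


@dataclass
class PanelSummary:
    n_accessions: int
    total_homologs: int
    per_accession: dict           # accession -> homolog count
    n_accessions_ge4: int
    n_accessions_with_digit1: int
    digit_spectrum: dict = field(default_factory=dict)   # digit -> count


def summarize_panel(inferences: list) -> PanelSummary:
    """Panel-level totals over per-accession inferences."""
    if not inferences:
        raise ValueError("at least one inference required")
    ids = [inf.accession for inf in inferences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate accession ids in panel")
    per = {inf.accession: inf.homolog_count for inf in inferences}
    spectrum = {d: 0 for d in range(1, 8)}
    for inf in inferences:
        for ch in inf.digits:
            spectrum[int(ch)] += 1
    return PanelSummary(
        n_accessions=len(inferences),
        total_homologs=sum(per.values()),
        per_accession=per,
        n_accessions_ge4=sum(1 for v in per.values() if v >= 4),
        n_accessions_with_digit1=sum(1 for inf in inferences if "1" in inf.digits),
        digit_spectrum=spectrum,
    )
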