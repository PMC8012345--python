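"""Tandem repeat-unit annotation in coding sequences.

Detects the near-identical 65-codon (195-nt) repeat unit array of the LRR2
domain in an in-frame CDS, counts copies (k), excises all copies to build a
"virtual CDS" for repeat-free alignment and phylogeny, and partitions a CDS
into pre-array / array / post-array blocks.

Detection is self-contained for k >= 2 (tandem periodicity); a single copy
has no periodic signal, so k = 1 calls require a reference unit
(``unit_hint``), mirroring annotation against a reference gene.

Repeat copy boundaries are constrained to codon boundaries: the unit is
defined at the amino-acid level and excision must keep the virtual CDS in
frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import encode, seq_identity

logger = logging.getLogger(__name__)

SELF_MATCH_THRESHOLD = 0.6   # windowed self-match fraction that seeds an array


@dataclass
class RepeatAnnotation:
    """The repeat array of one CDS: tandem copy intervals and identities."""

    cds_id: str
    cds_length: int
    start: int                     # array start (nt, 0-based, codon-aligned)
    end: int                       # array end (half-open)
    copies: list                   # [(s, e), ...] tandem, non-overlapping
    unit_consensus: str
    copy_identity: list            # % identity of each copy to the consensus

    @property
    def k(self) -> int:
        return len(self.copies)


@dataclass
class VirtualCds:
    cds_id: str
    sequence: str
    # coord_map[i] = original coordinate of virtual position i (strictly increasing)
    coord_map: np.ndarray = field(repr=False, default=None)


@dataclass
class BlockPartition:
    pre: tuple      # [0, array start)
    array: tuple    # the repeat array
    post: tuple     # [array end, len)


def _consensus(copies: list[str]) -> str:
    arr = np.stack([encode(c) for c in copies])
    out = []
    for col in arr.T:
        vals, counts = np.unique(col, return_counts=True)
        out.append("ACGTN"[vals[np.argmax(counts)]])
    return "".join(out)


def _empty_annotation(cds_id: str, n: int) -> RepeatAnnotation:
    return RepeatAnnotation(cds_id, n, 0, 0, [], "", [])


def _grow_array(
    cds: str, seed_start: int, unit: int, min_copy_identity: float
) -> tuple[list, list[str]]:
    """Extend tandem copies in both directions from a codon-aligned seed,
    comparing each candidate copy against the running majority consensus."""
    n = len(cds)
    copies = [(seed_start, seed_start + unit)]
    seqs = [cds[seed_start: seed_start + unit]]
    # forward
    while True:
        s = copies[-1][1]
        if s + unit > n:
            break
        cand = cds[s: s + unit]
        if seq_identity(cand, _consensus(seqs)) < min_copy_identity:
            break
        copies.append((s, s + unit))
        seqs.append(cand)
    # backward
    while True:
        s = copies[0][0] - unit
        if s < 0:
            break
        cand = cds[s: s + unit]
        if seq_identity(cand, _consensus(seqs)) < min_copy_identity:
            break
        copies.insert(0, (s, s + unit))
        seqs.insert(0, cand)
    return copies, seqs


def _changepoint_bounds(t: np.ndarray, anchor: int, tau: float = 0.5) -> tuple[int, int]:
    """Array bounds from a 0/1 tile-match indicator ``t``.

    Inside the array the match rate is high (> tau), outside it is the
    background (~0.25), so the array start maximises the prefix sum of
    (tau - t) over codon boundaries <= anchor and the array end maximises
    the corresponding suffix sum over codon boundaries >= anchor.
    """
    d = tau - t.astype(np.float64)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    n = len(t)
    starts = np.arange(0, anchor + 1, 3)
    b = int(starts[np.argmax(cum[starts])])
    ends = np.arange(3 * ((anchor + 2) // 3), n + 1, 3)
    suffix = cum[n] - cum[ends]
    e = int(ends[np.argmax(suffix)])
    return b, e


def find_repeats(
    cds: str,
    unit_aa: int = 65,
    min_copy_identity: float = 70.0,
    cds_id: str = "cds",
    unit_hint: str | None = None,
) -> RepeatAnnotation:
    """Detect and count tandem repeat units in an in-frame CDS.

    Procedure: (1) scan lags in [3*unit_aa - 9, 3*unit_aa + 9] for the lag
    maximising the windowed self-match fraction; (2) anchor one interior
    copy at the best-matching window and tile it across the CDS; (3) place
    the array boundaries at the changepoints of the tile-match indicator,
    snapped to codon boundaries; (4) segment into whole tandem copies,
    dropping terminal copies below ``min_copy_identity``.  If no lag
    reaches the self-match threshold a k=0 annotation is returned (a lone
    copy has no periodic signal and is found only via ``unit_hint``).
    """
    cds = cds.upper()
    n = len(cds)
    unit = 3 * unit_aa
    if n < unit:
        raise ValueError("CDS shorter than one repeat unit")

    arr = encode(cds)
    best_lag, best_score, best_pos = None, 0.0, 0
    win = unit
    for lag in range(unit - 9, unit + 10):
        if lag >= n:
            continue
        m = (arr[:-lag] == arr[lag:]).astype(np.float64)
        if len(m) < win:
            continue
        sm = np.convolve(m, np.ones(win) / win, mode="valid")
        i = int(np.argmax(sm))
        if sm[i] > best_score:
            best_lag, best_score, best_pos = lag, float(sm[i]), i

    if best_lag is None or best_score < SELF_MATCH_THRESHOLD:
        if unit_hint is not None:
            return _find_with_hint(cds, unit_hint, min_copy_identity, cds_id)
        return _empty_annotation(cds_id, n)

    # interior anchor copy: the window that best self-matches at the lag
    anchor = min(3 * round(best_pos / 3), n - unit)
    anchor_copy = arr[anchor: anchor + unit]
    tiled = anchor_copy[(np.arange(n) - anchor) % unit]
    t = (arr == tiled).astype(np.float64)
    b, e = _changepoint_bounds(t, anchor)

    k = max(1, round((e - b) / unit))
    if b + k * unit > n:
        k = (n - b) // unit
    if k < 1:
        return _empty_annotation(cds_id, n)
    copies = [(b + j * unit, b + (j + 1) * unit) for j in range(k)]
    seqs = [cds[s:ee] for s, ee in copies]
    # drop terminal copies that fall below the identity floor
    while len(seqs) > 1:
        cons = _consensus(seqs)
        if seq_identity(seqs[0], cons) < min_copy_identity:
            copies, seqs = copies[1:], seqs[1:]
        elif seq_identity(seqs[-1], cons) < min_copy_identity:
            copies, seqs = copies[:-1], seqs[:-1]
        else:
            break
    cons = _consensus(seqs)
    if len(seqs) == 1 and seq_identity(seqs[0], cons) < min_copy_identity:
        return _empty_annotation(cds_id, n)
    idents = [seq_identity(s, cons) for s in seqs]
    return RepeatAnnotation(
        cds_id, n, copies[0][0], copies[-1][1], copies, cons, idents
    )


def _find_with_hint(
    cds: str, hint: str, min_copy_identity: float, cds_id: str
) -> RepeatAnnotation:
    """Locate copies of a reference unit: best codon-aligned gap-free match,
    then tandem extension (handles k = 1)."""
    n, unit = len(cds), len(hint)
    best, best_m = None, -1
    for s in range(0, n - unit + 1, 3):
        m = sum(a == b for a, b in zip(cds[s: s + unit], hint))
        if m > best_m:
            best, best_m = s, m
    if best is None or 100.0 * best_m / unit < min_copy_identity:
        return _empty_annotation(cds_id, n)
    copies, seqs = _grow_array(cds, best, unit, min_copy_identity)
    cons = _consensus(seqs)
    idents = [seq_identity(s, cons) for s in seqs]
    return RepeatAnnotation(
        cds_id, n, copies[0][0], copies[-1][1], copies, cons, idents
    )


def build_virtual_cds(cds: str, annotation: RepeatAnnotation) -> VirtualCds:
    """Excise every repeat copy; remaining sequence concatenated in order.

    ``len(cds) == len(virtual) + sum(copy lengths)`` exactly; a k=0
    annotation returns the CDS unchanged.
    """
    if annotation.cds_length != len(cds):
        raise ValueError(
            f"annotation is for a CDS of length {annotation.cds_length}, "
            f"got {len(cds)}"
        )
    keep = np.ones(len(cds), dtype=bool)
    for s, e in annotation.copies:
        if not (0 <= s < e <= len(cds)):
            raise ValueError(f"copy interval ({s}, {e}) outside CDS bounds")
        keep[s:e] = False
    idx = np.flatnonzero(keep)
    virtual = "".join(cds[i] for i in idx)
    return VirtualCds(annotation.cds_id, virtual, coord_map=idx)


def partition_blocks(cds: str, annotation: RepeatAnnotation) -> BlockPartition:
    """pre / array / post blocks covering the CDS exactly (k >= 1 only)."""
    if annotation.k == 0:
        raise ValueError(
            "CDS has no repeat array (k=0); analyse it in whole-CDS mode"
        )
    if annotation.cds_length != len(cds):
        raise ValueError("annotation/CDS length mismatch")
    return BlockPartition(
        pre=(0, annotation.start),
        array=(annotation.start, annotation.end),
        post=(annotation.end, len(cds)),
    )


def repeat_consensus(annotations: list, cdss: dict) -> tuple[str, np.ndarray]:
    """Pooled unit consensus and per-position variability over a set of
    annotated CDSs.

    ``cdss`` maps cds_id -> sequence.  Copies are aligned by unit frame; the
    consensus is the per-position majority base over all pooled copies of
    modal length, the profile the per-position mismatch fraction.  Copies of
    non-modal length are logged and excluded from the gap-free vote.
    """
    pooled = []
    for ann in annotations:
        seq = cdss[ann.cds_id]
        for s, e in ann.copies:
            pooled.append(seq[s:e])
    if not pooled:
        raise ValueError("no repeat copies in the annotation set")
    lengths = [len(c) for c in pooled]
    modal = max(set(lengths), key=lengths.count)
    kept = [c for c in pooled if len(c) == modal]
    dropped = len(pooled) - len(kept)
    if dropped:
        logger.warning("%d non-modal-length copies excluded from consensus", dropped)
    arr = np.stack([encode(c) for c in kept])
    cons_idx = []
    for col in arr.T:
        vals, counts = np.unique(col, return_counts=True)
        cons_idx.append(vals[np.argmax(counts)])
    cons_idx = np.array(cons_idx)
    consensus = "".join("ACGTN"[i] for i in cons_idx)
    variability = (arr != cons_idx[None, :]).mean(axis=0)
    return consensus, variability
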