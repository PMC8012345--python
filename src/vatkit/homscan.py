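"""Homology scanning and gene-model assembly in genomic regions.

Finds copies of exon-derived query sequences in a genomic region by exact
k-mer seeding followed by alignment of each candidate window (edlib,
end-gap-free on the target), filters hits on percent identity and query
coverage, groups collinear same-strand hits into gene models with
splice-boundary (GT..AG) refinement, classifies each model
(intact / pseudo_stop / pseudo_insertion / partial), and extracts spliced
coding sequences.

The minus strand is scanned as the plus strand of the reverse-complemented
region and coordinates are mirrored back, so hit sets are strand-symmetric
by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._util import revcomp, translate

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 40.0   # %
DEFAULT_MIN_COVERAGE = 30.0   # % of query length aligned
DEFAULT_SEED_K = 12
DEFAULT_MAX_INTRON = 3000     # nt; hit-grouping distance
DEFAULT_INSERT_THRESHOLD = 2000   # nt; inter-exon gap above this => insertion
SPLICE_WINDOW = 30            # nt; GT/AG search window around hit boundaries
MIN_INTRON = 30               # gaps shorter than this are merged into one exon


@dataclass
class HomologyHit:
    query_id: str
    start: int            # region coordinates, 0-based half-open
    end: int
    strand: str           # '+' or '-'
    identity: float       # % over aligned columns
    coverage: float       # % of query aligned
    score: int            # aligned matches minus edits


@dataclass
class VatGeneModel:
    locus_id: str
    exons: list           # [(start, end), ...] ascending region coords
    strand: str
    cds: str = ""
    class_: str = "partial"
    evidence: list = field(default_factory=list)   # hits used

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict:
    idx: dict[str, list] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i: i + k], []).append(i)
    return idx


MIN_WINDOW_SEEDS = 2   # a lone random k-mer match never seeds an alignment
DIAG_BAND = 100        # diagonals this close support the same alignment


def _candidate_windows(region_idx: dict, query: str, k: int, qlen: int) -> list:
    """Cluster seed diagonals into candidate target windows.

    Seeds are counted within diagonal bands (indels shift the diagonal only
    slightly); bands with fewer than MIN_WINDOW_SEEDS seeds are discarded —
    scattered random k-mer matches never seed an alignment.
    """
    diag_seeds: dict[int, int] = {}
    for j in range(0, qlen - k + 1):
        for pos in region_idx.get(query[j: j + k], ()):
            d = pos - j
            diag_seeds[d] = diag_seeds.get(d, 0) + 1
    bands: list[list[int]] = []   # [min_diag, max_diag, count]
    for diag in sorted(diag_seeds):
        if bands and diag - bands[-1][1] <= DIAG_BAND:
            bands[-1][1] = diag
            bands[-1][2] += diag_seeds[diag]
        else:
            bands.append([diag, diag, diag_seeds[diag]])
    slack = max(qlen // 5, 50)
    windows: list[list[int]] = []
    for lo, hi, c in bands:
        if c < MIN_WINDOW_SEEDS:
            continue
        s, e = max(0, lo - slack), hi + qlen + slack
        if windows and s <= windows[-1][1]:
            windows[-1][1] = max(windows[-1][1], e)
        else:
            windows.append([s, e])
    return [(s, e) for s, e in windows]


def _align_window(query: str, target: str, offset: int, qid: str, strand: str,
                  min_identity: float, min_coverage: float) -> HomologyHit | None:
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    cigar = res["cigar"] or ""
    cols = matches = q_aligned = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        cols += n
        if ch == "=":
            matches += n
            q_aligned += n
        elif ch == "X":
            q_aligned += n
        elif ch == "I":      # insertion relative to target: query-only columns
            q_aligned += n
    if cols == 0:
        return None
    identity = 100.0 * matches / cols
    coverage = 100.0 * q_aligned / len(query)
    score = matches - (cols - matches)
    # net-score floor: an unconstrained edit alignment of unrelated sequence
    # still attains ~50% column identity, but its net score stays near zero
    if identity < min_identity or coverage < min_coverage or score < 0.25 * len(query):
        return None
    start, end = offset + loc[0], offset + loc[1] + 1
    return HomologyHit(qid, start, end, strand,
                       round(identity, 3), round(coverage, 3),
                       matches - (cols - matches))


def scan_region(
    region: str,
    queries: dict,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    seed_k: int = DEFAULT_SEED_K,
) -> list:
    """Search both strands of ``region`` for every query sequence.

    ``queries`` maps query id -> sequence.  Returns hits sorted by region
    position; hits below either the identity or the coverage threshold are
    removed.
    """
    if seed_k < 8:
        raise ValueError("seed_k must be >= 8")
    if not region or not queries or any(not q for q in queries.values()):
        raise ValueError("region and queries must be non-empty")
    region = region.upper()
    if set(region) <= {"N"}:
        logger.warning("region is all-N; no hits possible")
        return []

    hits: list[HomologyHit] = []
    n = len(region)
    for strand, seq in (("+", region), ("-", revcomp(region))):
        idx = _kmer_index(seq, seed_k)
        for qid, q in queries.items():
            q = q.upper()
            for s, e in _candidate_windows(idx, q, seed_k, len(q)):
                h = _align_window(q, seq[s: min(e, n)], s, qid, strand,
                                  min_identity, min_coverage)
                if h is None:
                    continue
                if strand == "-":
                    h.start, h.end = n - h.end, n - h.start
                hits.append(h)
    # deduplicate overlapping calls of the same query (keep best score)
    hits.sort(key=lambda h: (h.query_id, h.strand, h.start, -h.score))
    dedup: list[HomologyHit] = []
    for h in hits:
        prev = dedup[-1] if dedup else None
        if (
            prev
            and prev.query_id == h.query_id
            and prev.strand == h.strand
            and h.start < prev.end
        ):
            if h.score > prev.score:
                dedup[-1] = h
            continue
        dedup.append(h)
    dedup.sort(key=lambda h: (h.start, h.end))
    return dedup


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


def _refine_boundary(region: str, pos: int, motif: str, anchor: str) -> int | None:
    """Nearest position within +/- SPLICE_WINDOW where the splice motif sits.

    ``anchor='donor'`` looks for GT at region[p:p+2] (p = exon end);
    ``anchor='acceptor'`` looks for AG at region[p-2:p] (p = exon start).
    """
    best = None
    for d in sorted(range(-SPLICE_WINDOW, SPLICE_WINDOW + 1), key=abs):
        p = pos + d
        if anchor == "donor":
            if 0 <= p <= len(region) - 2 and region[p: p + 2] == motif:
                best = p
                break
        else:
            if 2 <= p <= len(region) and region[p - 2: p] == motif:
                best = p
                break
    return best


def assemble_models(
    hits: list,
    region: str,
    max_intron: int = DEFAULT_MAX_INTRON,
    linked_queries: set | None = None,
    insert_threshold: int = DEFAULT_INSERT_THRESHOLD,
) -> list:
    """Group collinear same-strand hits into gene models.

    Hits on the same strand within ``max_intron`` of each other form one
    locus.  The gap between consecutive hits becomes an intron when GT..AG
    splice motifs are found within +/-30 nt of the hit boundaries;
    otherwise the hits are bridged into one exon, unless the gap exceeds
    ``insert_threshold`` (insertion evidence, kept as separate exons).
    ``linked_queries`` marks ordered query-id pairs that flank a single
    exon (e.g. the two repeat-free flanks of the array-bearing exon) and
    are always bridged.  Loci on opposite strands are never merged.
    """
    linked = linked_queries or set()
    region = region.upper()
    models: list[VatGeneModel] = []
    for strand in ("+", "-"):
        sh = sorted((h for h in hits if h.strand == strand), key=lambda h: h.start)
        group: list[HomologyHit] = []
        groups: list[list[HomologyHit]] = []
        for h in sh:
            if group and h.start - group[-1].end > max_intron:
                groups.append(group)
                group = []
            group.append(h)
        if group:
            groups.append(group)
        for g in groups:
            exons: list[list[int]] = [[g[0].start, g[0].end]]
            prev = g[0]
            for h in g[1:]:
                if h.start <= exons[-1][1]:     # overlapping hits: one exon
                    exons[-1][1] = max(exons[-1][1], h.end)
                    prev = h
                    continue
                pair = (
                    (prev.query_id, h.query_id)
                    if strand == "+"
                    else (h.query_id, prev.query_id)
                )
                gap = h.start - exons[-1][1]
                if gap < MIN_INTRON:            # alignment-end wobble, not an intron
                    exons[-1][1] = h.end
                    prev = h
                    continue
                donor = acceptor = None
                if pair not in linked:
                    # minus-strand introns read CT..AC on the plus strand
                    d_motif, a_motif = ("GT", "AG") if strand == "+" else ("CT", "AC")
                    donor = _refine_boundary(region, exons[-1][1], d_motif, "donor")
                    acceptor = _refine_boundary(region, h.start, a_motif, "acceptor")
                if (
                    pair not in linked
                    and donor is not None
                    and acceptor is not None
                    and acceptor - donor >= MIN_INTRON
                ):
                    exons[-1][1] = donor
                    exons.append([acceptor, h.end])
                elif pair not in linked and gap > insert_threshold:
                    exons.append([h.start, h.end])   # unspliceable long gap
                else:
                    exons[-1][1] = h.end             # bridge: same exon
                prev = h
            models.append(
                VatGeneModel(
                    locus_id="",
                    exons=[tuple(e) for e in exons],
                    strand=strand,
                    evidence=list(g),
                )
            )
    models.sort(key=lambda m: m.span)
    for i, m in enumerate(models, 1):
        m.locus_id = f"model{i}"
    return models


TERMINUS_WINDOW = 12   # nt; search range for start/stop codon refinement


def refine_termini(model: VatGeneModel, region: str) -> None:
    """Snap the model's outer boundaries to a start codon and an in-frame
    stop codon within a small window, compensating alignment-end wobble.

    Mirrors manual curation against a reference CDS: the 5' boundary is
    moved to the nearest ATG, then the 3' boundary to the nearest position
    giving an in-frame terminal stop.  Boundaries are left untouched when
    no candidate exists in the window.
    """
    exons = [list(e) for e in model.exons]
    n = len(region)

    def spliced_len():
        return sum(e - s for s, e in exons)

    if model.strand == "+":
        s0 = exons[0][0]
        for d in sorted(range(-TERMINUS_WINDOW, TERMINUS_WINDOW + 1), key=abs):
            p = s0 + d
            if 0 <= p <= n - 3 and region[p: p + 3] == "ATG":
                exons[0][0] = p
                break
        e_last = exons[-1][1]
        for d in sorted(range(-TERMINUS_WINDOW, TERMINUS_WINDOW + 1), key=abs):
            p = e_last + d
            if not (exons[-1][0] + 3 <= p <= n):
                continue
            exons[-1][1] = p
            if spliced_len() % 3 == 0 and region[p - 3: p] in ("TAA", "TAG", "TGA"):
                break
            exons[-1][1] = e_last
    else:
        e0 = exons[-1][1]   # gene 5' end
        for d in sorted(range(-TERMINUS_WINDOW, TERMINUS_WINDOW + 1), key=abs):
            p = e0 + d
            if 3 <= p <= n and region[p - 3: p] == "CAT":   # revcomp(ATG)
                exons[-1][1] = p
                break
        s_last = exons[0][0]   # gene 3' end
        for d in sorted(range(-TERMINUS_WINDOW, TERMINUS_WINDOW + 1), key=abs):
            p = s_last + d
            if not (0 <= p <= exons[0][1] - 3):
                continue
            exons[0][0] = p
            if spliced_len() % 3 == 0 and region[p: p + 3] in ("TTA", "CTA", "TCA"):
                break
            exons[0][0] = s_last
    model.exons = [tuple(e) for e in exons]


# ---------------------------------------------------------------------------
# classification and CDS extraction
# ---------------------------------------------------------------------------


def extract_cds(model: VatGeneModel, region: str) -> str:
    """Spliced CDS of a model; reverse-complemented for minus-strand loci
    so the result reads 5'->3' of the gene."""
    if not model.exons:
        raise ValueError("model has no exons")
    for s, e in model.exons:
        if not (0 <= s < e <= len(region)):
            raise ValueError(f"exon ({s}, {e}) outside region bounds")
    spliced = "".join(region[s:e] for s, e in model.exons)
    return revcomp(spliced) if model.strand == "-" else spliced


def classify_locus(
    model: VatGeneModel,
    region: str,
    required_queries: set | None = None,
    insert_threshold: int = DEFAULT_INSERT_THRESHOLD,
) -> str:
    """Classify a gene model.

    partial            a required exon query has no hit in the model;
    pseudo_insertion   an inter-exon gap exceeds ``insert_threshold``
                       (ordinary introns are shorter; TE inserts are not);
    pseudo_stop        the spliced frame contains an internal stop;
    intact             complete ORF (ATG .. stop, frame-length, no internal
                       stop).
    """
    if required_queries:
        found = {h.query_id for h in model.evidence}
        if not required_queries <= found:
            return "partial"
    gaps = [
        model.exons[i + 1][0] - model.exons[i][1]
        for i in range(len(model.exons) - 1)
    ]
    if any(g > insert_threshold for g in gaps):
        return "pseudo_insertion"
    cds = extract_cds(model, region)
    aa = translate(cds)
    if "*" in aa[:-1]:
        return "pseudo_stop"
    if cds[:3] == "ATG" and len(cds) % 3 == 0 and aa.endswith("*"):
        return "intact"
    return "partial"


def scan_and_annotate(
    region: str,
    queries: dict,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_intron: int = DEFAULT_MAX_INTRON,
    insert_threshold: int = DEFAULT_INSERT_THRESHOLD,
    required_queries: set | None = None,
    linked_queries: set | None = None,
) -> list:
    """scan_region + assemble_models + classify + extract, in one call."""
    hits = scan_region(region, queries, min_identity, min_coverage)
    models = assemble_models(hits, region, max_intron, linked_queries, insert_threshold)
    for m in models:
        refine_termini(m, region)
        m.class_ = classify_locus(m, region, required_queries, insert_threshold)
        m.cds = extract_cds(m, region)
    return models
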