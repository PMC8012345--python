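"""Ground-truthed simulator of NLR (Vat-like) gene clusters.

The simulator emulates the architecture of a melon-type resistance-gene
cluster: a five-exon/four-intron CC-NLR gene whose second exon carries a
tandem array of k near-identical 195-nt repeat units (65 codons each, the
"R65aa" unit of the LRR2 domain), embedded in a genomic region together with
marker anchors and primer-binding sites.  Lineages diversify by gene
duplication, unequal-crossover gain/loss of repeat units, transposable-element
insertion (pseudogenisation), premature-stop gain, point substitution with an
elevated nonsynonymous acceptance inside a sub-window of the repeat unit, and
one optional retrotransposed reverse-strand copy (intron-less, mirroring an
mRNA copy-paste origin).

Geometry is chosen so that in-silico PCR on emitted regions reproduces the
closed-form amplicon arithmetic of the four diagnostic primer classes:

* repeat-spanning (intron-anchored):      572 + 195*k
* exon-2 internal:                        272 + 195*k   (467 for k=1)
* exon1-exon2 (intron-1 spanning):       1307 + 195*k   (1502 for k=1,
                                          +2345 for the insertion pseudo-class,
                                          i.e. 3847 for k=1)
* reverse-strand exon-1 pair:             933

All coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import (
    BASES,
    CODON_TABLE,
    STOP_CODONS,
    random_orf_codons,
    random_seq,
    revcomp,
    translate,
)

# ---------------------------------------------------------------------------
# fixed gene geometry (nt)
# ---------------------------------------------------------------------------

E1_LEN = 2306          # coding part of exon 1 (CC-NBS-ARC-LRR1)
FLANK = 136            # exon-2 coding flank on each side of the repeat array
PRE_LEN = E1_LEN + FLANK          # CDS nt before the repeat array (2442)
E3_LEN = 400
E4_LEN = 400
INTRON_LENS = (400, 400, 300, 300)
PRIMER_LEN = 20
Z649F_SITE = (250, 270)    # within intron 1; 150 nt from its 3' end
Z649R_SITE = (130, 150)    # within intron 2
Z5895F_CDS = (1671, 1691)  # within exon-1 coding; 635 nt from its 3' end
Z5474F_CDS = (1373, 1393)  # retro-specific sites at the end of "exon 1"
Z5474R_CDS = (2286, 2306)
TE_EXON1_LEN = 2345        # insertion class inflating the exon1-exon2 product
TE_EXON1_POS = 260         # offset in intron 1 -- splits the Z649F site
TE_LINE1_LEN = 2540        # LINE-1-like class
TE_LINE1_END_OFFSET = 10   # inserted this many nt before the exon-2 end

DEFAULT_AMPLICON_CONSTANTS = {
    "repeat_spanning": 572,
    "exon2_internal": 272,
    "exon1_exon2": 1307,
    "reverse_strand_exon1": 933,
    "insertion_offset": TE_EXON1_LEN,
}

CLASSES = ("intact", "pseudo_stop", "pseudo_insertion", "partial")


class SimConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


# ---------------------------------------------------------------------------
# configuration and domain types
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for a simulated accession panel.

    Rates are events per gene lineage per unit time; ``sub_rate`` is
    substitutions proposed per site per unit time.  ``nonsyn_hot_window``
    is a 1-based inclusive codon interval within the repeat unit where
    proposed nonsynonymous changes are accepted ``nonsyn_hot_factor`` times
    more readily than the ``nonsyn_background`` acceptance elsewhere.
    """

    seed: int = 0
    n_accessions: int = 80
    ancestor_repeat_count: int = 4
    unit_nt: int = 195
    duplication_rate: float = 1.4
    crossover_rate: float = 1.0
    te_insertion_rate: float = 0.3
    stop_gain_rate: float = 0.1
    sub_rate: float = 0.01
    nonsyn_hot_window: tuple[int, int] = (25, 35)
    nonsyn_hot_factor: float = 5.0
    # background acceptance of proposed nonsynonymous changes; 0.2 keeps the
    # default x5 hot factor exactly representable (0.2 * 5 = 1.0, no cap)
    nonsyn_background: float = 0.2
    tree_height: float = 1.0
    retro_copy: bool = True
    ref_protein_len: int = 1467   # protein length (aa) of the k=4 reference
    te_len_jitter: int = 0
    amplicon_constants: dict = field(
        default_factory=lambda: dict(DEFAULT_AMPLICON_CONSTANTS)
    )

    def validate(self) -> None:
        if self.n_accessions < 1:
            raise SimConfigError("n_accessions must be >= 1")
        if not 1 <= self.ancestor_repeat_count <= 7:
            raise SimConfigError("ancestor_repeat_count must be in [1, 7]")
        if self.unit_nt % 3 != 0 or self.unit_nt < 9:
            raise SimConfigError("unit_nt must be a positive multiple of 3")
        for name in (
            "duplication_rate",
            "crossover_rate",
            "te_insertion_rate",
            "stop_gain_rate",
            "sub_rate",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        lo, hi = self.nonsyn_hot_window
        if not (1 <= lo <= hi <= self.unit_nt // 3):
            raise SimConfigError("nonsyn_hot_window must lie within [1, unit_nt/3]")
        if self.nonsyn_hot_factor < 1:
            raise SimConfigError("nonsyn_hot_factor must be >= 1")
        if not 0 <= self.nonsyn_background <= 1:
            raise SimConfigError("nonsyn_background must be in [0, 1]")
        if self.tree_height < 0:
            raise SimConfigError("tree_height must be >= 0")
        coding_nt = 3 * (self.ref_protein_len + 1)
        post = coding_nt - 4 * self.unit_nt - PRE_LEN
        if post - FLANK - E3_LEN - E4_LEN < 30:
            raise SimConfigError("ref_protein_len too small for the exon layout")

    @property
    def post_len(self) -> int:
        """CDS nt after the repeat array (includes the stop codon)."""
        return 3 * (self.ref_protein_len + 1) - 4 * self.unit_nt - PRE_LEN

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise SimConfigError(f"unknown config field(s): {sorted(bad)}")
        if "nonsyn_hot_window" in data:
            data["nonsyn_hot_window"] = tuple(data["nonsyn_hot_window"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class EvolutionEvent:
    kind: str          # duplication | crossover_gain | crossover_loss |
                       # substitution | te_insertion | stop_gain | retro_copy_reverse
    lineage: str
    time: float
    detail: dict = field(default_factory=dict)


@dataclass
class Locus:
    """One gene lineage: spliced CDS + intron sequences + event history."""

    locus_id: str
    cds: str
    introns: list | None          # 4 intron sequences; None for the retro copy
    k: int
    class_: str = "intact"
    is_retro: bool = False
    te_insertions: list = field(default_factory=list)   # [(site, seq), ...]
    events: list = field(default_factory=list)

    def clone(self, new_id: str) -> "Locus":
        c = copy.deepcopy(self)
        c.locus_id = new_id
        return c


@dataclass
class TruthLocus:
    """A located gene model in an emitted region (region coordinates)."""

    locus_id: str
    start: int
    end: int
    strand: str
    class_: str
    k: int
    exons: list            # [(start, end), ...] ascending region coords
    cds: str
    is_retro: bool = False


@dataclass
class SimulatedRegion:
    accession: str
    sequence: str
    loci: list             # list[TruthLocus]
    anchors: dict          # {"M5": (s, e), "M4": (s, e)}


@dataclass
class AncestralGene:
    locus: Locus
    unit: str
    config: SimConfig
    te_exon1: str
    te_line1: str
    retro_tag_f: str       # Z5474F site content planted in the retro copy
    retro_tag_r: str       # Z5474R site content
    retro_scramble: str    # replaces the Z5895F site in the retro copy

    @property
    def protein_length(self) -> int:
        return len(translate(self.locus.cds)) - 1  # minus the stop


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _exon_coding_lengths(k: int, cfg: SimConfig) -> list[int]:
    e2 = 2 * FLANK + cfg.unit_nt * k
    e5 = cfg.post_len - FLANK - E3_LEN - E4_LEN
    return [E1_LEN, e2, E3_LEN, E4_LEN, e5]


def _cds_array_interval(k: int, cfg: SimConfig) -> tuple[int, int]:
    return PRE_LEN, PRE_LEN + cfg.unit_nt * k


def build_gene(locus: Locus, cfg: SimConfig) -> tuple[str, list, tuple]:
    """Assemble the genomic gene sequence of a locus.

    Returns ``(gene_seq, exon_intervals, array_interval)`` in gene-local
    coordinates.  Exon intervals are the structural exon spans (a TE inserted
    inside exon 2 inflates that span).  For the intron-less retro copy the
    gene is the CDS itself with a single exon.
    """
    te = dict(locus.te_insertions)
    if locus.is_retro:
        seq = locus.cds
        if "exon2_end" in te:
            e2_end_cds = PRE_LEN + cfg.unit_nt * locus.k + FLANK
            pos = e2_end_cds - TE_LINE1_END_OFFSET
            seq = seq[:pos] + te["exon2_end"] + seq[pos:]
        return seq, [(0, len(seq))], _cds_array_interval(locus.k, cfg)

    lens = _exon_coding_lengths(locus.k, cfg)
    bounds = np.cumsum([0] + lens)
    exon_seqs = [locus.cds[bounds[i]: bounds[i + 1]] for i in range(5)]
    introns = list(locus.introns)
    if "intron1" in te:
        introns[0] = introns[0][:TE_EXON1_POS] + te["intron1"] + introns[0][TE_EXON1_POS:]
    if "exon2_end" in te:
        e2 = exon_seqs[1]
        pos = len(e2) - TE_LINE1_END_OFFSET
        exon_seqs[1] = e2[:pos] + te["exon2_end"] + e2[pos:]

    parts, exons, cursor = [], [], 0
    array_iv = None
    for i in range(5):
        parts.append(exon_seqs[i])
        exons.append((cursor, cursor + len(exon_seqs[i])))
        if i == 1:
            a0, a1 = _cds_array_interval(locus.k, cfg)
            array_iv = (a0 - bounds[1] + cursor, a1 - bounds[1] + cursor)
        cursor += len(exon_seqs[i])
        if i < 4:
            parts.append(introns[i])
            cursor += len(introns[i])
    return "".join(parts), exons, array_iv


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------


def _stopfree_plant(cds: str, start: int, end: int, repl: str) -> bool:
    """Would replacing cds[start:end] by repl keep the frame stop-free?"""
    new = cds[:start] + repl + cds[end:]
    c0 = 3 * (start // 3)
    c1 = 3 * ((end + 2) // 3)
    return all(
        new[i: i + 3] not in STOP_CODONS for i in range(c0, min(c1, len(new) - 3), 3)
    )


def make_ancestor(config: SimConfig, rng: np.random.Generator | None = None) -> AncestralGene:
    """Build the ancestral gene: 5 exons / 4 introns, exon 2 carrying
    ``ancestor_repeat_count`` tandem copies of one ``unit_nt`` repeat unit.

    The CDS is a complete ORF (ATG ... stop); with the default geometry the
    k=4 ancestor translates to a 1467-aa protein.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k0 = config.ancestor_repeat_count
    unit_codons = config.unit_nt // 3

    # repeat unit: sense codons only, and unit must not start GT / end AG so
    # that the array boundary is never mistaken for a splice site downstream
    while True:
        unit = random_orf_codons(rng, unit_codons)
        if not unit.startswith("GT") and not unit.endswith("AG"):
            break

    pre = "ATG" + random_orf_codons(rng, PRE_LEN // 3 - 1)
    post = random_orf_codons(rng, config.post_len // 3 - 1) + "TAA"
    cds = pre + unit * k0 + post

    introns = [
        "GT" + random_seq(rng, n - 4) + "AG" for n in INTRON_LENS
    ]
    te_exon1 = random_seq(rng, TE_EXON1_LEN)
    te_line1 = random_seq(rng, TE_LINE1_LEN)

    def _divergent_20mer(site: tuple[int, int]) -> str:
        ref = cds[site[0]: site[1]]
        while True:
            cand = random_seq(rng, PRIMER_LEN)
            ham = sum(a != b for a, b in zip(cand, ref))
            if ham >= 8 and _stopfree_plant(cds, site[0], site[1], cand):
                return cand

    tag_f = _divergent_20mer(Z5474F_CDS)
    tag_r = _divergent_20mer(Z5474R_CDS)
    scramble = _divergent_20mer(Z5895F_CDS)

    locus = Locus(locus_id="L1", cds=cds, introns=introns, k=k0)
    return AncestralGene(
        locus=locus,
        unit=unit,
        config=config,
        te_exon1=te_exon1,
        te_line1=te_line1,
        retro_tag_f=tag_f,
        retro_tag_r=tag_r,
        retro_scramble=scramble,
    )


def ancestor_queries(anc: AncestralGene) -> dict[str, str]:
    """Exon-derived homology-search queries (repeat array excluded).

    ``e2L``/``e2R`` are the repeat-free exon-2 flanks; the array itself is
    annotated downstream by the repeat finder, as in manual curation against
    a reference gene.
    """
    cfg = anc.config
    cds = anc.locus.cds
    lens = _exon_coding_lengths(anc.locus.k, cfg)
    b = np.cumsum([0] + lens)
    a0, a1 = _cds_array_interval(anc.locus.k, cfg)
    return {
        "e1": cds[b[0]: b[1]],
        "e2L": cds[b[1]: a0],
        "e2R": cds[a1: b[2]],
        "e3": cds[b[2]: b[3]],
        "e4": cds[b[3]: b[4]],
        "e5": cds[b[4]: b[5]],
    }


def panel_primers(anc: AncestralGene):
    """The four diagnostic primer pairs, taken verbatim from ancestral sites."""
    from .pcrinfer import PrimerPair

    cfg = anc.config
    cds = anc.locus.cds
    introns = anc.locus.introns
    a1 = PRE_LEN + cfg.unit_nt * anc.locus.k
    e2_end = a1 + FLANK
    z649f = introns[0][Z649F_SITE[0]: Z649F_SITE[1]]
    z649r = revcomp(introns[1][Z649R_SITE[0]: Z649R_SITE[1]])
    z6097f = cds[E1_LEN: E1_LEN + PRIMER_LEN]
    z6095r = revcomp(cds[e2_end - PRIMER_LEN: e2_end])
    z5895f = cds[Z5895F_CDS[0]: Z5895F_CDS[1]]
    z5474f = anc.retro_tag_f
    z5474r = revcomp(anc.retro_tag_r)
    return [
        PrimerPair("Z649FR", z649f, z649r, 2500, "repeat_spanning"),
        PrimerPair("Z6097F/Z6095R", z6097f, z6095r, 2000, "exon2_internal"),
        PrimerPair("Z5895FR", z5895f, z6095r, 6000, "exon1_exon2"),
        PrimerPair("Z5474FR", z5474f, z5474r, 1500, "reverse_strand_exon1"),
    ]


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------


def _mutate_te(master: str, rng: np.random.Generator, jitter: int) -> str:
    """A fresh TE copy: >= 99.8%-identical to the master (recent, active)."""
    seq = list(master)
    n = rng.poisson(0.001 * len(seq))
    for pos in rng.integers(0, len(seq), size=n):
        seq[pos] = BASES[(BASES.index(seq[pos]) + rng.integers(1, 4)) % 4]
    out = "".join(seq)
    if jitter:
        d = int(rng.integers(-jitter, jitter + 1))
        out = out[: len(out) + d] if d < 0 else out + "".join(
            BASES[i] for i in rng.integers(0, 4, size=d)
        )
    return out


def _hot_window_contains(pos: int, locus: Locus, cfg: SimConfig) -> bool:
    a0 = PRE_LEN
    a1 = PRE_LEN + cfg.unit_nt * locus.k
    if not a0 <= pos < a1:
        return False
    codon_in_unit = ((pos - a0) % cfg.unit_nt) // 3 + 1
    lo, hi = cfg.nonsyn_hot_window
    return lo <= codon_in_unit <= hi


def _apply_substitutions(
    locus: Locus, dt: float, cfg: SimConfig, rng: np.random.Generator, t: float
) -> None:
    if cfg.sub_rate == 0 or dt <= 0:
        return
    cds = list(locus.cds)
    n = rng.poisson(cfg.sub_rate * len(cds) * dt)
    for _ in range(n):
        pos = int(rng.integers(0, len(cds)))
        if pos < 3 or pos >= len(cds) - 3:
            continue  # start and stop codons are conserved
        old = cds[pos]
        new = BASES[(BASES.index(old) + int(rng.integers(1, 4))) % 4]
        c0 = 3 * (pos // 3)
        codon = cds[c0: c0 + 3]
        newcodon = list(codon)
        newcodon[pos - c0] = new
        newcodon = "".join(newcodon)
        if newcodon in STOP_CODONS:
            continue  # premature stops arise only via the stop_gain event
        if CODON_TABLE["".join(codon)] != CODON_TABLE[newcodon]:
            p = cfg.nonsyn_background
            if _hot_window_contains(pos, locus, cfg):
                p = min(1.0, p * cfg.nonsyn_hot_factor)
            if rng.random() >= p:
                continue
        cds[pos] = new
        locus.events.append(
            EvolutionEvent("substitution", locus.locus_id, t, {"pos": pos})
        )
    locus.cds = "".join(cds)

    if locus.introns is not None:
        new_introns = []
        for iseq in locus.introns:
            s = list(iseq)
            m = rng.poisson(cfg.sub_rate * len(s) * dt)
            for _ in range(m):
                pos = int(rng.integers(0, len(s)))
                if pos < 2 or pos >= len(s) - 2:
                    continue  # GT..AG splice dinucleotides are conserved
                s[pos] = BASES[(BASES.index(s[pos]) + int(rng.integers(1, 4))) % 4]
            new_introns.append("".join(s))
        locus.introns = new_introns


def _apply_crossover(locus: Locus, cfg: SimConfig, rng, t: float, log: list) -> None:
    dk = int(rng.choice([-1, 1]))
    if locus.k + dk < 1:
        dk = 1
    elif locus.k + dk > 7:
        dk = -1
    a0 = PRE_LEN
    u = cfg.unit_nt
    if dk == 1:
        locus.cds = locus.cds[:a0] + locus.cds[a0: a0 + u] + locus.cds[a0:]
        kind = "crossover_gain"
    else:
        locus.cds = locus.cds[:a0] + locus.cds[a0 + u:]
        kind = "crossover_loss"
    locus.k += dk
    ev = EvolutionEvent(kind, locus.locus_id, t, {"dk": dk, "k": locus.k})
    locus.events.append(ev)
    log.append(ev)


def _apply_te(locus: Locus, anc: AncestralGene, cfg, rng, t: float, log: list) -> None:
    if locus.te_insertions:
        return  # at most one insertion per locus (keeps band decoding defined)
    if locus.is_retro:
        te_class, site = "line1", "exon2_end"
        seq = _mutate_te(anc.te_line1, rng, cfg.te_len_jitter)
    elif rng.random() < 0.5:
        te_class, site = "exon1_class", "intron1"
        seq = _mutate_te(anc.te_exon1, rng, cfg.te_len_jitter)
    else:
        te_class, site = "line1", "exon2_end"
        seq = _mutate_te(anc.te_line1, rng, cfg.te_len_jitter)
    locus.te_insertions.append((site, seq))
    # an insertion is structurally decisive: it dominates a prior stop gain
    locus.class_ = "pseudo_insertion"
    ev = EvolutionEvent(
        "te_insertion", locus.locus_id, t,
        {"class": te_class, "site": site, "length": len(seq)},
    )
    locus.events.append(ev)
    log.append(ev)


def _apply_stop_gain(locus: Locus, rng, t: float, log: list) -> None:
    n_codons = len(locus.cds) // 3
    codon = int(rng.integers(10, n_codons - 10))
    locus.cds = locus.cds[: 3 * codon] + "TAA" + locus.cds[3 * codon + 3:]
    if locus.class_ == "intact":
        locus.class_ = "pseudo_stop"
    ev = EvolutionEvent("stop_gain", locus.locus_id, t, {"codon": codon})
    locus.events.append(ev)
    log.append(ev)


def _make_retro(anc: AncestralGene, t: float, log: list) -> Locus:
    cfg = anc.config
    cds = anc.locus.cds
    k0 = anc.locus.k
    # reduce to one repeat unit, drop introns (retrotransposed mRNA copy)
    a0, u = PRE_LEN, cfg.unit_nt
    cds = cds[:a0 + u] + cds[a0 + u * k0:]
    cds = cds[: Z5474F_CDS[0]] + anc.retro_tag_f + cds[Z5474F_CDS[1]:]
    cds = cds[: Z5474R_CDS[0]] + anc.retro_tag_r + cds[Z5474R_CDS[1]:]
    cds = cds[: Z5895F_CDS[0]] + anc.retro_scramble + cds[Z5895F_CDS[1]:]
    retro = Locus(locus_id="LR", cds=cds, introns=None, k=1, is_retro=True)
    ev = EvolutionEvent("retro_copy_reverse", "LR", t, {"source": anc.locus.locus_id})
    retro.events.append(ev)
    log.append(ev)
    return retro


def evolve_cluster(
    anc: AncestralGene, config: SimConfig, rng: np.random.Generator
) -> tuple[list, list]:
    """Evolve one accession's cluster from the ancestor.

    Returns ``(loci, events)``: the final locus set (each locus carrying its
    own event log) and the flat chronological event list.  Structural events
    are drawn from a continuous-time jump process; substitutions accumulate
    along each lineage between jumps, so duplicated loci share their
    pre-duplication substitution history.
    """
    config.validate()
    log: list[EvolutionEvent] = []
    lineages = [anc.locus.clone("L1")]
    if config.retro_copy:
        lineages.append(_make_retro(anc, 0.0, log))
    next_id = 2
    per_locus = (
        config.duplication_rate
        + config.crossover_rate
        + config.te_insertion_rate
        + config.stop_gain_rate
    )
    t = 0.0
    T = config.tree_height
    while True:
        total = per_locus * len(lineages)
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t + dt >= T:
            for lo in lineages:
                _apply_substitutions(lo, T - t, config, rng, T)
            break
        for lo in lineages:
            _apply_substitutions(lo, dt, config, rng, t + dt)
        t += dt
        lo = lineages[int(rng.integers(0, len(lineages)))]
        r = rng.random() * per_locus
        if lo.is_retro and r < config.duplication_rate + config.crossover_rate:
            continue  # the isolated retro copy neither duplicates in tandem
                      # nor has a mispairing partner for unequal crossover
        if r < config.duplication_rate:
            child = lo.clone(f"L{next_id}")
            next_id += 1
            ev = EvolutionEvent("duplication", lo.locus_id, t, {"child": child.locus_id})
            lo.events.append(ev)
            child.events.append(ev)
            log.append(ev)
            lineages.append(child)
        elif r < config.duplication_rate + config.crossover_rate:
            if not lo.is_retro:   # the isolated retro copy has no tandem partner
                _apply_crossover(lo, config, rng, t, log)
        elif r < config.duplication_rate + config.crossover_rate + config.te_insertion_rate:
            _apply_te(lo, anc, config, rng, t, log)
        else:
            _apply_stop_gain(lo, rng, t, log)
    return lineages, log


# ---------------------------------------------------------------------------
# region emission and panel simulation
# ---------------------------------------------------------------------------

ANCHOR_LEN = 300
SPACER_LEN = 5000     # intergenic spacing; well above any intron-grouping span


def emit_region(
    loci: list, config: SimConfig, accession: str = "acc1"
) -> SimulatedRegion:
    """Lay the locus set out on a genomic region between M5/M4-like anchors.

    Forward loci are placed in lineage order on the plus strand; the retro
    copy (if present) is placed last, reverse-complemented, just before the
    M4 anchor.  Anchor and spacer sequences are drawn from a layout RNG
    keyed only on the config seed, so accessions with identical locus sets
    yield identical regions.
    """
    layout_rng = np.random.default_rng([config.seed, 7])
    m5 = random_seq(layout_rng, ANCHOR_LEN)
    m4 = random_seq(layout_rng, ANCHOR_LEN)
    forward = [lo for lo in loci if not lo.is_retro]
    retro = [lo for lo in loci if lo.is_retro]

    parts = [m5]
    cursor = ANCHOR_LEN
    truth: list[TruthLocus] = []
    for lo in forward + retro:
        spacer = random_seq(layout_rng, SPACER_LEN)
        parts.append(spacer)
        cursor += SPACER_LEN
        gene, exons, _ = build_gene(lo, config)
        if lo.is_retro:
            gene_out = revcomp(gene)
            n = len(gene)
            exons_abs = sorted(
                (cursor + n - e, cursor + n - s) for s, e in exons
            )
            strand = "-"
        else:
            gene_out = gene
            exons_abs = [(cursor + s, cursor + e) for s, e in exons]
            strand = "+"
        parts.append(gene_out)
        truth.append(
            TruthLocus(
                locus_id=lo.locus_id,
                start=cursor,
                end=cursor + len(gene),
                strand=strand,
                class_=lo.class_,
                k=lo.k,
                exons=exons_abs,
                cds=lo.cds,
                is_retro=lo.is_retro,
            )
        )
        cursor += len(gene)
    tail_spacer = random_seq(layout_rng, SPACER_LEN)
    parts.append(tail_spacer)
    cursor += SPACER_LEN
    parts.append(m4)
    seq = "".join(parts)
    anchors = {"M5": (0, ANCHOR_LEN), "M4": (cursor, cursor + ANCHOR_LEN)}
    return SimulatedRegion(accession=accession, sequence=seq, loci=truth, anchors=anchors)


def truth_digits(region: SimulatedRegion) -> str:
    """Per-accession digit string: sorted repeat counts of intact loci."""
    ds = sorted(lo.k for lo in region.loci if lo.class_ == "intact")
    return "".join(str(d) for d in ds)


def simulate_panel(config: SimConfig):
    """Simulate ``n_accessions`` independent accessions.

    Returns ``(ancestor, regions, truth_table)``; the truth table is a
    DataFrame with one row per accession (digit string of intact loci,
    homolog count, class counts).  Deterministic for a given config.
    """
    config.validate()
    anc = make_ancestor(config)
    regions, rows = [], []
    for i in range(config.n_accessions):
        rng = np.random.default_rng([config.seed, 11, i])
        loci, _ = evolve_cluster(anc, config, rng)
        region = emit_region(loci, config, accession=f"acc{i + 1}")
        regions.append(region)
        ds = truth_digits(region)
        classes = [lo.class_ for lo in region.loci]
        rows.append(
            {
                "accession": region.accession,
                "digit_string": ds,
                "n_homologs": len(ds),
                "n_loci": len(region.loci),
                "n_pseudo_stop": classes.count("pseudo_stop"),
                "n_pseudo_insertion": classes.count("pseudo_insertion"),
                "has_reverse": any(lo.is_retro and lo.class_ == "intact"
                                   for lo in region.loci),
            }
        )
    truth = pd.DataFrame(rows)
    return anc, regions, truth


# ---------------------------------------------------------------------------
# truth I/O (FASTA / GFF3 / TSV)
# ---------------------------------------------------------------------------


def write_truth(region: SimulatedRegion, outdir: str | Path) -> dict:
    """Write region FASTA, truth GFF3 (1-based inclusive) and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = region.accession
    fasta = outdir / f"{stem}.fasta"
    gff = outdir / f"{stem}.gff3"
    tsv = outdir / f"{stem}.truth.tsv"

    with open(fasta, "w") as fh:
        fh.write(f">{stem}\n")
        for i in range(0, len(region.sequence), 80):
            fh.write(region.sequence[i: i + 80] + "\n")

    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {stem} 1 {len(region.sequence)}\n")
        for lo in region.loci:
            attrs = f"ID={lo.locus_id};class={lo.class_};k={lo.k}"
            fh.write(
                f"{stem}\tvatkit\tgene\t{lo.start + 1}\t{lo.end}\t.\t{lo.strand}\t.\t{attrs}\n"
            )
            for j, (s, e) in enumerate(lo.exons, 1):
                fh.write(
                    f"{stem}\tvatkit\texon\t{s + 1}\t{e}\t.\t{lo.strand}\t."
                    f"\tID={lo.locus_id}.exon{j};Parent={lo.locus_id}\n"
                )

    pd.DataFrame(
        [
            {
                "accession": region.accession,
                "locus_id": lo.locus_id,
                "start": lo.start,
                "end": lo.end,
                "strand": lo.strand,
                "class": lo.class_,
                "k": lo.k,
                "is_retro": lo.is_retro,
            }
            for lo in region.loci
        ]
    ).to_csv(tsv, sep="\t", index=False)
    return {"fasta": fasta, "gff3": gff, "tsv": tsv}


def read_truth_gff(path: str | Path) -> list[dict]:
    """Parse a truth GFF3 back into gene records (0-based half-open)."""
    genes: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";"))
        if f[2] == "gene":
            genes[attrs["ID"]] = {
                "locus_id": attrs["ID"],
                "start": int(f[3]) - 1,
                "end": int(f[4]),
                "strand": f[6],
                "class": attrs["class"],
                "k": int(attrs["k"]),
                "exons": [],
            }
        elif f[2] == "exon":
            genes[attrs["Parent"]]["exons"].append((int(f[3]) - 1, int(f[4])))
    for g in genes.values():
        g["exons"].sort()
    return list(genes.values())


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
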