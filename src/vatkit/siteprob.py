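"""Per-site nonsynonymous-change probability with permutation bands.

For each codon column i of an alignment, over all unordered sequence pairs
whose codons at i are gap-free, non-stop and different, p(i) is the fraction
of those pairs whose codons encode different amino acids — the conditional
probability of an amino-acid change given a codon change.  The per-site
values are smoothed along the nucleotide axis with a Gaussian kernel
(Nadaraya-Watson), and pointwise confidence bands are obtained by permuting
the per-site count tuples across codon positions: under the null that change
intensity carries no positional structure, the observed smoothed curve
should stay inside the empirical quantile envelope.  Positions where the
observed curve exceeds the upper (lower) quantile are reported as peaks
(valleys) of nonsynonymous acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import CODON_TABLE, STOP_CODONS, encode

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass
class CodonAlignment:
    ids: list
    seqs: list                      # aligned, equal length, length % 3 == 0
    block: str = "whole"            # preLRR2 | LRR2 | postLRR2 | whole

    def __post_init__(self):
        if not self.seqs:
            raise AlignmentError("empty alignment")
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise AlignmentError("sequences have unequal lengths")
        if L % 3 != 0:
            raise AlignmentError("alignment length is not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3


@dataclass
class SiteChangeCounts:
    n_diff: np.ndarray   # per codon site: pairs with differing gap-free codons
    n_ns: np.ndarray     # of those, pairs encoding different amino acids
    positions: np.ndarray  # nt midpoint of each codon (3*i + 1)

    @property
    def p(self) -> np.ndarray:
        """p(i) = n_ns/n_diff; NaN where no pair differs."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_diff > 0, self.n_ns / np.maximum(self.n_diff, 1), np.nan)


@dataclass
class PermutationEnvelope:
    positions: np.ndarray
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    peaks: np.ndarray        # positions where observed > upper
    valleys: np.ndarray      # positions where observed < lower
    bandwidth: float
    n_permutations: int
    alpha: float
    seed: int | None = None


def site_change_counts(alignment: CodonAlignment) -> SiteChangeCounts:
    """Pairwise codon-change counts per site.

    Pairs with a gap or a stop codon in either sequence at a site are
    excluded from both counts.
    """
    S = alignment.n_codons
    N = len(alignment.seqs)
    n_diff = np.zeros(S, dtype=np.int64)
    n_ns = np.zeros(S, dtype=np.int64)
    codons = [
        [s[3 * i: 3 * i + 3] for i in range(S)] for s in alignment.seqs
    ]
    for i in range(S):
        col = [codons[j][i] for j in range(N)]
        valid = [
            c for c in col
            if GAP not in c and c in CODON_TABLE and c not in STOP_CODONS
        ]
        if len(valid) < 2:
            continue
        uniq: dict[str, int] = {}
        for c in valid:
            uniq[c] = uniq.get(c, 0) + 1
        keys = list(uniq)
        total = len(valid)
        same = sum(c * (c - 1) // 2 for c in uniq.values())
        n_diff[i] = total * (total - 1) // 2 - same
        ns = 0
        for a in range(len(keys)):
            for b in range(a + 1, len(keys)):
                if CODON_TABLE[keys[a]] != CODON_TABLE[keys[b]]:
                    ns += uniq[keys[a]] * uniq[keys[b]]
        n_ns[i] = ns
    positions = 3 * np.arange(S) + 1.0
    return SiteChangeCounts(n_diff, n_ns, positions)


def _kernel_matrix(x: np.ndarray, pos: np.ndarray, h: float) -> np.ndarray:
    d = x[:, None] - pos[None, :]
    return np.exp(-0.5 * (d / h) ** 2)


def smooth_curve(
    counts: SiteChangeCounts,
    bandwidth_nt: float,
    x: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothed curve q(x) of p(i) over nucleotide positions.

    q(x) = sum_i K_h(x - pos_i) p(i) / sum_i K_h(x - pos_i), the sum running
    over sites with defined p (undefined sites carry zero weight).
    Returns ``(x, q)``; ``x`` defaults to every nt position of the block.
    """
    p = counts.p
    defined = ~np.isnan(p)
    if not defined.any():
        raise AlignmentError("no site has a defined change probability")
    if x is None:
        L = int(counts.positions[-1] + 2)
        x = np.arange(L, dtype=float)
    K = _kernel_matrix(x, counts.positions[defined], float(bandwidth_nt))
    w = K.sum(axis=1)
    q = (K @ p[defined]) / np.where(w > 0, w, 1.0)
    return x, q


def permutation_envelope(
    alignment: CodonAlignment,
    bandwidth_nt: float,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    counts: SiteChangeCounts | None = None,
) -> PermutationEnvelope:
    """Pointwise permutation confidence band for the smoothed curve.

    Each of the B permutations shuffles the per-site (n_diff, n_ns) tuples
    uniformly across the codon positions of the block and recomputes the
    smoothed curve; the band is the pointwise empirical alpha/2 and
    1 - alpha/2 quantile.  Deterministic for a given seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if counts is None:
        counts = site_change_counts(alignment)
    rng = np.random.default_rng(seed)
    x, q_obs = smooth_curve(counts, bandwidth_nt)

    p = counts.p
    S = len(p)
    K_full = _kernel_matrix(x, counts.positions, float(bandwidth_nt))
    p_filled = np.where(np.isnan(p), 0.0, p)
    defined = (~np.isnan(p)).astype(float)

    # columns of P: permuted p-vectors; W: permuted defined-masks
    perm = np.stack([rng.permutation(S) for _ in range(B)], axis=1)
    P = p_filled[perm]           # S x B
    W = defined[perm]
    num = K_full @ (P * W)
    den = K_full @ W
    Q = num / np.where(den > 0, den, 1.0)    # len(x) x B

    lower = np.quantile(Q, alpha / 2, axis=1)
    upper = np.quantile(Q, 1 - alpha / 2, axis=1)
    peaks = x[q_obs > upper]
    valleys = x[q_obs < lower]
    return PermutationEnvelope(
        positions=x,
        observed=q_obs,
        lower=lower,
        upper=upper,
        peaks=peaks,
        valleys=valleys,
        bandwidth=float(bandwidth_nt),
        n_permutations=B,
        alpha=alpha,
        seed=seed,
    )


def repeat_unit_alignment(annotations: list, cdss: dict) -> CodonAlignment:
    """Stack all repeat copies of a set of annotated CDSs into one pooled
    unit alignment (one row per copy).

    Copies of the modal length are stacked gap-free; copies of other
    lengths are aligned to the modal-length consensus with an end-gap-free
    codon-level alignment (whole-codon gaps only) when their length
    difference is a codon multiple, and dropped with a warning otherwise.
    """
    import logging

    logger = logging.getLogger(__name__)
    pooled, ids = [], []
    for ann in annotations:
        seq = cdss[ann.cds_id]
        for ci, (s, e) in enumerate(ann.copies, 1):
            pooled.append(seq[s:e])
            ids.append(f"{ann.cds_id}.copy{ci}")
    if len(pooled) < 2:
        raise AlignmentError("need at least two repeat copies to align")
    lengths = [len(c) for c in pooled]
    modal = max(set(lengths), key=lengths.count)
    modal_copies = [c for c in pooled if len(c) == modal]

    cons = _codon_consensus(modal_copies)
    rows, row_ids = [], []
    for cid, copy in zip(ids, pooled):
        if len(copy) == modal:
            rows.append(copy)
            row_ids.append(cid)
        elif (modal - len(copy)) % 3 == 0 and len(copy) < modal:
            rows.append(_codon_glocal(copy, cons))
            row_ids.append(cid)
        else:
            logger.warning("copy %s has incompatible length %d; dropped", cid, len(copy))
    return CodonAlignment(row_ids, rows, block="LRR2")


def _codon_consensus(copies: list) -> str:
    arr = np.stack([encode(c) for c in copies])
    out = []
    for col in arr.T:
        vals, counts = np.unique(col, return_counts=True)
        out.append("ACGTN"[vals[np.argmax(counts)]])
    return "".join(out)


def _codon_glocal(copy: str, ref: str) -> str:
    """Align a shorter copy to the reference with whole-codon gaps
    (end-gap-free on the reference): simple codon-unit NW, match-count
    scoring, gaps cost zero at the ends of neither sequence (the copy is
    fully consumed)."""
    ca = [copy[i: i + 3] for i in range(0, len(copy), 3)]
    cb = [ref[i: i + 3] for i in range(0, len(ref), 3)]
    n, m = len(ca), len(cb)
    NEG = -1e9
    score = np.full((n + 1, m + 1), NEG)
    back = np.zeros((n + 1, m + 1), dtype=np.int8)
    score[0, 0] = 0.0
    for j in range(1, m + 1):
        score[0, j] = 0.0          # leading reference gap is free
        back[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = sum(x == y for x, y in zip(ca[i - 1], cb[j - 1]))
            diag = score[i - 1, j - 1] + match
            gap_ref = score[i, j - 1] - 1.0    # codon gap in the copy
            if diag >= gap_ref:
                score[i, j], back[i, j] = diag, 1
            else:
                score[i, j], back[i, j] = gap_ref, 2
    i, j = n, m
    out = []
    while i > 0 or j > 0:
        if back[i, j] == 1:
            out.append(ca[i - 1])
            i, j = i - 1, j - 1
        else:
            out.append("---")
            j -= 1
    return "".join(reversed(out))
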