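"""Distance phylogenetics: TN93 distances, neighbor joining, bootstrap,
progressive profile alignment, newick IO, and a two-segment incongruence
(breakpoint) scan.

The distance machinery distinguishes the two transition classes (A<->G,
C<->T) with empirical base frequencies per pair (Tamura-Nei 1993).  Trees
are built with canonical Saitou-Nei neighbor joining (lowest-index
tie-breaking; negative intermediate branch lengths clamped to zero with the
deficit moved to the sister edge).  The breakpoint scan is a deliberately
simple stand-in for likelihood-based recombination detection: for every
candidate codon boundary it fits separate NJ trees to the two flanking
segments and asks whether the two-tree fit to the segment distance matrices
improves enough on the single-tree fit, calibrated by a column-permutation
null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from numba import njit

from ._util import encode

logger = logging.getLogger(__name__)

class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list
    matrix: np.ndarray    # symmetric, zero diagonal; np.inf flags saturation

    def __post_init__(self):
        m = self.matrix
        if m.shape[0] != m.shape[1] or len(self.ids) != m.shape[0]:
            raise PhyloError("matrix shape does not match taxon ids")
        if not np.allclose(m, m.T, equal_nan=True):
            raise PhyloError("distance matrix is not symmetric")


# ---------------------------------------------------------------------------
# TN93 distance
# ---------------------------------------------------------------------------


def _tn93_from_counts(n, p1, p2, q, gA, gC, gG, gT) -> float:
    """TN93 closed form from substitution-class fractions and frequencies."""
    gR, gY = gA + gG, gC + gT
    if min(gA, gC, gG, gT) <= 0:
        # degenerate composition: fall back to the K2P-style limit terms
        gA = gC = gG = gT = 0.25
        gR = gY = 0.5
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - p1 / k1 - q / (2 * gR)
    w2 = 1 - p2 / k2 - q / (2 * gY)
    w3 = 1 - q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return np.inf
    return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))


def tn93_distance(seq1: str, seq2: str) -> float:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Sites where either sequence is not A/C/G/T are excluded; base
    frequencies are empirical over the comparable sites of both sequences.
    A saturated pair (non-positive log argument) returns ``inf``.
    """
    if len(seq1) != len(seq2):
        raise PhyloError("sequences must have equal length")
    a, b = encode(seq1), encode(seq2)
    ok = (a < 4) & (b < 4)
    n = int(ok.sum())
    if n == 0:
        raise PhyloError("no comparable (gap-free) sites")
    a, b = a[ok], b[ok]
    diff = a != b
    transitions_ag = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0)))
    transitions_ct = diff & (((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
    p1 = transitions_ag.sum() / n
    p2 = transitions_ct.sum() / n
    q = (diff.sum() - transitions_ag.sum() - transitions_ct.sum()) / n
    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    gA, gC, gG, gT = counts / counts.sum()
    return _tn93_from_counts(n, p1, p2, q, gA, gC, gG, gT)


def tn93_matrix(ids: list, seqs: list) -> DistanceMatrix:
    """Pairwise TN93 distance matrix; saturated pairs are flagged inf and
    replaced by twice the largest finite distance for tree building."""
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tn93_distance(seqs[i], seqs[j])
    if np.isinf(m).any():
        finite_max = np.nanmax(np.where(np.isinf(m), np.nan, m))
        logger.warning("saturated pairs in distance matrix; capped at %.3f",
                       2 * finite_max)
        m = np.where(np.isinf(m), 2 * finite_max, m)
    return DistanceMatrix(ids, m)


# ---------------------------------------------------------------------------
# neighbor joining (numba engine + dendropy wrapper)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _nj_engine(D):
    """Saitou-Nei agglomeration.

    Returns (parent, elen, root, n_nodes): node ids 0..n-1 are leaves in
    input order; internal nodes are appended; the root is the final
    trifurcation point.  Ties broken towards the lowest-index pair;
    negative branch lengths clamped to 0, deficit moved to the sister edge.
    """
    n = D.shape[0]
    max_nodes = 2 * n
    W = np.zeros((max_nodes, max_nodes))
    W[:n, :n] = D
    parent = np.full(max_nodes, -1, dtype=np.int64)
    elen = np.zeros(max_nodes)
    active = np.zeros(max_nodes, dtype=np.bool_)
    active[:n] = True
    n_active = n
    next_node = n
    while n_active > 3:
        idx = np.where(active)[0]
        na = len(idx)
        r = np.zeros(na)
        for ii in range(na):
            s = 0.0
            for jj in range(na):
                s += W[idx[ii], idx[jj]]
            r[ii] = s
        best_q = 1e300
        bi = bj = -1
        for ii in range(na):
            for jj in range(ii + 1, na):
                qv = (na - 2) * W[idx[ii], idx[jj]] - r[ii] - r[jj]
                if qv < best_q - 1e-12:
                    best_q = qv
                    bi, bj = ii, jj
        i, j = idx[bi], idx[bj]
        li = 0.5 * W[i, j] + (r[bi] - r[bj]) / (2 * (na - 2))
        lj = W[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_node
        next_node += 1
        for kk in range(na):
            k = idx[kk]
            if k == i or k == j:
                continue
            w = 0.5 * (W[i, k] + W[j, k] - W[i, j])
            if w < 0:
                w = 0.0
            W[u, k] = w
            W[k, u] = w
        parent[i] = u
        elen[i] = li
        parent[j] = u
        elen[j] = lj
        active[i] = False
        active[j] = False
        active[u] = True
        n_active -= 1
    idx = np.where(active)[0]
    root = next_node
    next_node += 1
    if len(idx) == 3:
        a, b, c = idx[0], idx[1], idx[2]
        la = 0.5 * (W[a, b] + W[a, c] - W[b, c])
        lb = 0.5 * (W[a, b] + W[b, c] - W[a, c])
        lc = 0.5 * (W[a, c] + W[b, c] - W[a, b])
        for node, ln in ((a, la), (b, lb), (c, lc)):
            parent[node] = root
            elen[node] = ln if ln > 0 else 0.0
    elif len(idx) == 2:
        a, b = idx[0], idx[1]
        parent[a] = root
        parent[b] = root
        elen[a] = W[a, b] / 2
        elen[b] = W[a, b] / 2
    else:
        parent[idx[0]] = root
        elen[idx[0]] = 0.0
    return parent, elen, root, next_node


@njit(cache=True)
def _patristic(parent, elen, root, n_leaves):
    """Leaf-pair path-length matrix from the NJ node arrays."""
    maxd = 64
    paths = np.full((n_leaves, maxd), -1, dtype=np.int64)
    plen = np.zeros((n_leaves, maxd))
    depth = np.zeros(n_leaves, dtype=np.int64)
    for i in range(n_leaves):
        node = i
        acc = 0.0
        d = 0
        while node != root:
            paths[i, d] = node
            plen[i, d] = acc + elen[node]
            acc += elen[node]
            node = parent[node]
            d += 1
        paths[i, d] = root
        plen[i, d] = acc
        depth[i] = d
    T = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            # first shared node on the two root-ward paths
            dij = 0.0
            done = False
            for di in range(depth[i] + 1):
                if done:
                    break
                for dj in range(depth[j] + 1):
                    if paths[i, di] == paths[j, dj]:
                        # plen[·, d-1] is the accumulated length up to (not
                        # including) the LCA's own edge
                        dij = (plen[i, di - 1] if di > 0 else 0.0) + (
                            plen[j, dj - 1] if dj > 0 else 0.0
                        )
                        done = True
                        break
            T[i, j] = dij
            T[j, i] = dij
    return T


def _arrays_to_dendropy(ids: list, parent, elen, root, n_nodes) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = {}
    for v in range(n_nodes):
        nd = dendropy.Node()
        if v < len(ids):
            nd.taxon = ns.get_taxon(ids[v])
        nodes[v] = nd
    for v in range(n_nodes):
        if v == root:
            continue
        p = parent[v]
        if p >= 0:
            nodes[p].add_child(nodes[v])
            nodes[v].edge.length = float(elen[v])
    tree.seed_node = nodes[root]
    tree.is_rooted = False
    return tree


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted, trifurcating root) from a distance
    matrix."""
    n = len(dm.ids)
    if n < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    parent, elen, root, n_nodes = _nj_engine(dm.matrix.astype(np.float64))
    return _arrays_to_dendropy(dm.ids, parent, elen, root, n_nodes)


def _splits(parent, root, n_leaves, n_nodes) -> set:
    """Non-trivial bipartitions (as frozensets of leaf indices, the side
    not containing leaf 0) of an NJ node-array tree."""
    children: dict[int, list] = {v: [] for v in range(n_nodes)}
    for v in range(n_nodes):
        if v != root and parent[v] >= 0:
            children[parent[v]].append(v)
    out = set()

    def leafset(v):
        if v < n_leaves:
            return {v}
        s = set()
        for c in children[v]:
            s |= leafset(c)
        return s

    for v in range(n_leaves, n_nodes):
        if v == root:
            continue
        ls = leafset(v)
        if 1 < len(ls) < n_leaves - 1:
            if 0 in ls:
                ls = set(range(n_leaves)) - ls
            out.add(frozenset(ls))
    return out


def tree_splits(tree: dendropy.Tree, ids: list) -> set:
    """Non-trivial bipartitions of a dendropy tree as frozensets of indices
    into ``ids`` (side not containing index 0)."""
    index = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    out = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        ls = {
            index[lf.taxon.label]
            for lf in edge.head_node.leaf_iter()
        }
        if 1 < len(ls) < n - 1:
            if 0 in ls:
                ls = set(range(n)) - ls
            out.add(frozenset(ls))
    return out


def bootstrap_support(
    ids: list,
    seqs: list,
    B: int = 500,
    seed: int | None = None,
    codon: bool = True,
) -> dendropy.Tree:
    """NJ tree with bootstrap split supports.

    B column-resampled replicates (codon-block resampling when ``codon``);
    each internal split of the point-estimate tree is labelled with the
    percentage of replicate trees containing it.  ``B=0`` returns the point
    tree without supports.  Deterministic for a given seed.
    """
    if len(ids) < 4:
        raise PhyloError("bootstrap support needs at least 4 taxa")
    L = len(seqs[0])
    dm = tn93_matrix(ids, seqs)
    parent, elen, root, n_nodes = _nj_engine(dm.matrix)
    point_tree = _arrays_to_dendropy(ids, parent, elen, root, n_nodes)
    if B == 0:
        return point_tree
    point_splits = _splits(parent, root, len(ids), n_nodes)
    counts = {s: 0 for s in point_splits}
    rng = np.random.default_rng(seed)
    enc = np.stack([encode(s) for s in seqs])
    block = 3 if codon and L % 3 == 0 else 1
    n_blocks = L // block
    for _ in range(B):
        bidx = rng.integers(0, n_blocks, size=n_blocks)
        sites = (bidx[:, None] * block + np.arange(block)[None, :]).ravel()
        sub = enc[:, sites]
        reps = ["".join("ACGTN"[v] for v in row) for row in sub]
        dmr = tn93_matrix(ids, reps)
        p2, e2, r2, nn2 = _nj_engine(dmr.matrix)
        rep_splits = _splits(p2, r2, len(ids), nn2)
        for s in point_splits & rep_splits:
            counts[s] += 1
    # label internal nodes with % support
    index = {t: i for i, t in enumerate(ids)}
    for node in point_tree.preorder_node_iter():
        if node.is_leaf() or node is point_tree.seed_node:
            continue
        ls = {index[lf.taxon.label] for lf in node.leaf_iter()}
        if 0 in ls:
            ls = set(range(len(ids))) - ls
        key = frozenset(ls)
        if key in counts:
            node.label = str(round(100.0 * counts[key] / B))
    return point_tree


# ---------------------------------------------------------------------------
# newick IO
# ---------------------------------------------------------------------------


def write_newick(tree: dendropy.Tree) -> str:
    """Newick string; internal node labels carry supports, branch lengths
    with 6 decimals."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    return s.strip() + ("" if s.strip().endswith(";") else ";")


def parse_newick(newick: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhyloError(f"malformed newick: {exc}") from exc


# ---------------------------------------------------------------------------
# progressive profile alignment
# ---------------------------------------------------------------------------

MATCH, MISMATCH = 2.0, -1.0
GAP_OPEN, GAP_EXTEND = -6.0, -1.0


@njit(cache=True)
def _profile_align(pa, pb, gap_open, gap_extend, match, mismatch):
    """Affine-gap global profile-profile alignment (Gotoh).

    Profiles are (5, L) frequency matrices over A,C,G,T,gap.  Returns the
    traceback ops array: 0 = column from both, 1 = gap in B, 2 = gap in A.
    """
    La = pa.shape[1]
    Lb = pb.shape[1]
    NEG = -1e18
    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)   # gap in B (consumes A)
    Y = np.full((La + 1, Lb + 1), NEG)   # gap in A (consumes B)
    bM = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    bX = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    bY = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
        bX[i, 0] = 1
    for j in range(1, Lb + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
        bY[0, j] = 2
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            # expected column score
            s = 0.0
            for x in range(4):
                for y in range(4):
                    if x == y:
                        s += pa[x, i - 1] * pb[y, j - 1] * match
                    else:
                        s += pa[x, i - 1] * pb[y, j - 1] * mismatch
            best_prev = M[i - 1, j - 1]
            bm = 0
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
                bm = 1
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
                bm = 2
            M[i, j] = best_prev + s
            bM[i, j] = bm

            vo = M[i - 1, j] + gap_open
            ve = X[i - 1, j] + gap_extend
            if vo >= ve:
                X[i, j] = vo
                bX[i, j] = 0
            else:
                X[i, j] = ve
                bX[i, j] = 1

            vo = M[i, j - 1] + gap_open
            ve = Y[i, j - 1] + gap_extend
            if vo >= ve:
                Y[i, j] = vo
                bY[i, j] = 0
            else:
                Y[i, j] = ve
                bY[i, j] = 2

    ops = np.zeros(La + Lb, dtype=np.int8)
    nops = 0
    i, j = La, Lb
    state = 0
    best = M[La, Lb]
    if X[La, Lb] > best:
        best = X[La, Lb]
        state = 1
    if Y[La, Lb] > best:
        state = 2
    while i > 0 or j > 0:
        if state == 0:
            ops[nops] = 0
            nops += 1
            state = bM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[nops] = 1
            nops += 1
            state = bX[i, j]
            i -= 1
        else:
            ops[nops] = 2
            nops += 1
            state = bY[i, j]
            j -= 1
    return ops[:nops][::-1]


def _profile(rows: list) -> np.ndarray:
    L = len(rows[0])
    prof = np.zeros((5, L))
    lut = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
    for r in rows:
        for i, ch in enumerate(r):
            prof[lut.get(ch, 4), i] += 1
    return prof / len(rows)


def _merge(rows_a: list, rows_b: list) -> list:
    ops = _profile_align(_profile(rows_a), _profile(rows_b),
                         GAP_OPEN, GAP_EXTEND, MATCH, MISMATCH)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    i = j = 0
    for op in ops:
        if op == 0:
            for r, s in enumerate(rows_a):
                out_a[r] += s[i]
            for r, s in enumerate(rows_b):
                out_b[r] += s[j]
            i += 1
            j += 1
        elif op == 1:
            for r, s in enumerate(rows_a):
                out_a[r] += s[i]
            for r in range(len(rows_b)):
                out_b[r] += "-"
            i += 1
        else:
            for r in range(len(rows_a)):
                out_a[r] += "-"
            for r, s in enumerate(rows_b):
                out_b[r] += s[j]
            j += 1
    return out_a + out_b


def _kmer_distance_matrix(seqs: list, k: int = 6) -> np.ndarray:
    sets = [frozenset(s[i: i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            d[i, j] = d[j, i] = 1.0 - (inter / union if union else 0.0)
    return d


def progressive_align(
    seqs: dict, guide: dendropy.Tree | None = None
) -> tuple[list, list]:
    """Guide-tree progressive profile alignment with affine gaps.

    ``seqs`` maps id -> sequence.  The guide defaults to an NJ tree on
    k-mer (Jaccard) distances.  Output columns preserve the input residues
    exactly.  Returns ``(ids, aligned_rows)``.
    """
    ids = list(seqs)
    if any(not seqs[i] for i in ids):
        raise PhyloError("empty sequence in input")
    if len(ids) == 1:
        return ids, [seqs[ids[0]]]
    if len(ids) == 2:
        rows = _merge([seqs[ids[0]]], [seqs[ids[1]]])
        return ids, rows
    if guide is None:
        d = _kmer_distance_matrix([seqs[i] for i in ids])
        guide = nj_tree(DistanceMatrix(ids, d))
    # postorder merge
    aligned: dict[int, tuple[list, list]] = {}

    def visit(node):
        if node.is_leaf():
            return [node.taxon.label], [seqs[node.taxon.label]]
        parts = [visit(c) for c in node.child_nodes()]
        cur_ids, cur_rows = parts[0]
        for nxt_ids, nxt_rows in parts[1:]:
            cur_rows = _merge(cur_rows, nxt_rows)
            cur_ids = cur_ids + nxt_ids
        return cur_ids, cur_rows

    out_ids, rows = visit(guide.seed_node)
    order = {t: i for i, t in enumerate(out_ids)}
    perm = sorted(range(len(ids)), key=lambda r: ids.index(out_ids[r]))
    return [out_ids[r] for r in perm], [rows[r] for r in perm]


# ---------------------------------------------------------------------------
# breakpoint scan
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pair_site_codes(enc):
    """Per unordered pair, per site: substitution class and base counts.

    cls: 0 incomparable, 1 equal, 2 transition A<->G, 3 transition C<->T,
    4 transversion.  bases: per pair/site counts of A,C,G,T over the two
    sequences (0 when incomparable).
    """
    N, L = enc.shape
    P = N * (N - 1) // 2
    cls = np.zeros((P, L), dtype=np.int8)
    bases = np.zeros((P, L, 4), dtype=np.int8)
    p = 0
    for i in range(N):
        for j in range(i + 1, N):
            for s in range(L):
                a, b = enc[i, s], enc[j, s]
                if a > 3 or b > 3:
                    continue
                bases[p, s, a] += 1
                bases[p, s, b] += 1
                if a == b:
                    cls[p, s] = 1
                elif (a == 0 and b == 2) or (a == 2 and b == 0):
                    cls[p, s] = 2
                elif (a == 1 and b == 3) or (a == 3 and b == 1):
                    cls[p, s] = 3
                else:
                    cls[p, s] = 4
            p += 1
    return cls, bases


@njit(cache=True)
def _cumulants(cls, bases, order):
    """Per-pair cumulative substitution-class and base counts along the
    given column order: cum[p, t] covers columns order[0:t].

    Channels: n, ts_AG, ts_CT, tv, A, C, G, T.
    """
    P, L = cls.shape
    cum = np.zeros((P, L + 1, 8))
    for p in range(P):
        for t in range(L):
            s = order[t]
            for ch in range(8):
                cum[p, t + 1, ch] = cum[p, t, ch]
            c = cls[p, s]
            if c == 0:
                continue
            cum[p, t + 1, 0] += 1
            if c == 2:
                cum[p, t + 1, 1] += 1
            elif c == 3:
                cum[p, t + 1, 2] += 1
            elif c == 4:
                cum[p, t + 1, 3] += 1
            for x in range(4):
                cum[p, t + 1, 4 + x] += bases[p, s, x]
    return cum


@njit(cache=True)
def _segment_distances(cum, a, b, N):
    """TN93 matrix for ordered columns [a:b] from the cumulant array."""
    D = np.zeros((N, N))
    p = 0
    for i in range(N):
        for j in range(i + 1, N):
            n = cum[p, b, 0] - cum[p, a, 0]
            if n == 0:
                p += 1
                continue
            ts1 = cum[p, b, 1] - cum[p, a, 1]
            ts2 = cum[p, b, 2] - cum[p, a, 2]
            tv = cum[p, b, 3] - cum[p, a, 3]
            cA = cum[p, b, 4] - cum[p, a, 4]
            cC = cum[p, b, 5] - cum[p, a, 5]
            cG = cum[p, b, 6] - cum[p, a, 6]
            cT = cum[p, b, 7] - cum[p, a, 7]
            tot = cA + cC + cG + cT
            gA, gC, gG, gT = cA / tot, cC / tot, cG / tot, cT / tot
            p1, p2, q = ts1 / n, ts2 / n, tv / n
            gR, gY = gA + gG, gC + gT
            if gA <= 0 or gC <= 0 or gG <= 0 or gT <= 0:
                gA = gC = gG = gT = 0.25
                gR = gY = 0.5
            k1 = 2 * gA * gG / gR
            k2 = 2 * gC * gT / gY
            k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
            w1 = 1 - p1 / k1 - q / (2 * gR)
            w2 = 1 - p2 / k2 - q / (2 * gY)
            w3 = 1 - q / (2 * gR * gY)
            if w1 <= 0 or w2 <= 0 or w3 <= 0:
                d = 5.0    # saturated; large finite stand-in
            else:
                d = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
            D[i, j] = d
            D[j, i] = d
            p += 1
    return D


@njit(cache=True)
def _fit_residual(D, T):
    n = D.shape[0]
    r = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            e = D[i, j] - T[i, j]
            r += e * e
    return r


@njit(cache=True)
def _scan_best(cls, bases, order, candidates, N, L):
    """Best breakpoint and score for one column ordering."""
    best_b = -1
    best_score = -1e300
    cum = _cumulants(cls, bases, order)
    D_full = _segment_distances(cum, 0, L, N)
    parent, elen, root, _ = _nj_engine(D_full)
    T_full = _patristic(parent, elen, root, N)
    for ci in range(len(candidates)):
        b = candidates[ci]
        DL = _segment_distances(cum, 0, b, N)
        DR = _segment_distances(cum, b, L, N)
        pL, eL, rL, _ = _nj_engine(DL)
        TL = _patristic(pL, eL, rL, N)
        pR, eR, rR, _ = _nj_engine(DR)
        TR = _patristic(pR, eR, rR, N)
        # length-weighted residuals: segment distance noise scales as
        # 1/segment length, so unweighted residual differences blow up at
        # the alignment ends and swamp the incongruence signal
        wl, wr = b / L, (L - b) / L
        single = wl * _fit_residual(DL, T_full) + wr * _fit_residual(DR, T_full)
        two = wl * _fit_residual(DL, TL) + wr * _fit_residual(DR, TR)
        score = single - two
        if score > best_score:
            best_score = score
            best_b = b
    return best_b, best_score


@dataclass
class BreakpointResult:
    best_position: int          # nt, codon boundary
    score: float                # single-tree minus two-tree fit residual
    p_value: float
    left_tree: dendropy.Tree
    right_tree: dendropy.Tree
    candidates: list


def breakpoint_scan(
    ids: list,
    seqs: list,
    n_perm: int = 200,
    seed: int | None = None,
    min_segment: int = 60,
) -> BreakpointResult:
    """Two-segment incongruence scan over codon boundaries.

    For each candidate boundary b the alignment is split into [0, b) and
    [b, L); NJ trees are fitted to each segment's TN93 distances, and the
    score is the improvement of the two-tree least-squares distance fit
    over the single full-alignment tree.  The p-value is the fraction of
    column-permuted alignments whose best score reaches the observed best.
    Deterministic for a given seed.
    """
    if len(ids) < 4:
        raise PhyloError("breakpoint scan needs at least 4 taxa")
    L = len(seqs[0])
    enc = np.stack([encode(s) for s in seqs])
    # variable sites: >= 2 distinct comparable bases
    variable = np.zeros(L, dtype=bool)
    for s in range(L):
        col = enc[:, s]
        col = col[col < 4]
        variable[s] = len(np.unique(col)) > 1
    if not variable.any():
        raise PhyloError("no variable sites in alignment")
    var_cum = np.concatenate([[0], np.cumsum(variable)])
    candidates = [
        b
        for b in range(3 * (min_segment // 3 + 1), L - min_segment, 3)
        if var_cum[b] > 0 and var_cum[L] - var_cum[b] > 0
    ]
    # segments need >= 4 distinct sequences
    def distinct_ok(a, b):
        sub = {s[a:b] for s in seqs}
        return len(sub) >= 4

    kept = [b for b in candidates if distinct_ok(0, b) and distinct_ok(b, L)]
    dropped = len(candidates) - len(kept)
    if dropped:
        logger.info("%d candidate boundaries skipped (<4 distinct sequences)", dropped)
    if len(kept) < 2:
        raise PhyloError("fewer than 2 usable candidate boundaries")
    candidates = np.array(kept, dtype=np.int64)

    cls, bases = _pair_site_codes(enc)
    order = np.arange(L, dtype=np.int64)
    N = len(ids)
    best_b, best_score = _scan_best(cls, bases, order, candidates, N, L)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(L).astype(np.int64)
        _, s = _scan_best(cls, bases, perm, candidates, N, L)
        if s >= best_score:
            exceed += 1
    p_value = (exceed + 1) / (n_perm + 1)

    cum = _cumulants(cls, bases, order)
    DL = _segment_distances(cum, 0, int(best_b), N)
    DR = _segment_distances(cum, int(best_b), L, N)
    left = nj_tree(DistanceMatrix(ids, DL))
    right = nj_tree(DistanceMatrix(ids, DR))
    return BreakpointResult(
        best_position=int(best_b),
        score=float(best_score),
        p_value=float(p_value),
        left_tree=left,
        right_tree=right,
        candidates=list(map(int, candidates)),
    )


# ---------------------------------------------------------------------------
# sequence evolution on a tree (simulation utility for calibration tests)
# ---------------------------------------------------------------------------


def simulate_alignment(
    newick: str, length: int, seed: int | None = None
) -> tuple[list, list]:
    """Evolve a Jukes-Cantor alignment down a newick tree (branch lengths in
    substitutions/site).  Returns ``(leaf ids, sequences)``."""
    tree = parse_newick(newick)
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    out_ids, out_seqs = [], []

    def visit(node, seq):
        for child in node.child_nodes():
            d = child.edge.length or 0.0
            p = 0.75 * (1 - np.exp(-4.0 * d / 3.0))
            s = seq.copy()
            mut = rng.random(length) < p
            s[mut] = (s[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
            if child.is_leaf():
                out_ids.append(child.taxon.label)
                out_seqs.append("".join("ACGT"[v] for v in s))
            else:
                visit(child, s)

    visit(tree.seed_node, root_seq)
    return out_ids, out_seqs
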