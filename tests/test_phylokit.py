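"""TN93 distances, NJ trees, bootstrap, newick IO, progressive alignment,
breakpoint scan."""

import random

import dendropy
import numpy as np
import pytest

from vatkit import phylokit as pk


# frozen oracle: ape::dist.dna(model="TN93") on the three constructed pairs
APE_TN93 = [0.131361810119, 0.133534824909, 0.132869998544]


def _oracle_pair(seed, n, ts_bias, comp):
    """Deterministic mutated pair; mirrors the construction used to freeze
    the external reference values."""
    r = np.random.default_rng(seed)
    a = r.choice(4, size=n, p=comp)
    b = a.copy()
    pos = r.choice(n, int(0.12 * n), replace=False)
    ts = {0: 2, 2: 0, 1: 3, 3: 1}
    for p in pos:
        if r.random() < ts_bias:
            b[p] = ts[a[p]]
        else:
            choices = [x for x in range(4) if x != a[p] and x != ts[a[p]]]
            b[p] = r.choice(choices)
    s = "ACGT"
    return "".join(s[i] for i in a), "".join(s[i] for i in b)


def _random_additive(seed):
    """Random tree -> (ids, newick, patristic matrix via dendropy)."""
    rng = random.Random(seed)
    n = rng.randint(5, 12)
    ids = [f"t{i}" for i in range(n)]

    def build(sub):
        if len(sub) == 1:
            return f"{sub[0]}:{rng.uniform(0.1, 1.0):.4f}"
        k = rng.randint(1, len(sub) - 1)
        return f"({build(sub[:k])},{build(sub[k:])}):{rng.uniform(0.1, 1.0):.4f}"

    shuffled = ids[:]
    rng.shuffle(shuffled)
    k = rng.randint(1, n - 1)
    nwk = f"({build(shuffled[:k])},{build(shuffled[k:])});"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.distance(tax[ids[i]], tax[ids[j]])
    return ids, tree, D


class TestTN93:
    def test_identical_sequences_zero(self):
        s = "ACGT" * 100
        assert pk.tn93_distance(s, s) == 0.0

    def test_symmetry(self):
        a, b = _oracle_pair(1, 600, 0.5, [0.25] * 4)
        assert pk.tn93_distance(a, b) == pk.tn93_distance(b, a)

    @pytest.mark.parametrize(
        "spec,expected",
        list(zip(
            [(1, 600, 0.5, [.25] * 4), (2, 900, 0.8, [.25] * 4),
             (3, 600, 0.6, [.4, .1, .3, .2])],
            APE_TN93,
        )),
    )
    def test_matches_external_reference(self, spec, expected):
        a, b = _oracle_pair(*spec)
        assert pk.tn93_distance(a, b) == pytest.approx(expected, abs=1e-9)

    def test_reduces_to_jukes_cantor(self):
        """Uniform composition + equal substitution rates: TN93 equals the
        JC closed form to 1e-9."""
        a = list("ACGT" * 150)
        b = a[:]
        pairs = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
                 ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")]
        used = set()
        for x, y in pairs:
            placed = 0
            for i, base in enumerate(a):
                if base == x and i not in used and placed < 6:
                    b[i] = y
                    used.add(i)
                    placed += 1
        a, b = "".join(a), "".join(b)
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        jc = -0.75 * np.log(1 - 4 * p / 3)
        assert pk.tn93_distance(a, b) == pytest.approx(jc, abs=1e-9)

    def test_saturated_pair_is_inf(self):
        rng = np.random.default_rng(0)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        assert np.isinf(pk.tn93_distance(a, b))

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(pk.PhyloError):
            pk.tn93_distance("----", "ACGT")


class TestNJ:
    def test_fewer_than_three_taxa_rejected(self):
        dm = pk.DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]]))
        with pytest.raises(pk.PhyloError):
            pk.nj_tree(dm)

    def test_three_taxa_three_point_solution(self):
        D = np.array([[0, 3.0, 4], [3, 0, 5], [4, 5, 0]])
        tree = pk.nj_tree(pk.DistanceMatrix(["a", "b", "c"], D))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_four_taxon_example(self):
        # additive matrix of ((A:1,B:2):1,(C:3,D:4)); internal edge 1
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = pk.nj_tree(pk.DistanceMatrix(ids, D))
        assert pk.tree_splits(tree, ids) == {frozenset({2, 3})}
        internal = [
            e.length for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node and not e.head_node.is_leaf()
        ]
        assert internal == pytest.approx([1.0])
        parent, elen, root, _ = pk._nj_engine(D)
        assert np.allclose(pk._patristic(parent, elen, root, 4), D)

    def test_taxon_order_invariance(self):
        ids, _, D = _random_additive(3)
        splits_a = pk.tree_splits(pk.nj_tree(pk.DistanceMatrix(ids, D)), ids)
        perm = list(range(len(ids)))[::-1]
        ids_p = [ids[i] for i in perm]
        D_p = D[np.ix_(perm, perm)]
        tree_p = pk.nj_tree(pk.DistanceMatrix(ids_p, D_p))
        assert pk.tree_splits(tree_p, ids) == splits_a

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_recovery_and_skbio_agreement(self, seed):
        import skbio

        ids, true_tree, D = _random_additive(seed)
        mine = pk.nj_tree(pk.DistanceMatrix(ids, D))
        assert pk.tree_splits(mine, ids) == pk.tree_splits(true_tree, ids)
        sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        assert pk.tree_splits(mine, ids) == pk.tree_splits(
            pk.parse_newick(str(sk)), ids
        )


class TestNewick:
    def test_round_trip_example(self):
        t = pk.parse_newick("(A:1,B:2,(C:3,D:4):1);")
        s = pk.write_newick(t)
        t2 = pk.parse_newick(s)
        ids = ["A", "B", "C", "D"]
        assert pk.tree_splits(t, ids) == pk.tree_splits(t2, ids)
        assert pk.write_newick(t2) == s

    def test_three_leaf_trifurcation(self):
        D = np.array([[0, 2.0, 3], [2, 0, 3], [3, 3, 0]])
        tree = pk.nj_tree(pk.DistanceMatrix(["a", "b", "c"], D))
        assert len(tree.seed_node.child_nodes()) == 3

    @pytest.mark.parametrize("seed", range(20))
    def test_random_tree_round_trip(self, seed):
        ids, tree, _ = _random_additive(seed + 100)
        s1 = pk.write_newick(tree)
        t2 = pk.parse_newick(s1)
        assert pk.write_newick(t2) == s1
        assert pk.tree_splits(t2, ids) == pk.tree_splits(tree, ids)

    def test_malformed_rejected(self):
        with pytest.raises(pk.PhyloError):
            pk.parse_newick("((A:1,B:2;")


TOPO = ("((a:0.08,b:0.08):0.1,(c:0.08,d:0.08):0.1,"
        "((e:0.08,f:0.08):0.1,(g:0.08,h:0.08):0.1):0.05);")
TOPO_ALT = ("((a:0.08,e:0.08):0.1,(c:0.08,g:0.08):0.1,"
            "((b:0.08,f:0.08):0.1,(d:0.08,h:0.08):0.1):0.05);")


class TestBootstrap:
    def test_b0_point_tree_without_supports(self):
        ids, seqs = pk.simulate_alignment(TOPO, 600, seed=1)
        tree = pk.bootstrap_support(ids, seqs, B=0)
        labels = [n.label for n in tree.preorder_node_iter() if not n.is_leaf()]
        assert all(lb is None for lb in labels)

    def test_seed_determinism(self):
        ids, seqs = pk.simulate_alignment(TOPO, 600, seed=1)
        a = pk.write_newick(pk.bootstrap_support(ids, seqs, B=50, seed=4))
        b = pk.write_newick(pk.bootstrap_support(ids, seqs, B=50, seed=4))
        assert a == b

    def test_divergent_clades_full_support(self):
        nwk = "((a:0.02,b:0.02):0.5,(c:0.02,d:0.02):0.5,(e:0.02,f:0.02):0.5);"
        ids, seqs = pk.simulate_alignment(nwk, 900, seed=2)
        tree = pk.bootstrap_support(ids, seqs, B=100, seed=0)
        supports = [int(n.label) for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n.label is not None]
        assert supports and min(supports) >= 95


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        s = "ATGGCCTTAGGACCATTAGGC"
        _, rows = pk.progressive_align({"a": s, "b": s, "c": s})
        assert rows == [s, s, s]

    def test_single_codon_indel_single_gap(self):
        s = "ATGGCCTTAGGACCATTAGGCTTCAAG"
        t = s[:12] + s[15:]
        _, rows = pk.progressive_align({"x": s, "y": t})
        gapped = rows[1] if "-" in rows[1] else rows[0]
        assert gapped.count("-") == 3
        i = gapped.index("-")
        assert gapped[i: i + 3] == "---"
        assert rows[0].replace("-", "") == s
        assert rows[1].replace("-", "") == t

    def test_residues_preserved_exactly(self):
        rng = np.random.default_rng(3)
        seqs = {}
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        for i in range(4):
            s = list(base)
            for pos in rng.choice(300, 10, replace=False):
                s[pos] = "ACGT"[int(rng.integers(0, 4))]
            seqs[f"s{i}"] = "".join(s)
        ids, rows = pk.progressive_align(seqs)
        for tid, row in zip(ids, rows):
            assert row.replace("-", "") == seqs[tid]

    def test_alignment_length_close_to_input(self):
        """Repeat-free (virtual) CDS sets align within 5% of the longest
        input."""
        from vatkit import motifscan as ms
        from vatkit import simcluster as sc

        cfg = sc.SimConfig(seed=33, n_accessions=4, sub_rate=0.03)
        anc, regions, _ = sc.simulate_panel(cfg)
        seqs = {}
        for r in regions:
            for lo in r.loci:
                if lo.class_ == "intact" and not lo.is_retro:
                    ann = ms.find_repeats(lo.cds, unit_hint=anc.unit,
                                          cds_id="x")
                    v = ms.build_virtual_cds(lo.cds, ann)
                    seqs[f"{r.accession}.{lo.locus_id}"] = v.sequence
        seqs = dict(list(seqs.items())[:6])
        ids, rows = pk.progressive_align(seqs)
        longest = max(len(s) for s in seqs.values())
        assert len(rows[0]) <= 1.05 * longest

    def test_empty_sequence_rejected(self):
        with pytest.raises(pk.PhyloError):
            pk.progressive_align({"a": "ACGT", "b": ""})


class TestBreakpoint:
    def test_identical_sequences_error_path(self):
        seqs = ["ATGGCC" * 50] * 4
        with pytest.raises(pk.PhyloError):
            pk.breakpoint_scan(["a", "b", "c", "d"], seqs, n_perm=10, seed=0)

    def test_two_topology_junction_found(self):
        ids, sA = pk.simulate_alignment(TOPO, 600, seed=11)
        idsB, sB = pk.simulate_alignment(TOPO_ALT, 600, seed=12)
        m = dict(zip(idsB, sB))
        seqs = [a + m[i] for i, a in zip(ids, sA)]
        res = pk.breakpoint_scan(ids, seqs, n_perm=50, seed=0)
        assert abs(res.best_position - 600) <= 30
        assert res.p_value <= 0.05
        assert res.best_position % 3 == 0
        assert 0 <= res.p_value <= 1

    def test_single_topology_not_significant(self):
        ids, seqs = pk.simulate_alignment(TOPO, 1200, seed=21)
        res = pk.breakpoint_scan(ids, seqs, n_perm=100, seed=1)
        assert res.p_value > 0.05

    def test_seed_determinism(self):
        ids, seqs = pk.simulate_alignment(TOPO, 900, seed=31)
        r1 = pk.breakpoint_scan(ids, seqs, n_perm=30, seed=2)
        r2 = pk.breakpoint_scan(ids, seqs, n_perm=30, seed=2)
        assert (r1.best_position, r1.score, r1.p_value) == (
            r2.best_position, r2.score, r2.p_value
        )
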