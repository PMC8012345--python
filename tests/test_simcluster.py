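"""Simulator: ancestor construction, evolution events, region emission,
amplicon arithmetic and truth I/O."""

import dataclasses

import numpy as np
import pytest

from vatkit import pcrinfer as pc
from vatkit import simcluster as sc
from vatkit._util import revcomp, translate


class TestConfig:
    def test_defaults_valid(self):
        sc.SimConfig().validate()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("ancestor_repeat_count", 0),
            ("ancestor_repeat_count", 8),
            ("unit_nt", 196),
            ("duplication_rate", -0.1),
            ("sub_rate", -1e-9),
            ("nonsyn_hot_window", (0, 35)),
            ("nonsyn_hot_window", (30, 70)),
            ("nonsyn_hot_factor", 0.5),
            ("tree_height", -1.0),
            ("n_accessions", 0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, value):
        cfg = dataclasses.replace(sc.SimConfig(), **{field: value})
        with pytest.raises(sc.SimConfigError) as exc:
            cfg.validate()
        assert field.split("_")[0] in str(exc.value) or field in str(exc.value)


class TestAncestor:
    def test_protein_length_default_k4(self):
        anc = sc.make_ancestor(sc.SimConfig(seed=1))
        assert anc.protein_length == 1467

    def test_protein_length_k1(self):
        anc = sc.make_ancestor(sc.SimConfig(seed=1, ancestor_repeat_count=1))
        assert anc.protein_length == 1467 - 3 * 65

    def test_orf_structure(self):
        anc = sc.make_ancestor(sc.SimConfig(seed=3))
        cds = anc.locus.cds
        aa = translate(cds)
        assert cds.startswith("ATG")
        assert aa.endswith("*") and "*" not in aa[:-1]
        assert len(cds) % 3 == 0

    def test_exon2_holds_exact_tandem_copies(self):
        cfg = sc.SimConfig(seed=5, ancestor_repeat_count=6)
        anc = sc.make_ancestor(cfg)
        a0 = sc.PRE_LEN
        arr = anc.locus.cds[a0: a0 + 6 * cfg.unit_nt]
        assert arr == anc.unit * 6

    def test_determinism(self):
        a = sc.make_ancestor(sc.SimConfig(seed=9))
        b = sc.make_ancestor(sc.SimConfig(seed=9))
        assert a.locus.cds == b.locus.cds
        assert a.locus.introns == b.locus.introns

    def test_introns_are_gt_ag(self):
        anc = sc.make_ancestor(sc.SimConfig(seed=2))
        for intron in anc.locus.introns:
            assert intron.startswith("GT") and intron.endswith("AG")


class TestEvolve:
    def test_null_process_single_unchanged_lineage(self):
        cfg = sc.SimConfig(
            seed=4, duplication_rate=0, crossover_rate=0, te_insertion_rate=0,
            stop_gain_rate=0, sub_rate=0, retro_copy=False,
        )
        anc = sc.make_ancestor(cfg)
        loci, log = sc.evolve_cluster(anc, cfg, np.random.default_rng(0))
        assert len(loci) == 1
        assert loci[0].cds == anc.locus.cds
        assert loci[0].events == [] and log == []

    def test_duplication_shares_prefix_history(self):
        cfg = sc.SimConfig(
            seed=4, duplication_rate=5.0, crossover_rate=0, te_insertion_rate=0,
            stop_gain_rate=0, sub_rate=0, retro_copy=False,
        )
        anc = sc.make_ancestor(cfg)
        loci, log = sc.evolve_cluster(anc, cfg, np.random.default_rng(1))
        assert len(loci) >= 2
        dup_events = [e for e in log if e.kind == "duplication"]
        assert dup_events
        # the first duplication appears in both parent and child logs
        first = dup_events[0]
        child_id = first.detail["child"]
        child = next(lo for lo in loci if lo.locus_id == child_id)
        assert first in child.events

    def test_te_insertion_lengths_and_class(self):
        cfg = sc.SimConfig(
            seed=8, duplication_rate=0, crossover_rate=0, te_insertion_rate=20.0,
            stop_gain_rate=0, sub_rate=0, retro_copy=False,
        )
        anc = sc.make_ancestor(cfg)
        loci, log = sc.evolve_cluster(anc, cfg, np.random.default_rng(2))
        te = [e for e in log if e.kind == "te_insertion"]
        assert te and loci[0].class_ == "pseudo_insertion"
        for e in te:
            assert e.detail["length"] in (sc.TE_EXON1_LEN, sc.TE_LINE1_LEN)

    def test_te_copies_nearly_identical_to_master(self):
        anc = sc.make_ancestor(sc.SimConfig(seed=1))
        rng = np.random.default_rng(0)
        copies = [sc._mutate_te(anc.te_line1, rng, 0) for _ in range(20)]
        for c in copies:
            ident = np.mean([x == y for x, y in zip(c, anc.te_line1)])
            assert ident >= 0.995

    def test_crossover_keeps_k_in_range(self):
        cfg = sc.SimConfig(
            seed=8, duplication_rate=0, crossover_rate=30.0, te_insertion_rate=0,
            stop_gain_rate=0, sub_rate=0, retro_copy=False, ancestor_repeat_count=1,
        )
        anc = sc.make_ancestor(cfg)
        loci, log = sc.evolve_cluster(anc, cfg, np.random.default_rng(3))
        ks = [e.detail["k"] for e in log if e.kind.startswith("crossover")]
        assert ks and all(1 <= k <= 7 for k in ks)
        assert all(e.detail["dk"] != 0 for e in log if e.kind.startswith("crossover"))

    def test_at_most_one_reverse_locus(self, noisy_panel):
        _, _, regions, _ = noisy_panel
        for r in regions:
            assert sum(lo.strand == "-" for lo in r.loci) <= 1

    def test_stop_gain_creates_pseudo_stop(self):
        cfg = sc.SimConfig(
            seed=8, duplication_rate=0, crossover_rate=0, te_insertion_rate=0,
            stop_gain_rate=20.0, sub_rate=0, retro_copy=False,
        )
        anc = sc.make_ancestor(cfg)
        loci, _ = sc.evolve_cluster(anc, cfg, np.random.default_rng(5))
        assert loci[0].class_ == "pseudo_stop"
        assert "*" in translate(loci[0].cds)[:-1]


class TestEmitAndAmplicons:
    def test_truth_coordinates_inside_sequence(self, noisy_panel):
        _, _, regions, _ = noisy_panel
        for r in regions:
            for lo in r.loci:
                assert 0 <= lo.start < lo.end <= len(r.sequence)
                for s, e in lo.exons:
                    assert lo.start <= s < e <= lo.end

    def test_truth_k_equals_literal_copies(self, clean_panel):
        anc, regions, _ = clean_panel
        u = anc.unit
        for r in regions:
            for lo in r.loci:
                if lo.class_ != "intact":
                    continue
                gene = r.sequence[lo.start: lo.end]
                if lo.strand == "-":
                    gene = revcomp(gene)
                count = 0
                i = gene.find(u)
                while i != -1 and gene[i: i + len(u)] == u:
                    count += 1
                    i += len(u)
                    if gene[i: i + len(u)] != u:
                        break
                assert count == lo.k

    def test_null_process_regions_identical(self):
        cfg = sc.SimConfig(
            seed=6, n_accessions=4, duplication_rate=0, crossover_rate=0,
            te_insertion_rate=0, stop_gain_rate=0, sub_rate=0, retro_copy=False,
        )
        _, regions, _ = sc.simulate_panel(cfg)
        assert len({r.sequence for r in regions}) == 1

    def test_panel_determinism(self):
        cfg = sc.SimConfig(seed=15, n_accessions=3)
        _, regions_a, truth_a = sc.simulate_panel(cfg)
        _, regions_b, truth_b = sc.simulate_panel(cfg)
        assert [r.sequence for r in regions_a] == [r.sequence for r in regions_b]
        assert truth_a.equals(truth_b)

    @pytest.mark.parametrize(
        "pair_class,expected",
        [
            ("repeat_spanning", 572 + 195),
            ("exon2_internal", 467),
            ("exon1_exon2", 1502),
        ],
    )
    def test_single_repeat_amplicons(self, pair_class, expected):
        cfg = sc.SimConfig(seed=2, ancestor_repeat_count=1, retro_copy=False)
        anc = sc.make_ancestor(cfg)
        region = sc.emit_region([anc.locus.clone("L1")], cfg)
        pair = next(p for p in sc.panel_primers(anc) if p.class_ == pair_class)
        amps = pc.predict_amplicons(region.sequence, pair)
        assert [a.length for a in amps] == [expected]

    def test_insertion_pseudo_amplicon_3847(self):
        cfg = sc.SimConfig(seed=2, ancestor_repeat_count=1, retro_copy=False)
        anc = sc.make_ancestor(cfg)
        lo = anc.locus.clone("L1")
        lo.te_insertions.append(("intron1", anc.te_exon1))
        lo.class_ = "pseudo_insertion"
        region = sc.emit_region([lo], cfg)
        pair = next(p for p in sc.panel_primers(anc) if p.class_ == "exon1_exon2")
        amps = pc.predict_amplicons(region.sequence, pair)
        assert [a.length for a in amps] == [3847]

    def test_reverse_strand_amplicon_933(self):
        cfg = sc.SimConfig(
            seed=2, duplication_rate=0, crossover_rate=0, te_insertion_rate=0,
            stop_gain_rate=0, sub_rate=0, retro_copy=True,
        )
        anc = sc.make_ancestor(cfg)
        loci, _ = sc.evolve_cluster(anc, cfg, np.random.default_rng(0))
        region = sc.emit_region(loci, cfg)
        pair = next(p for p in sc.panel_primers(anc) if p.class_ == "reverse_strand_exon1")
        amps = pc.predict_amplicons(region.sequence, pair)
        assert [a.length for a in amps] == [933]

    def test_amplicon_arithmetic_all_k(self):
        """Repeat-spanning products follow f + 195k for every k in 1..7."""
        for k in range(1, 8):
            cfg = sc.SimConfig(seed=3, ancestor_repeat_count=k, retro_copy=False)
            anc = sc.make_ancestor(cfg)
            region = sc.emit_region([anc.locus.clone("L1")], cfg)
            pair = next(p for p in sc.panel_primers(anc) if p.class_ == "repeat_spanning")
            amps = pc.predict_amplicons(region.sequence, pair)
            assert [a.length for a in amps] == [572 + 195 * k]


class TestTruthIO:
    def test_round_trip(self, tmp_path, clean_panel):
        _, regions, _ = clean_panel
        region = regions[0]
        paths = sc.write_truth(region, tmp_path)
        genes = sc.read_truth_gff(paths["gff3"])
        assert len(genes) == len(region.loci)
        by_id = {g["locus_id"]: g for g in genes}
        for lo in region.loci:
            g = by_id[lo.locus_id]
            assert (g["start"], g["end"], g["strand"], g["k"]) == (
                lo.start, lo.end, lo.strand, lo.k
            )
            assert g["exons"] == sorted(lo.exons)
            assert g["class"] == lo.class_
        df = sc.read_truth_tsv(paths["tsv"])
        assert len(df) == len(region.loci)

    def test_gff_is_one_based_inclusive(self, tmp_path, clean_panel):
        _, regions, _ = clean_panel
        region = regions[0]
        paths = sc.write_truth(region, tmp_path)
        line = next(
            line for line in paths["gff3"].read_text().splitlines()
            if "\tgene\t" in line
        )
        f = line.split("\t")
        lo = next(x for x in region.loci if x.locus_id == f[8].split(";")[0][3:])
        assert int(f[3]) == lo.start + 1 and int(f[4]) == lo.end

    def test_fasta_round_trip(self, tmp_path, clean_panel):
        _, regions, _ = clean_panel
        region = regions[0]
        paths = sc.write_truth(region, tmp_path)
        text = paths["fasta"].read_text().splitlines()
        assert text[0] == f">{region.accession}"
        assert "".join(text[1:]) == region.sequence
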