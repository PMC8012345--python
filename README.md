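# vatkit

Simulation and analysis of plant NLR (nucleotide-binding-site
leucine-rich-repeat) resistance-gene clusters whose diversity is driven by
tandem duplication and by gain/loss of a near-identical repeat unit inside
the LRR domain — the situation exemplified by the melon *Vat* cluster, where
each homolog carries 1–7 copies of a 65-amino-acid (195-nt) repeat ("R65aa")
in its second exon, and a panel of accessions differs both in the number of
homologs and in the repeat count of each.

The package is written for researchers who annotate such clusters from
long-read assemblies, genotype them by PCR band patterns, and ask how the
copies diversify. It provides:

* **`simcluster`** — a ground-truthed simulator: a five-exon/four-intron
  CC-NLR ancestor (1467 aa at k = 4) evolves by gene duplication, ±1-unit
  unequal crossover (k bounded to [1, 7]), transposable-element insertion
  (2345-nt and 2540-nt LINE-1-like classes), premature-stop gain, point
  substitution with elevated nonsynonymous acceptance inside repeat-unit
  codons 25–35, and one optional intron-less reverse-strand retro-copy.
  Emitted regions carry primer sites obeying the diagnostic amplicon
  arithmetic (below) exactly.
* **`homscan`** — seed-and-extend homology search (k-mer seeding + infix
  alignment, identity > 40%, query coverage > 30%), assembly of collinear
  hits into gene models with GT..AG splice refinement, and classification
  into intact / pseudo_stop / pseudo_insertion / partial.
* **`motifscan`** — detection and counting of the tandem repeat unit in a
  CDS (period scan + changepoint boundaries, codon-aligned), construction
  of **virtual CDSs** with every repeat copy excised (exact length
  conservation), and pre-LRR2 / LRR2 / post-LRR2 block partition.
* **`pcrinfer`** — in-silico PCR (≤1 mismatch, exact 3′ base) and decoding
  of gel band patterns into per-accession "digit strings": one digit per
  homolog, each digit its repeat count. A repeat-spanning product has
  length f + 195·k (f = 572 with the default geometry); dedicated pairs
  give 467 bp (single-repeat exon-2), 1502 bp (exon1–exon2; 3847 bp when a
  2345-nt insertion intervenes) and 933 bp (reverse-strand homolog).
  Co-migrating bands collapse, so the homolog count is a minimum.
* **`siteprob`** — the per-site conditional probability p(i) that a codon
  change is nonsynonymous, computed over all gap-free sequence pairs,
  smoothed with a Gaussian kernel (h = 20 nt for the flanking blocks,
  h = 8 nt for the repeat array) and calibrated by a permutation envelope:
  per-site count tuples are shuffled across codon positions B times and the
  pointwise α/2, 1−α/2 quantiles form the confidence band; excursions are
  reported as peaks/valleys of nonsynonymous acceptance.
* **`phylokit`** — Tamura–Nei (TN93) distances, canonical neighbor joining
  (lowest-index tie-break, negative-branch clamping), codon-block bootstrap
  supports, guide-tree progressive profile alignment with affine gaps,
  newick IO, and a two-segment incongruence scan that locates a
  recombination-style breakpoint as the codon boundary where two
  segment-specific NJ trees fit the segment distance matrices better than
  one tree, calibrated by column permutation.

## Worked example

Simulate a five-accession panel (duplication and unequal crossover only),
run the diagnostic primers on each emitted region and decode the lanes:

```python
from vatkit import simcluster as sc, pcrinfer as pc, motifscan as ms

cfg = sc.SimConfig(seed=42, n_accessions=5, sub_rate=0.0,
                   te_insertion_rate=0.0, stop_gain_rate=0.0)
anc, regions, truth = sc.simulate_panel(cfg)
primers = sc.panel_primers(anc)
for r in regions[:3]:
    bands = pc.bands_from_amplicons(r.accession, primers, r.sequence)
    inf = pc.infer_accession(bands)
    lane = bands.get("repeat_spanning")
    print(f"{r.accession}: bands {lane.lengths if lane else []} "
          f"-> digits '{inf.digits}' (truth '{sc.truth_digits(r)}')")
```

prints

```
acc1: bands [767, 962, 1547] -> digits '1125' (truth '1125')
acc2: bands [1742] -> digits '16' (truth '16')
acc3: bands [1157, 1352] -> digits '134' (truth '134')
```

Each repeat-spanning band decodes as k = (L − 572)/195 — for acc1,
767 → k = 1, 962 → k = 2, 1547 → k = 5 — and the 933-bp reverse-strand
product adds the second digit-1 homolog, giving four homologs with repeat
counts 1, 1, 2, 5. Annotating one extracted CDS recovers its array:

```python
ann = ms.find_repeats(regions[0].loci[0].cds, cds_id="acc1.L1")
print("k =", ann.k, "array =", (ann.start, ann.end))
# k = 5 array = (2442, 3417)
```

The same decoding is exact for every accession whose homologs have distinct
repeat counts; equal counts co-migrate and are counted once — the band
pattern gives a *minimal* homolog number.

A command-line interface mirrors the library:
`vatkit simulate|scan|repeats|pcr|panel|siteprob|tree|breakpoint --help`.

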