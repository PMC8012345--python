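# Methods

This note documents the models, parameter choices and numerical decisions
behind `vatkit`. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## The cluster model

The simulated locus is a CC-NLR gene with five exons and four introns whose
second exon carries a tandem array of k identical-at-birth repeat units of
`unit_nt` = 195 nt (65 codons). The coding layout is fixed: 2442 nt of CDS
before the array (2306 nt in exon 1, a 136-nt exon-2 flank), 195·k nt of
array, and 1182 nt after it (136-nt exon-2 flank, then 400/400/246-nt
exons), so the k = 4 ancestor translates to 1467 aa. Introns are
400/400/300/300 nt with canonical GT..AG ends. These constants were chosen
so that the four diagnostic primer classes obey closed-form amplicon
arithmetic on every intact locus:

| primer class         | product length        | k = 1 |
|----------------------|-----------------------|-------|
| repeat-spanning      | 572 + 195·k           | 767   |
| exon-2 internal      | 272 + 195·k           | 467   |
| exon1–exon2          | 1307 + 195·k          | 1502  |
| …with 2345-nt insert | 3652 + 195·k          | 3847  |
| reverse-strand exon1 | 933 (intron-less copy)| 933   |

The repeat-free flank constant of the repeat-spanning pair (572 nt) is a
property of the primer design, not of the biology; it is carried in
`SimConfig.amplicon_constants` and must be supplied when decoding bands
from a different design.

### Evolution

Each accession evolves independently from the common ancestor over
`tree_height` time units. Structural events follow a continuous-time jump
process with per-lineage rates; substitutions accrue along every lineage
between jumps, so duplicated genes share their pre-duplication history.

* **Duplication** (default rate 1.4/lineage/time): a lineage is copied in
  tandem. e^1.4 ≈ 4 expected homologs per accession, matching a panel in
  which ~4 homologs per accession is typical.
* **Unequal crossover** (default 1.0): ±1 repeat unit, with k confined to
  [1, 7] (the observed range); at the boundary the feasible sign is taken.
  The reverse-strand retro-copy is exempt — it has no tandem partner to
  mispair with — and so is duplication of it, keeping at most one
  reverse-strand locus.
* **TE insertion** (default 0.3): pseudogenises the locus. Two classes:
  a 2345-nt element into intron 1 that splits the repeat-spanning forward
  primer site (so the locus contributes the +2345 exon1–exon2 product and
  no digit), and a 2540-nt LINE-1-like element 10 nt before the exon-2 end
  that splits the shared reverse-primer site (the locus becomes PCR-silent).
  Each insertion copies a per-simulation master element with 0.1% per-base
  divergence, so inserts are ≥99.8% identical to each other, as recently
  active retrotransposons are. One insertion per locus; an insertion
  dominates a prior premature stop in the class label.
* **Stop gain** (default 0.1): a codon is overwritten with TAA.
* **Retro-copy** (optional, default on): at time 0 an intron-less
  reverse-strand copy of the single-repeat ancestor is created —
  retrotransposition of the mRNA — with its own primer sites planted and
  the exon1–exon2 forward site scrambled, reflecting the divergence that
  made the real single-repeat primers lineage-specific. Being intron-less
  it is invisible to the intron-anchored repeat-spanning pair.
* **Substitution** (default 0.01 proposals/site/time): uniform random base
  changes. Proposals that create a stop are rejected (stops arise only via
  the stop-gain event), the start codon, terminal stop and splice
  dinucleotides are conserved, and nonsynonymous proposals are accepted
  with probability `nonsyn_background` (default 0.2) outside the hot
  window and `min(1, nonsyn_background · nonsyn_hot_factor)` inside
  repeat-unit codons 25–35 (default factor 5). The background of 0.2 keeps
  the nominal ×5 factor exactly representable (0.2·5 = 1.0); purifying
  selection on the NLR scaffold with relaxed constraint at the recognition
  surface is the biological reading.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive. Identical configuration and seed give byte-identical FASTA,
GFF3 and TSV outputs.

### What the simulator does and does not emulate

It reproduces the *structure* the analyses rely on: tandem homologs on one
strand plus one reverse-strand copy, 1–7 identical-period repeats in one
exon, the two pseudogene classes, primer-site arithmetic, and a localized
excess of nonsynonymous change. It does not emulate intergenic or intron
sequence realism beyond GT..AG ends, TE sequence families,
between-accession recombination, population structure, or indel evolution
inside the repeat unit (units are gained and lost whole). Tests passing on
simulated panels therefore validate the algorithms' correctness and
calibration, not their robustness to, e.g., unit-internal indels or
primer-site polymorphism in real panels.

## Homology scan and gene models

Queries (the ancestor's exon sequences; the array-bearing exon is
represented by its two repeat-free flanks) are located by exact 12-mer
seeding. Seeds are grouped into diagonal bands (±100); bands with fewer
than two seeds are discarded, because a lone random 12-mer match carries no
homology evidence, and each candidate window is aligned with edlib in
infix (HW) mode. Identity is computed over aligned columns (end-gap-free
on the target), coverage relative to the query, and a net-score floor
(matches − edits ≥ 0.25·|query|) removes the ~50%-identity gap-riddled
alignments an unconstrained edit distance produces on unrelated sequence.
Thresholds default to identity > 40% and coverage > 30%.

Same-strand hits within `max_intron` = 3000 nt form one locus. A gap
between consecutive hits becomes an intron when GT..AG (CT..AC for
minus-strand models) motifs are found within ±30 nt of the hit boundaries;
linked query pairs (the two flanks of the array exon) are always bridged
into one exon; gaps larger than `insert_threshold` = 2000 nt are never
bridged. Model termini are snapped to the reference ATG and an in-frame
stop within ±12 nt, as manual curation against a reference CDS does.
Classification: *partial* when a required query is unmatched, else
*pseudo_insertion* when any inter-exon gap exceeds 2000 nt (ordinary
introns here are ≤400 nt, intron+TE ≥ 2645 nt — the threshold separates
the two populations), else *pseudo_stop* on an internal stop, else
*intact* for a complete ORF. On default-noise panels this recovers locus
count, strand and class exactly in the tested aggregates.

## Repeat annotation and virtual CDSs

De-novo detection scans lags 186–204 for the best windowed self-match
fraction (threshold 0.6), anchors one interior copy at the best window,
tiles it across the CDS, and places the array boundaries at the
changepoints of the tile-match indicator — the codon boundary maximising
the cumulative (0.5 − match) sum on each side. Copies are then cut every
195 nt from the boundary; terminal copies under `min_copy_identity`
(default 70% — "near-perfect" is not quantified more precisely, so the
threshold is exposed) are trimmed. Copy boundaries are always codon
multiples, keeping the virtual CDS in frame. A single copy has no
self-periodicity, so k = 1 calls require `unit_hint` (a reference unit),
exactly as real single-repeat homologs are annotated against a reference
gene; recovery is ≥99% for k ≥ 2 at ≤5% per-copy mutation (measured 100%).

Virtual CDSs remove every copy interval; original length equals virtual
plus excised length exactly, and the coordinate map back to the original
is strictly increasing. Block partition is pre-array / array / post-array,
covering the CDS exactly.

## Band decoding

Within a gel lane, co-migrating products collapse: the repeat-spanning lane
yields one digit per *distinct* repeat count, so the inferred homolog
number is a minimum. Decoding: each repeat-spanning band gives
k = round((L − f)/195), valid for k ∈ 1..7 within ±5 nt; a 933-bp
reverse-strand product adds a digit-1 homolog (invisible to the
repeat-spanning pair); a 1502-bp or 467-bp product adds a digit 1 only if
none is implied; exon1–exon2 bands are decoded first against 1307 + 195·k
and then against the insertion class 3652 + 195·k (3847 is within 5 nt of
1307 + 195·13, so the insertion class must be tried before rejecting), and
set a flag rather than a digit. Off-grid bands raise an error naming the
length. Adding a band never decreases the homolog count. A stop-codon
pseudogene amplifies like an intact gene and is counted — the premature
stop is invisible to PCR, one of the method's stated limits.

## Per-site nonsynonymous probability

For codon column i, over all unordered pairs with gap-free, non-stop,
differing codons, p(i) is the fraction of pairs whose codons encode
different amino acids. The curve q(x) is a Nadaraya–Watson average of the
defined p(i) at codon midpoints under a Gaussian kernel; h = 20 nt for the
flanking blocks and h = 8 nt for the repeat array by default (both
exposed). The confidence band shuffles the per-site (n_diff, n_ns) tuples
across the block's codon positions B times (default 1000; the permuted
unit is the whole site tuple, preserving the marginal intensity
distribution while destroying positional structure) and takes pointwise
α/2 and 1 − α/2 quantiles; peaks/valleys are excursions beyond the band.
Null calibration: on iid-column alignments the mean flagged fraction is
≈0.05 at α = 0.05 (measured 0.052–0.057 over 100 replicates).

Power: on panels simulated with the ×5 hot window, the per-site statistic
is nearly binary (most segregating sites reflect a single historical
mutation), which caps the contrast-to-noise ratio of the smoothed curve;
deeper panels blunt the contrast again because multi-variant sites drive
the background p(i) toward 1. At the most favourable tested panel shape
(32 accessions, proposal rate 0.04/site) the codons-25–35 peak is flagged
in roughly 8 of 10 replicates — far above the 5% nominal false-positive
level but not near-certain; the acceptance script reports the measured
rate.

## Phylogenetics

TN93 distances use the closed form with the two transition classes
distinguished and base frequencies estimated empirically from each pair's
comparable sites; saturated pairs (non-positive logarithm argument) are
flagged infinite and capped at twice the largest finite distance for tree
building. Under uniform composition and equal substitution rates the value
equals the Jukes–Cantor form to ≤1e-9 (measured ≤1e-16). Neighbor joining
is the canonical Saitou–Nei agglomeration, ties broken toward the
lowest-index pair, negative branch lengths clamped to zero with the
deficit moved to the sister edge; recovery from additive matrices is exact
(100/100 random trees ≤12 taxa, and topologies agree with an independent
NJ implementation). Bootstrap resamples codon blocks, B = 500 by default;
supports are percentages of replicate trees containing each split of the
point tree, written as internal node labels in newick.

The progressive aligner builds a guide tree from k-mer Jaccard distances
(or accepts one), and merges profiles with an affine-gap Gotoh DP
(match +2, mismatch −1, gap open −6, extend −1); output columns preserve
input residues exactly.

### Breakpoint scan

For every candidate codon boundary b (both flanks ≥60 nt with at least one
variable site, both segments with ≥4 distinct sequences), NJ trees are
fitted to the two segments' TN93 matrices and the score is the
length-weighted improvement of the two-tree least-squares distance fit over
the single full-alignment tree:

score(b) = Σ_seg (len_seg/L)·[ r(D_seg, T_full) − r(D_seg, T_seg) ],

with r the sum of squared distance-fit residuals. The length weighting is
a variance stabilisation: segment distance noise scales as 1/length, and
without it the score is dominated by short-segment noise at the alignment
ends. The p-value is the fraction of column-permuted alignments whose best
score reaches the observed best; the null uses the identical statistic, so
the test stays calibrated (measured: junction within ±30 nt in 96/100
two-topology concatenations; 7/100 false positives at p ≤ 0.05 on
single-topology nulls). This is a deliberately simple distance-based
stand-in for likelihood-based recombination detection: one breakpoint,
distance-fit residuals instead of likelihoods, column permutation instead
of information-criterion model comparison.

## Problem sizes and defaults

The shipped tests and the acceptance script use: 500 accessions for the
round-trip, 500 CDSs for repeat recovery, 100 random additive matrices,
100 null alignments (B = 500) for band coverage, 40 panels for hot-window
detection, and 100 runs each for breakpoint power and size — sizes at
which the binomial uncertainty of each rate is a few percent and the whole
acceptance run completes in a couple of minutes on one CPU.

## Known limitations

* Homolog divergence beyond ~25% defeats the fixed 12-mer seeding before
  the identity threshold does.
* De-novo repeat detection cannot see a single copy (use `unit_hint`), and
  fractional terminal copies are deliberately excluded from k.
* The band decoder assumes a single cluster design (one flank-constant set
  per primer class) and rejects, rather than reinterprets, off-grid bands.
* The breakpoint scan fits one breakpoint; serial recombination events
  yield only the dominant boundary.
* p(i) is tree-free: shared ancestry among pooled repeat copies is not
  corrected for, so the permutation band calibrates positional structure,
  not phylogenetic non-independence.
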