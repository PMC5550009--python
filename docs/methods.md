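# Methods

This note records the models, parameter choices and numerical conventions
behind `thermedit`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Hyper-editing detection

A-to-I editing is read as A→G by sequencers. Reads carrying dense clusters
of edits exceed a standard aligner's mismatch budget and are discarded; the
detector recovers them by collapsing the mismatch type. For a mismatch type
X→Y, both orientations of the read and the plus strand of the genome are
transformed (every X replaced by Y) and the read is re-placed in the reduced
three-letter alphabet. A placement is accepted only when a single best
candidate exists within the mismatch budget; ties drop the read (counted in
QC). The original sequences are then compared at the placement to recover
mismatches of the target type.

Editing on the plus strand appears as A→G; editing on the minus strand
appears as T→C once the read is oriented to the plus strand, so editing
detection runs the A→G and T→C transforms and reports the latter as
A-on-minus sites. All 12 ordered mismatch types are run for the QC spectrum.
Because the data are unstranded, each run X→Y is canonicalized to the strand
on which the reference base is X, with A/C chosen as the plus-strand
representative; the A→G class therefore aggregates the A→G (plus) and T→C
(minus) runs, and a balanced ~50/50 strand split together with a flat
read-position histogram is the signature of genuine editing rather than
sequencing artifacts.

Cluster rules, applied per read after discarding mismatches below the
quality floor or within the end-exclusion zone:

- `min_edits` = 4 target-type mismatches (the field's pipelines require a
  "dense" cluster without quantifying it; 4 is conservative and
  configurable);
- span = (last − first mismatch position + 1) ≥ `span_fraction` (0.10) × read
  length, computed on the full read length;
- `end_exclusion` = 6 bases: mismatches within 6 nt of either read end (in
  sequencing orientation) are untrusted — harmonized with the 6-nt
  quantification trim — and are removed *before* the other two rules rather
  than vetoing the whole cluster, which keeps mid-read clusters whose reads
  merely carry an additional spurious end mismatch;
- `quality_min` = Phred 30, common practice for editing pipelines.

Clusters on the same contig and strand merge into a region when the genomic
gap between them (next start − previous end, half-open coordinates) is at
most `max_gap` = 20 bases; a gap of exactly 20 merges, 21 does not. Region
boundaries run from the first base of the upstream cluster to the last base
of the downstream cluster.

The first-pass aligner is an embedded exact-seed (20-mer, three seed
offsets), ungapped-extension mapper with a budget of 4 mismatches per 100
bp. What downstream stages consume is only its contract — unique placements,
ambiguous reads excluded, budget failures pooled for hyper-editing — so any
aligner honoring that contract can be substituted. The mismatch budget that
routes reads to the unaligned pool is not something the upstream literature
fixes; it is exposed as a parameter.

## Quantification

Editing level is G/(A+G) per site with counts oriented to the site strand
(plus-strand T/C reads count as A/G at a minus-strand site). Bases within
`trim` = 6 nt of either read end or below Phred 30 are ignored; bases that
are neither A nor G are tallied separately and excluded from the level.
Support filtering keeps sites with ≥ 2 G reads at level ≥ 1% in at least one
sample.

The editing index of a site set pools counts before dividing:
`Σ G / Σ (A+G)`, the fraction of inosines among all expressed adenosines.
This equals the coverage-weighted mean of per-site levels (tested as an
algebraic identity) and is invariant to splitting the set and pooling
counts. Pipelines pass both uniquely aligned reads and the realigned
hyper-edited reads into the pileup; excluding the recovered reads would
censor exactly the most heavily edited molecules and bias the index
downward (at a planted per-site rate of 0.3 and a 4-mismatch budget the
bias is about −0.02, which the recovered reads remove).

Genomic categories are assigned with precedence CDS > 5'UTR > 3'UTR >
noncoding-exon > intron > intergenic, first gene id on ties. The precedence
is a package choice: external annotators used in this field do not document
theirs.

## Differential editing

Per condition pair and site, Pearson's χ² (df = 1, no continuity correction
— the coverage filter keeps expected counts comfortably large) on the 2×2
table of (G, A) counts, skipping sites with a zero margin, followed by
Benjamini–Hochberg adjustment across the tested sites of that pair. A site
is *significant* only when q ≤ 0.05, both conditions have ≥ 50 informative
reads, and the absolute level difference exceeds 0.20. With three or more
conditions the comparisons are pairwise (each pair BH-adjusted separately),
the simplest reading of "difference between temperatures"; an any-pair
union view can be formed from the emitted table.

## Gene-set bootstrap

The statistic is the pooled editing index of a gene set. Null sets of the
target's size are drawn without replacement from a control pool — by
default the top 60% of genes ranked by mean expression — B = 10,000 times
(configurable), and the one-sided add-one p-value
`p = (1 + #{null ≥ observed}) / (B + 1)` is reported, matching the
directional question "is this set more edited than expected". Under the
null the p-values are uniform on a grid of (B+1) values; the calibration
test verifies this by KS against the uniform distribution.

## Inverted-repeat (dsRNA) search

A 40-nt window centered on the site (site at position 20 of 1..40; for a
region, its midpoint) is aligned against the ±2 kb same-strand flanks:
antisense mode aligns against the reverse complement of the flank (the
duplex-forming configuration), sense mode against the flank as-is (the
negative control), and the edited modes first substitute G at the known
edited window positions. Each flank side is searched separately so no
artificial junction sequence is created.

The aligner finds every exact 7-mer shared by window and flank and extends
each seed on both sides with an anchored affine-gap DP (match +2, mismatch
−3, gap of length g costs 2 + 2g). The extension rectangles are capped at
the remaining window length plus one window length of subject: any larger
subject shift needs gaps costing more than the total attainable match
score, so no optimal positive-scoring local alignment is lost. Consequently
the best seeded score provably equals the full Smith–Waterman optimum
whenever a 7-nt exact match lies on an optimal path (verified against an
independent exact aligner). An E-value cutoff is unnecessary at these
lengths; the implicit floor is the seed score itself (14). A window is
matched when identity (matches / alignment columns) ≥ 70% and coverage
(aligned window residues / 40) ≥ 70%; both thresholds are monotone, i.e.
raising either can only unmatch. Coverage is defined against the 40-nt
window; a region-length variant can be computed by centering windows on
region midpoints, which is what the pipeline does.

## Conservation and fold overlap

The conservation profile is the per-offset mean of a per-base score track
over −20..+20 (site-strand oriented) for three strata: sites supported by
more than one event, single-event sites, and an equal-sized seeded random
sample of genomic adenosines (optionally restricted to expressed regions).
Tracks are consumed as fixed-step wiggle or 3-column TSV. Fold overlap is
the percentage of sites inside conserved-structure intervals (BED, 0-based
half-open), rounded to two decimals.

## Synthetic data

The generator encodes exactly the structure the analysis assumes, nothing
more:

- uniform-composition random genome (default 200 kb) with a simple gene
  model (genes tiling 60% of the genome, each 5'UTR + three CDS exons +
  two introns + 3'UTR, alternating strand);
- editing clusters laid out in equal-width non-overlapping slots; cluster
  strands alternate so site calls are strand-balanced by construction;
  within a cluster, site positions are written into the genome as
  adenosines with inter-site gaps of 3–7 nt (span ≥ 10% of the read
  length), and the −1/+1 context bases are drawn with P(G at −1) = 0.05 and
  P(G at +1) = 0.40 — the ADAR-like depletion/enrichment;
- per-condition per-site editing rates; the default regimes are a cold-like
  condition at 0.6 and a warm-like condition at 0.2 per site, mirroring
  "higher rate at low temperature, lower rate at high temperature";
- for a configurable fraction of clusters, the reverse complement of the
  40-nt cluster core is copied onto the same strand 200–2000 nt downstream
  (a perfect inverted repeat);
- reads drawn uniformly, 50/50 from both strands; planted conversions
  applied on the site strand, then independent uniform sequencing errors
  (default 0.1% per base); constant Phred-40 qualities — the error process
  is explicit rather than quality-driven; single-end only, since that
  exercises every stage.

One integer seed drives everything through fixed-label substreams, so equal
configurations give byte-identical FASTA/FASTQ/truth outputs.

What passing these tests shows — and does not. The simulation validates the
detection rules, coordinate bookkeeping, strand logic, estimator
calibration and the search algorithms against known truth. It does not
model splicing, indels, coverage bias, quality-dependent errors, genomic
polymorphism or imperfect/branched inverted repeats, so performance numbers
on synthetic data (e.g. site sensitivity ≈ 0.93 at 30× and rate 0.8) are
upper bounds on what identical parameters would achieve on real libraries.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale problems chosen to make the
measured quantities statistically meaningful: 1 Mb / 200 clusters / 30×
for site recovery (~1,200 truth sites), ≥ 500 called sites for strand-split
checks, pooled site coverage ≥ 5,000 for index recovery (binomial SD
≈ 0.006), 10 × 1,000 null sites for FDR calibration, 200 replicates for
bootstrap calibration. Coordinates are 0-based half-open internally;
1-based positions appear only in TSV site tables. Levels at zero coverage
are NaN and excluded; a zero-denominator editing index is reported as
undefined rather than zero. Ambiguous placements are dropped, never
guessed; all ties (equal alignment scores, equal category precedence) break
deterministically toward the first candidate in sorted order.

## Known limitations

- The embedded aligner is ungapped and exact-seeded; true indel-containing
  or spliced reads are outside its contract (and outside the cluster
  definition, which is indel-free).
- The QC spectrum runs twelve transformed realignments and therefore builds
  twelve genome indexes; on large genomes this is the most memory-hungry
  stage.
- Strandedness of the library is not modeled; transcript strand is inferred
  from the mismatch identity, which is correct for A→G editing but cannot
  distinguish a genuinely stranded artifact the way a stranded library
  could.
- The bootstrap conditions on the gene-level counts as fixed; it does not
  propagate per-site sampling noise into the null.
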