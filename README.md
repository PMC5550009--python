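# thermedit

Temperature-resolved analysis of A-to-I RNA editing from short-read RNA-seq.

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA; sequencers
read inosine as guanosine, so editing appears as A→G mismatches against the
genome. ADAR often edits its substrates at many nearby positions, producing
*hyper-edited* reads so dense with A→G mismatches that standard aligners
reject them. In poikilotherms such as *Drosophila*, both the amount and the
specificity of editing shift with ambient temperature, which makes a
cluster-aware, condition-comparing pipeline necessary. `thermedit` provides
that pipeline for researchers studying editing landscapes across conditions:

- **Hyper-editing detection** by base-transformed realignment: reads and
  genome are collapsed (A→G), unalignable reads are re-placed uniquely in the
  reduced alphabet, and the recovered high-quality A→G mismatch clusters are
  filtered by three rules (≥ 4 edits, span ≥ 10% of the read, no mismatch
  within 6 bases of a read end). Clusters ≤ 20 bases apart merge into
  hyper-edited regions. All 12 mismatch types are run for QC; only A→G is
  treated as editing.
- **Quantification**: per-site editing level `G/(A+G)` with base-quality and
  read-end trimming, support filtering (≥ 2 G reads at level ≥ 1%), and the
  pooled *editing index* `Σ G / Σ (A+G)` — the fraction of inosines among all
  expressed adenosines of a site set.
- **Differential editing**: per-site Pearson χ² on the 2×2 (G, A) ×
  (condition A, condition B) table, Benjamini–Hochberg FDR at 5%, plus
  coverage (≥ 50 reads) and effect-size (|Δlevel| > 0.20) filters.
- **dsRNA context**: a blastn-like word-seeded local aligner searches ± 2 kb
  of flanking sequence for an inverted-repeat partner of the 40-nt window
  around each site (match when identity ≥ 70% over ≥ 70% of the window), with
  sense-strand and edited-form (A substituted by G) controls.
- **Conservation and structure context**: per-offset conservation profiles
  stratified by event support against a random-adenosine background, and
  overlap of sites with conserved-RNA-structure intervals.
- **Gene-set bootstrap**: the editing index of a target gene set against
  null sets resampled from the most-expressed control pool,
  `p = (1 + #{null ≥ observed}) / (B + 1)`.
- **Synthetic data with planted truth**: genomes, gene models, clustered
  editable adenosines with an ADAR-like context (G depleted at −1, enriched
  at +1), per-condition editing rates, inverted repeats, strand-balanced
  reads with uniform sequencing error — so every stage is testable end to end
  and evaluated against known truth.

## Worked example

Run the whole pipeline on a synthetic dataset (two conditions: a cold-like
regime editing at rate 0.6 per site and a warm-like regime at 0.2):

```python
from thermedit.pipeline import RunConfig, run_pipeline
from thermedit.simulate import SimConfig

cfg = RunConfig(
    outdir="demo_out", seed=17,
    sim=SimConfig(
        genome_length=60_000, n_genes=6, n_clusters=8,
        per_site_edit_rate={"T18": 0.7, "T29": 0.25},
        coverage=20, ir_fraction=0.5, seed=17,
    ),
    min_cov=20, max_structure_sites=6, bootstrap_B=200,
)
report = run_pipeline(cfg)
print({c: round(v, 3) for c, v in report["editing_index"].items()})
print(report["evaluation"]["T18"])
```

prints

```
{'T18': 0.694, 'T29': 0.237}
{'n_truth': 56, 'n_called': 57, 'true_positives': 56,
 'sensitivity': 1.0, 'precision': 0.9824561403508771}
```

i.e. the pooled editing index recovers each regime's planted per-site rate
(0.7 and 0.25), and all 56 planted sites are recovered with a single false
call. The output
directory contains the stage tables (sites, regions, pileups, differential
tests, structure matches, conservation profile), `report.json`, and a
manifest with versions, seed and parameter hash.

The same stages are available from the shell:

```bash
thermedit simulate --seed 17 --out sim/
thermedit detect --genome sim/genome.fa --reads sim/reads_T18.fq --out det/
thermedit all --seed 17 --out run_out/
```

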