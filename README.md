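# methaplo

Block-level co-methylation and co-hydroxymethylation analysis for
base-resolution bisulfite data. oxBS-seq reads out 5-methylcytosine (5mC)
and TAB-seq reads out 5-hydroxymethylcytosine (5hmC) at single-CpG,
single-molecule resolution; `methaplo` turns the per-read CpG call strings
("methylation haplotypes") from both assays into:

- **modified-site calls** — a binomial test of each CpG's "C" count
  against the conversion-error null, Benjamini–Hochberg corrected,
  called at q ≤ 0.05 with coverage ≥ 5; sites called in *both* channels
  are **co-modified** (different molecules at one position carry
  different marks — a cell-subpopulation signature);
- **haplotype blocks** — maximal runs of CpGs whose adjacent pairs are in
  methylation linkage disequilibrium,
  r² = (P_AB − P_A·P_B)² / (P_A(1−P_A)·P_B(1−P_B)), estimated over reads
  covering both sites; MHBs use cutoff 0.5 on the 5mC channel, hMHBs use
  0.2 on the 5hmC channel restricted to gene bodies, both with ≥ 4 CpGs;
- **methylation haplotype load** — MHL = Σᵢ i·fᵢ / Σᵢ i, where fᵢ is the
  fraction of fully methylated length-i substrings among all observed
  length-i substrings of reads clipped to the block; MHL separates
  coordinated from scattered methylation at equal average level (AML);
- **tissue specificity** — TSI = Σⱼ (1 − 10^MHL(j)/10^MHL(max)) / (n−1)
  over a block's per-tissue MHLs; TSI > 0.6 marks tissue-specific blocks,
  the rest split into shared-low/high by mean MHL;
- **enrichment and overlap statistics** — log2(observed/expected) scores
  with CpG-content-proportional expectations, matched random-sampling
  nulls (length- or CpG-count-matched regions re-placed in a universe,
  10,000 reps, empirical p with the +1/(n+1) correction), exact
  hypergeometric tails for count tables, midpoint-distance histograms
  (100-bp bins within 5 kb), and active/poised enhancer classification
  from distal H3K4me1 ± H3K27ac peaks.

A synthetic-cohort generator with planted, recoverable epiallele
structure makes the whole stack testable without sequencing data: within
a planted block each simulated molecule is fully modified with per-tissue
probability π or fully unmodified, so the expected MHL is exactly π and
adjacent in-block r² tends to 1.

The package is for epigenomicists analyzing multi-tissue oxBS/TAB
cohorts, and for methodologists who want a tested, read-level reference
implementation of MHL/MHB-style statistics.

## Worked example

```python
from methaplo import RunConfig, run_pipeline

cfg = RunConfig(outdir="scratch/pipeline_demo", seed=11, n_reps=1000)
result = run_pipeline(cfg)
print(result.mhl.round(2))
print(result.classification["class"].value_counts().to_dict())
```

prints (MHL matrix excerpted):

```
           cerebellum  cortex  olfactory_bulb
MHB_00000        0.83    0.18            0.11
MHB_00001        0.86    0.76            0.78
MHB_00002        0.14    0.10            0.13
MHB_00003        0.12    0.78            0.07
...
{'tissue-specific': 4, 'shared-high-MHL': 4, 'shared-low-MHL': 4}
```

Each row is one discovered MHB, each entry its per-tissue methylation
haplotype load. `MHB_00000` carries its load in the cerebellum only
(TSI ≈ 0.8 > 0.6 → tissue-specific); `MHB_00001` is uniformly high
(shared-high); `MHB_00002` uniformly low (shared-low). The demo cohort
plants four blocks of each design, and the classification recovers all
twelve. `examples/` contains one short script per capability
(simulation, site calling, block discovery, MHL/TSI, enrichment, full
pipeline); each prints its numbers with a note on what they mean.

A thin CLI mirrors the library:

```bash
methaplo run --outdir out --seed 11
methaplo call-sites --counts counts.tsv --error-rate 0.005 --out calls.tsv
methaplo call-blocks --reads reads_a.tsv --reads reads_b.tsv --out blocks.bed
```

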