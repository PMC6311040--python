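# Methods

## Data model

The unit of evidence is the methylation haplotype: the ordered binary
modification states of the CpGs covered by one sequencing read (or read
pair), on one channel. oxBS-seq reads report 5mC ("1" = methylated);
TAB-seq reads report 5hmC ("1" = hydroxymethylated). Haplotype-table
positions are 1-based forward-strand C coordinates (Bismark convention);
all interval arithmetic (segments, blocks, BED I/O) is 0-based half-open.
A block's BED record spans from (first member CpG − 1) to (last member
CpG). Calls from the reverse-strand G of a CpG dyad are assumed collapsed
onto the forward-strand C upstream of this package; the simulator emits
forward-strand calls only.

Analysis segments ("sequenceable and mappable" regions) are assembled by
merging read footprints whose gaps are ≤ `max_gap` (default 500 bp; the
underlying notion of a high-quality mapping region is not quantitatively
pinned down anywhere authoritative, so the gap rule is configuration).

## Site calling

Each CpG's modified count N_C out of coverage N_C + N_T is tested against
the null that every "C" readout is a conversion failure:
p = P(X ≥ N_C), X ~ Binomial(N_C + N_T, ε). The upper tail is the only
direction that tests *presence* of the mark. ε is a named input per
channel, ideally estimated from the assay's own spike-in controls
(`estimate_conversion_error`: pooled misread fraction across spike
contigs, floored at 1/(total+1) when no misread is seen so the binomial
stays well-defined). BH correction is applied genome-wide per channel per
tissue (statsmodels' step-up implementation); a site is called at
q ≤ α = 0.05 **and** coverage ≥ 5, with levels N_C/(N_C+N_T) reported for
every site regardless of call status. Co-modified CpGs are the
intersection of the two channels' called position sets. Overdispersion
(beta-binomial) is deliberately out of scope.

## Block discovery

Methylation LD between two CpGs is r² = D²/(P_A(1−P_A)P_B(1−P_B)),
D = P_AB − P_A·P_B, estimated over reads covering both sites with
non-missing calls. An estimate is *undefined* — flagged, never an
exception — when either marginal is 0 or 1 or fewer than
`min_pair_reads` (default 5) reads cover the pair. Values are clipped to
[0, 1] against floating-point fuzz.

Within each segment, blocks are maximal runs of consecutive CpGs whose
every adjacent pair has a defined r² at or above the cutoff (0.5 for
MHBs, 0.2 for hMHBs), keeping runs of ≥ `min_cpgs` = 4 CpGs. The
candidate-plus-extension description of block growth reduces to exactly
this maximal-run scan under a single cutoff, which is what we implement;
requiring the full pairwise matrix to pass instead would only fragment
blocks and is not the adjacent-pair semantics we adopt. Undefined pairs
*break* runs — a conservative choice that prevents blocks from spanning
gaps with no co-coverage evidence. Discovery runs on haplotypes pooled
across tissues (the LD signal is a property of the combined cohort);
per-tissue MHL is computed afterwards on the shared block set, and a
test asserts that every reported adjacent pair indeed passes the cutoff
on the pooled reads. hMHB discovery masks CpGs outside gene bodies
before partitioning, because TAB-seq's 5hmC signal outside gene bodies
sits within the assay's error range and would produce spurious low-level
blocks; hMHBs reuse min_cpgs = 4 (stated only for MHBs; mirrored as the
default here).

## MHL, AML, TSI

MHL = Σᵢ wᵢ·fᵢ / Σᵢ wᵢ with wᵢ = i, where fᵢ is the fraction of fully
modified contiguous substrings of length i over all observed substrings
of length i from reads clipped to the block. Lengths with zero observed
substrings drop out of both sums; substrings never span a missing call
(a "?" splits the read into independent runs). The linear weight is the
originating definition; the weight function is a hook
(`mhl_from_strings(..., weight=...)`). Blocks with fewer than
`min_reads` = 5 informative reads get a missing value — never a silent
zero. AML is the plain fraction of "1" calls over the same clipped reads.

A note on the often-quoted AML ≥ MHL bound: it holds whenever all
clipped haplotypes have equal length (per-read, the fully-modified
window fraction is non-increasing in window length), and that is what
our property test asserts. With heterogeneous clipped lengths it can
fail — e.g. reads {111, 0} give MHL 0.958 > AML 0.75, because only the
long fully-methylated read contributes to the longer substring lengths.

TSI = Σⱼ (1 − 10^MHL(j)/10^MHL(max)) / (n − 1) over the non-missing
per-tissue MHLs; the maximal tissue contributes zero, so equal loads
give TSI = 0 and TSI → 1 as non-maximal loads vanish. Classification:
TSI > 0.6 (strict) → tissue-specific; otherwise shared, split into
low/high by the cross-tissue mean MHL against `shared_split` = 0.5 — a
natural midpoint for a bimodal load distribution; the boundary used in
the original three-class split was never printed, so it is exposed as
configuration. Strict missing-data mode (default) leaves blocks with any
missing tissue unclassified; a lenient mode would renormalize n, but
silently comparing TSIs computed over different tissue sets is a foot-gun,
so strict is the default.

## Enrichment and overlap statistics

All score-form statistics are log2(observed/expected) with
expected = (calls genome-wide) × (CpGs in element) / (CpGs genome-wide),
applied at element, gene and block level. Zero expectation → NaN
(undefined, flagged); zero observed with positive expectation → −inf
sentinel, also flagged; a gene/block is "enriched" iff its score > 0.

The matched-resampling null re-places |templates| regions uniformly in a
universe, matched on length (coordination analyses) or on CpG count
(element enrichment), selected by flag. Placements within one rep are
mutually non-overlapping (rejection sampling, interval choice weighted by
its number of valid starts), which makes the null exactly hypergeometric
on a slot universe — the property the calibration test checks (KS
distance < 0.02 at 10,000 reps against Hypergeom(10,4,5)). Empirical
p = (1 + #{reps ≥ observed}) / (n_reps + 1), the standard
permutation-test correction that never returns exactly 0. The exact
hypergeometric upper tail is used for count tables (class-level
co-modification enrichment: population = classified blocks, successes =
enriched blocks, draws = class size). For block-vs-block overlap both
routes are reported rather than forcing one parameterization: collapsing
continuous placements into a hypergeometric population is ill-posed, so
the empirical p carries the sampling analysis and the exact test carries
the count tables.

Midpoint-distance histograms bin each A-block's distance to the nearest
B-block midpoint into 100-bp bins up to 5 kb; blocks beyond 5 kb or on
chromosomes without B blocks are counted separately, so histogram total
plus excluded equals |A|. Enhancer classification keeps H3K4me1 peaks
farther than `distal_bp` = 2000 bp from every TSS (the "distal" radius
is not standardized; 2 kb is a conventional promoter exclusion) and
labels them active when overlapping H3K27ac, else poised. The overlap
predicate everywhere is ≥ 1 bp intersection.

## Synthetic cohort

The generator plants a two-component epiallele mixture per block: each
simulated molecule is fully modified with per-tissue probability π or
fully unmodified; background CpGs are independent Bernoulli draws. This
is the simplest process producing tightly coupled neighbor states — the
phenomenon block discovery exists to find — with clean closed forms:
expected MHL = π, in-block adjacent r² → 1 for 0 < π < 1, background
r² → 0. Conversion errors flip calls independently per CpG (ε_fp: a
truly unmodified base reads "1", default 0.005; ε_fn: a modified base
reads "0", default 0.02 — plausible magnitudes for bisulfite-chemistry
assays; the observed spike-in rates were never printed, so both are
configurable). Reads cover a contiguous window of CpGs (uniform start,
fixed span); a missing-call mechanism is tolerated downstream but not
generated by default. One RNG stream per (tissue, channel), keyed from
the master seed via `SeedSequence` spawn keys, so adding a tissue leaves
the others' reads byte-identical. Background and error rates are
parameters of `simulate_reads` rather than per-block fields: they are
properties of the assay and cohort, not of a planted block.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: sequence-level artifacts (no FASTQ, mapping or
PCR duplicates), non-CpG methylation, k > 2 epiallele mixtures,
read-depth heterogeneity, and correlated (rather than per-base
independent) conversion failures.

## Demo cohort and problem sizes

The bundled demo (pipeline defaults) is 12 segments × 24 CpGs (~40 bp
mean spacing), three tissues, 200 reads/segment/tissue/channel, span 6.
It plants 12 5mC blocks — four tissue-specific (π = 0.85 in one rotating
tissue, 0.15 elsewhere), four shared-high (0.85 everywhere), four
shared-low (0.15) — and a π = 0.5 5hmC block in each gene-body segment
(even-indexed segments are annotated gene bodies). 5mC background is
0.45 (independent, hence uncoupled); 5hmC background 0.03. These sizes
give per-block MHL standard errors of a few hundredths, comfortably
inside the classification margins, while the whole pipeline runs in
about a second. Validation simulations use larger sizes where precision
matters: 10,000 reads for mixture-weight recovery (3-SE bands), 10,000
null sites for error control, 50 segments for block recovery, 10,000
reps for resampling calibration.

## Numerical choices and degenerate inputs

- r² clipped to [0, 1]; undefined estimates carry NaN plus a flag.
- Empty inputs return empty outputs (site caller, block caller,
  segment derivation); parsers reject malformed lines with the line
  number, duplicate count rows, negative counts, and zero-length BED
  intervals.
- BH on an empty vector returns an empty vector; a single p maps to
  itself.
- `classify_blocks` uses strict inequalities at both thresholds, so a
  block sitting exactly at TSI = 0.6 is shared.
- Pipeline configs are validated (every threshold within its domain)
  before any compute; stage outputs are checksummed into a manifest and
  a stage-completion state file is updated as the run progresses, so a
  partial failure leaves completed outputs and a marker behind.

## Known limitations

Real Bismark alignments must be converted to the haplotype-table format
externally (a BAM adapter is documented as out of scope and untested);
strand collapsing for real dyad data is the caller's responsibility; the
binomial model ignores overdispersion, so its error control on real data
is anti-conservative when biological variance exceeds the conversion
noise; and the resampling machinery assumes templates fit inside the
universe intervals (it raises otherwise rather than silently shrinking
templates).
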