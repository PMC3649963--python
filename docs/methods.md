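# Methods

This note documents the statistical procedures implemented in `darscan`,
the defaults they run with, and the modeling choices made where the
procedure left room for interpretation.

## Coordinates and interval conventions

All coordinates are 0-based, half-open (UCSC table convention). Overlap
means ≥ 1 shared base. Peak resizing uses the floor midpoint
`(start + end) // 2` and windows are shifted — not truncated — to stay
inside `[0, chrom_length)`, so every resized region keeps its full width.
Peak clustering merges intervals whose gap is *strictly* less than the
threshold (default 100 bp; overlap counts as gap 0), which makes
clustering idempotent and the cluster count monotone in the threshold.
DHS and ChIP peaks are unstranded; strand is consumed only by aggregate
tag profiles (minus-strand instances are coordinate-reversed) and by TSS
computation.

## Gene-proximity annotation and matched backgrounds

Regions are annotated by their midpoint's relation to the gene models,
with precedence TSS (±1 kb of a TSS) > promoter (≤ 5 kb upstream,
strand-aware) > intragenic > proximal (≤ 10 kb from a gene boundary) >
distal (≤ 100 kb) > desert. Midpoint distance and the precedence order
are implementation choices — the procedure being reproduced states the
six categories but neither the tie-break nor the anchor point; midpoints
make annotation deterministic and independent of region width.

The background sampler tiles each chromosome at `region_width / 4` steps,
annotates tile centers once, and then rejection-samples positions within
eligible tiles until each category's quota — largest-remainder rounding
of `n × target fraction` — is filled. Every sampled region re-annotates
as its assigned category by construction. Draws are fully determined by a
64-bit seed; the per-dataset seed is `run_seed XOR crc32(dataset_id)`
(a stable hash, unlike Python's builtin).

## The DAR test

Trials are the subfamily's instance count and the success probability is
the expected *fraction* of instances hit, `expected / n`. The expected
count is the background's **overlap-pair count** with the subfamily
(the intersect count), scaled by `n_peaks / n_random`. Pair counts rather
than distinct-instance counts matter at desk scale: on a 10-Mb synthetic
genome, 200,000 random regions touch nearly every instance, so a
distinct-instance count saturates and under-estimates the expectation by
almost an order of magnitude, while pair counts scale linearly in
`n_random` at any genome size and reduce to distinct counts in the sparse
regime of a 3-Gb genome. After this choice the null calibration on a
no-signal synthetic study is `mean(observed/expected) ≈ 0.92` (the
residual 8% is the distinct-vs-pair saturation on the *observed* side,
which makes the test slightly conservative).

p-values are carried as log10 throughout, computed by `gammaln` +
`logsumexp` over the exact tail; `scipy.stats.binom.logsf` underflows to
−inf for the strongest enrichments, the own kernel does not (the flagship
example reaches log10 p ≈ −1276). Benjamini–Hochberg q-values are
reported per dataset as an extra column but never used for calls; the DAR
call is the fixed cutoff p < 1e-5. Expected counts stay real-valued; no
rounding occurs before the test. No minimum-instance floor is applied —
tiny subfamilies simply cannot reach significance.

## Repeat age and mappability

Subfamily age is Jukes–Cantor on the mean milliDiv over all instances:
`d = −(3/4) ln(1 − 4p/3)`, age = d / rate with rate 2.2e-9
substitutions/site/year (divergence accrues on one lineage relative to
the ancestral consensus; 15% divergence ↦ ≈ 76 Myr). Subfamilies younger
than 95 Myr are primate-specific. The JC correction is undefined at
p ≥ 0.75 and raises.

The mappability simulation samples reads uniformly from the genome
(defaults mirror the two sequencing designs: 20 bp / 1 mismatch and
36 bp / 2 mismatches) and asks whether each read's sequence occurs at
exactly one genomic position-and-strand within the mismatch budget;
reverse-complement matches count as mapping positions. Matching is
seeded exact k-mer anchoring over a sorted polynomial-hash index with
vectorized Hamming verification — pigeonhole over `mismatches + 1` equal
seeds guarantees completeness, and hash candidates are always verified
against the actual sequence, so 64-bit hash collisions cannot create
false matches. The pipeline default is 100,000 reads per read length,
a sample size chosen so the per-subfamily ratios carry binomial sampling
error of a few percent at desk scale; the read count, mismatch budget and
seed are recorded in the output.

## Cell-type specificity

Observed open-instance counts are normalized by the dataset's total peak
count, and folds are taken against the *median* normalized count across
datasets of the same lab group (UW and Duke medians kept separate, as a
proxy for their different read lengths and hence mappability). The focal
dataset is included in its own median — with many datasets per group
this is immaterial, and it keeps the definition symmetric. The median of
an even count is the mean of the central pair. `fold > 3` together with
the pair being a DAR marks cell-type specificity. Note the group median
is only a meaningful null when planted/true signal occupies a minority of
a group's datasets; the synthetic defaults respect this.

## TF and motif association

ChIP co-occurrence uses a hypergeometric over the subfamily's instances:
population N = instances, successes K = ChIP-bound instances, draws
n = DHS-contributing instances, observed k = both; significance at
p < 0.001. Instance flags use any-overlap with 200-bp resized peak
windows, mirroring the DAR procedure.

The PWM scanner scores log2 odds against a 0-order background (uniform
by default, configurable) on both strands; N positions contribute 0.
Exact p-values come from position-wise convolution of the per-position
score distributions discretized at 1e-3 bits, so a scan threshold can be
placed at any p (default 1e-5) without sampling; the convolution agrees
with full 4^L enumeration to within the bin width.

The five motif–subfamily features are: f1 the fraction of instances with
≥ 1 hit; f2 the fraction of the genome's hits falling inside the
subfamily; f3 the mean best-hit score ratio of ChIP-bound vs unbound
instances (absent without ChIP data); f4 a binomial enrichment of the
subfamily's hit count against the genome-wide per-position hit rate; and
f5 the observed hit count divided by its mean over dinucleotide-shuffled
copies of the instance sequences (Altschul–Erickson shuffles, scanned
instance-by-instance exactly like the observed sequences). The exact
statistical form of f4/f5 and the rank weights are not published for the
original classifier, so f4/f5 are realized as above and the weighted rank
average defaults to equal weights; ranks are normalized to [0, 1] with
ties sharing the mean rank, and the top 10% of pairs are flagged. The
original classifier's reported discrimination (AUC 0.81) is tied to its
unpublished training corpus and is not a target here.

Tissue-specific motif support retains a (DAR, motif) pair iff the motif
occurs in > 25 instances *and* in > 20% of the DHS-contributing
instances (both strict).

## Expression association

A gene is up-regulated in a cell type if its Z-score — one focal dataset
against the mean/SD (ddof = 1) of all other cell types' datasets —
exceeds 2 in at least one focal dataset; zero-spread genes are never
called. Genes are associated to a DAR when their body overlaps a 50-kb
window centered on an open instance midpoint (the window mirrors the
RNA-seq design; gene-level "proximity" was otherwise unspecified). The
permutation null redraws the same number of genes uniformly without
replacement from the array universe 10,000 times; because the count of
up-regulated genes in such a draw is exactly hypergeometric, the draws
are realized with a seeded hypergeometric sampler — distributionally
identical to drawing names and far faster; the closed-form hypergeometric
moments serve as an independent oracle in the tests. The Z denominator is
the population SD of the permutation statistic (ddof = 0; at 10,000
draws the distinction from ddof = 1 is negligible). The RNA-seq variant
applies the same logic to average tag densities in 50-kb windows, with a
genome segmented into non-overlapping 50-kb background windows.

## Auxiliary enrichments

Chromatin-state assignment requires a state to cover strictly more than
half the region (none otherwise); the 15 states are reported after
grouping into 7 combined states (promoter, enhancer, insulator,
transcribed, repressed, heterochromatin, repetitive — the enhancer
grouping is stated by the procedure, the rest is this package's
configurable default). Conservation compares the CNEE-overlap fraction
of open instances to the all-instance fraction with the shared one-sided
binomial kernel (the original test for this comparison is unnamed; a
two-proportion z would behave similarly at these counts). dsQTL
enrichment assigns each dsQTL to the cluster it overlaps most (ties
leftmost) and tests DAR-contributed clusters among dsQTL-bearing ones
with the shared hypergeometric kernel, counting *distinct* clusters so
the statistic stays inside the hypergeometric support when several
dsQTLs share a cluster.

## The synthetic study generator

The generator emulates the *structure* of a multi-cell-type DNase study,
not its sequencing physics: peaks are placed directly (no read-level
noise or peak-caller behavior), and instances are consensus copies
mutated at per-instance milliDiv rates. Defaults are the study
conditions: two 5-Mb chromosomes at 41% GC with CpG depletion (iid draw
plus vectorized CpG thinning — a first-order composition that keeps
10-Mb generation fast), 40 subfamilies × 100–500 non-overlapping
instances of 120–300 bp cycling through the LTR/ERV, DNA, LINE and SINE
classes, 300 genes, and 12 datasets spanning the 8 tissue groups and
both lab groups with 800–1,500 peaks each. Six subfamily×cell-type
enrichments are planted at folds 5–10 (planted subfamilies are forced to
≥ 200 instances so the planted regime matches the recovery criteria);
planting places one peak at each chosen instance center, with the count
calibrated as `(fold − 1)·n·q/(1 − q)` against the analytic background
hit rate `q`, while background peaks are uniform — which is what makes
the annotation-matched background an unbiased null and lets a no-signal
study calibrate to observed/expected ≈ 1. ChIP peaks bind planted-active
instances with probability 0.8 (plus uniform background peaks), motifs
are planted into 50–60% of target-subfamily instances as consensus sites
written into the genome, expression of genes within 50 kb of active
instances is shifted by 4 noise-SDs in the matching cell type's
datasets, CNEEs land on open instances at twice the base rate (5%), and
30% of dsQTLs are drawn inside DAR-contributed lymphoblastoid clusters.
A truth table records every planted effect; `truth_report` scores
recovery. Everything is reproducible byte-for-byte from `master_seed`
via spawned child generators.

What passing recovery tests shows — and does not show: they demonstrate
that the statistics recover planted signal at the stated folds and reject
calibrated nulls on data whose background is uniform by construction.
Real peak sets carry GC and mappability biases, correlated peak
placement, and annotation structure that only partially matches any
background model; those failure modes are represented only insofar as the
annotation-matched sampler is exercised, so desk-scale green tests do not
certify the method against, e.g., sequencing-bias-driven artifacts (the
GC QC stage exists precisely because such artifacts occur in real data).

## Problem sizes and numerical notes

Default analysis sizes: 200,000 background regions per dataset, 10,000
permutation draws, 100,000 simulated reads per read length, 5
dinucleotide shuffles per subfamily in the classifier stage. The full
default synthetic run (generation + all stages) completes in about a
minute on one CPU. Degenerate inputs are handled explicitly: expected = 0
yields fold sentinels (1 when observed = 0, +inf otherwise), zero
permutation SD yields ±inf Z with a warning, subfamilies with no
instances are skipped with a warning, and empty tag sets or region lists
raise. Known limitations: cross-species coordinate mapping (lineage
labels must be supplied by the caller), FastQC-style read-quality
metrics, and binary genomics formats (bigWig/bigBed) are out of scope.
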