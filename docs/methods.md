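# Methods

`scntomics` implements the computational core of an allele-specific
DNA-methylation and expression comparison between cloned (SCNT) and
fertilized (ICSI) primate embryos produced from a hybrid cross, together
with the placenta-phenotype quantifications that accompany such a study.
Because the real datasets are sequencing-scale, every stage is driven by a
synthetic-data generator with exact ground truth; this note records the
models, the parameters that matter, and the numerical choices, and states
what the synthetic results do and do not establish about real data.

## The hybrid-cross design

Two parental genomes that are homozygous for different alleles at many
sites make every offspring read covering such an *informative SNP*
attributable to one parent. The pipeline therefore:

1. hard-filters parental variant calls with the standard inequality set
   (QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0, MQRankSum < −12.5,
   ReadPosRankSum < −8.0; a record fails if any holds, and every inequality
   is strict so boundary values pass);
2. keeps exactly the homozygous-divergent sites and N-masks the reference
   there, removing reference bias from allele assignment;
3. assigns each aligned read to the maternal or paternal allele by majority
   of usable SNP observations. Missing quality annotations do not fail a
   record (they are flagged); multi-allelic sites are excluded.

**Bisulfite-aware SNP exclusion.** On the original-top strand an
unmethylated C reads as T, so C/T SNPs are uninformative there; on the
original-bottom strand (reference frame) G reads as A, so G/A SNPs are
uninformative. On usable SNPs the converted base remains diagnostic: a top
strand read T still matches a C allele when the other allele cannot produce
T. Reads with support for both parents are `conflicting`; a read base
matching neither allele is counted as a mismatched-base event and votes for
no one. These rules are verified in the tests by exhaustive enumeration
over all allele pairs × strands × read bases.

## Methylation model

A CpG site is the C of a reference-top-strand C-G dinucleotide. Methylation
is symmetric: the bottom-strand G carries the state of its partner C, and
bottom-strand evidence is merged onto the C coordinate by default (a flag
preserves strand-resolved counts; merging never changes total call counts).
Non-CpG cytosines are always unmethylated in the simulation and ignored in
CpG summaries — except on the unmethylated lambda spike-in, where *all*
cytosine contexts are pooled to estimate bisulfite conversion efficiency as
converted/(converted + unconverted).

Window summaries use the unweighted mean of per-CpG levels (coverage floor
1 read, 10-kb windows by default); genome-wide levels are reported both
coverage-weighted (Σmeth/Σcalls) and as the mean of per-CpG levels. Group
comparisons of window sets use the two-sided Wilcoxon rank-sum test — exact
for small tie-free samples, tie-corrected normal otherwise. Region
metaprofiles rescale each region body to a fixed bin count with fixed-width
flanks in bp and pool per-CpG levels per bin.

## DMR calling

Per-CpG differences are tested with Fisher's exact test on the 2×2
methylated/unmethylated table (two-sided: the sum of hypergeometric point
probabilities not exceeding the observed one, with a 1e-7 relative epsilon
absorbing floating-point ties; vectorized over the genome via broadcast
log-pmf). A CpG *qualifies* at unadjusted p < 0.05 with a sign-consistent
level difference.

Qualifying CpGs chain into runs under three constraints:

* genomic gap between consecutive qualifying CpGs ≤ 1000 bp;
* at most 2 covered-but-non-qualifying CpGs intervene (interior
  tolerance for occasional per-CpG power losses);
* run *ends* are stricter: a terminal qualifying CpG separated from its
  inner neighbour by ≥ 2 non-qualifying CpGs is trimmed. At 30× coverage an
  isolated background CpG reaches p < 0.05 with a consistent sign a couple
  of percent of the time; without end-trimming such a CpG within 1 kb of a
  genuine region attaches to it and drags the boundary outward. The
  two-level rule keeps interiors robust and boundaries tight (within ±2
  covered CpGs of planted edges in the recovery tests).

A run is emitted as a DMR when it spans ≥ 25 covered CpGs, contains ≥ 25
qualifying CpGs, and its mean level difference over all covered CpGs in the
span is ≥ 25% in absolute value; all three thresholds are independently
configurable. Direction is test − control: `hypo` = lower methylation in
the cloned condition. Annotation is by DMR midpoint with priority
promoter > exon > intron > TTS > intergenic, the promoter being
[−1000, +100] bp of the strand-aware gene start and the TTS window its
mirror image.

## Expression and imprinting

FPKM = count / (exonic kb × mapped millions). The differential-expression
engine is a self-contained negative-binomial Wald test: median-of-ratios
size factors; per-gene method-of-moments dispersion pooled within groups,
floored at 0.01 and raised to at least the across-gene median of expressed
genes (an empirical-Bayes-style moderation — the per-gene estimate at 2–3
replicates is far too noisy to referee a normal Wald statistic on its own,
and moderation keeps the false-positive rate near nominal while preserving
power); a delta-method standard error on the log2 ratio of normalized group
means. The log2 fold change is the exact ratio of normalized group means,
with a 0.5 pseudocount only where a group mean vanishes, so doubling one
sample's depth leaves every fold change exactly unchanged. Threshold
semantics follow the study's cutoffs: p < 0.01, fold change > 2,
baseMean > 10. Measured operating characteristics at the design conditions
(4-fold change, n = 3/group, dispersion 0.1): ≈96% sensitivity, ≈1% null
pass rate.

The imprinted-gene cascade: (1) candidate imprinted genes with FPKM > 1 in
both groups; (2) of those, genes whose body ±10 kb overlaps a DMR; (3) of
those, genes with FPKM ratio > 2 or < 0.5 (control set to 1). A parallel
route intersects the DEG set with the candidate list and applies the DMR
filter. Allelic expression status uses maternal-fraction bands — ≤ 0.15
paternal, ≥ 0.85 maternal, 0.30–0.70 biallelic, otherwise (or under 10
informative reads) not evaluable. Loss of imprinting is called when a
control-monoallelic gene becomes biallelic in the test group, or when a
maternal-vs-paternal DMR methylation bias ≥ 0.3 in the control collapses
below 0.15 in the test. The packaged candidate list is a synthetic
stand-in that mimics public imprinted-gene catalogue structure; any TSV
with the same columns substitutes.

## Placenta morphometry

Slides are 8-bit grayscale (plain luminance for color input). The tissue
mask is Huang's fuzzy-entropy auto-threshold on the full histogram (holes
filled); the calcified mask is Yen's maximum-correlation auto-threshold on
the tissue-pixel histogram. Both criteria are implemented from their
original definitions, break ties to the lowest level, return a sentinel on
single-level histograms, and are verified against exhaustive 256-level
search (Yen also against scikit-image). Because an auto-threshold always
returns *some* split, a bimodality guard rejects the calcified class when
its mean is within 4 tissue-noise standard deviations of the tissue mean or
when it would swallow more than a quarter of the tissue — otherwise an
uncalcified slide would report half its noise as calcification.

Particles are 8-connected components; those strictly smaller than
0.0003 mm² are removed (a particle of exactly the minimum survives). Areas
pool across the slides of one placenta before division. CCI = 100 ×
calcified/total area (percent); CCN follows the printed convention
(dots/area × 100) with dots-per-mm² also reported. Thickness is the tissue
mask's minor bounding-box extent per slide, averaged over slides — adequate
for the synthetic ellipse sections, ambiguous on convoluted real sections
(flagged limitation).

## Outcome statistics

Outcome percentages are k/n × 100 rounded half-up to one decimal (the
convention that reproduces printed outcome tables exactly). Survival uses
the Kaplan–Meier product-limit estimator and the standard unweighted
log-rank test via lifelines, with the median defined as the earliest time
with S(t) ≤ 0.5 and reported as undefined when never reached. Curves over
abortion events treat each aborted fetus as one unit and can be restricted
to event-only records; fetuses alive at term are censored at delivery.
Abortion timing is summarized by a Gaussian KDE (Silverman bandwidth).

## The synthetic-data generator

The generator emulates: two haplotypes differing only at planted
homozygous-divergent SNPs (never inside a CpG unless explicitly allowed, so
conversion chemistry and variation cannot be accidentally confounded);
CpG-depleted sequence (each raw CpG of the i.i.d. draw survives with
probability 0.2, giving ≈1 CpG per 80 bp — vertebrate-like; an i.i.d.
sequence's 1-per-16-bp density would make any gap-limited segmentation
chain background noise across the genome); per-allele, per-condition CpG
methylation with three region kinds (maternal imprint — optionally lost in
the cloned condition; somatic hypo/hyper memory); directional bisulfite
reads at configured depth, read length and conversion efficiency with a
fully unmethylated lambda spike-in fraction; negative-binomial RNA counts
(gamma–Poisson; Poisson at zero dispersion) with allelic reads placed over
informative SNPs inside genes; slide images as a bright tissue ellipse with
brighter calcified disks, Gaussian noise, and rasterized-truth areas; and
two-group gestation tables from point/exponential/Weibull event-day
distributions with optional censoring at term.

All randomness derives from one integer seed through fixed per-stage
substreams (`SeedSequence(seed, spawn_key=(stage, substream))`), so adding
or re-running one stage never perturbs another and identical configurations
are byte-reproducible. Read count equals depth × genome / read length
(rounded). The conversion/methylation draw is collapsed to a single uniform
per base against ce × (1 − p_meth), which is distributionally identical to
drawing methylation and conversion separately.

What the generator does **not** emulate: sequencing errors and quality
scores, PCR duplicates, mapping ambiguity (reads carry their true
coordinates), indels and structural variation, paired-end geometry, CpG
islands or other sequence-composition structure beyond uniform depletion,
non-CpG methylation, cell-type mixtures, and stain-specific color. Passing
the recovery tests therefore establishes correctness of the *analysis
logic* under clean alignments, not robustness to alignment or chemistry
artifacts in real libraries.

## Problem sizes and numerical choices

* DMR recovery runs on 2-Mb genomes at 30× with five planted 40-CpG
  regions (|Δ| = 0.5) over ten seeds in the test suite and three seeds in
  the acceptance script; planted blocks avoid internal CpG gaps > 500 bp,
  since the 1-kb chaining rule treats a kb-scale CpG desert as a region
  boundary by design.
* Allelic recovery uses 150-kb genomes at SNP density 8 × 10⁻³ (dense,
  as a hybrid cross provides), 30×, ten seeds.
* DE characteristics: 50 four-fold + 450 null genes, n = 3/group,
  dispersion 0.1, twenty seeds.
* Fisher p-values match exact-rational enumeration to 1e-12; threshold
  criteria match exhaustive search to 1e-12; ties break to the lowest
  level everywhere.
* Degenerate inputs: empty histograms, all-censored survival, zero
  spike-in coverage, all-zero genes and empty SNP lists all return explicit
  sentinels or flags rather than numbers.
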