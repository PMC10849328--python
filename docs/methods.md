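# Methods

## The analysis and its assumptions

The package asks one question of a diploid biallelic cohort: which locus
most distinguishes gamecocks from nongame chickens, and does it look
selected? It answers with four semi-independent lines of evidence computed
from the same filtered genotype matrix: allele-frequency differentiation
(Hudson F<sub>ST</sub>, population branch statistic), within-cohort
diversity (observed heterozygosity, nucleotide diversity), and a
stratified case/control association test. All statistics are
missingness-aware: a masked genotype simply contributes no alleles.

The association model is deliberately simple — a Cochran–Mantel–Haenszel
χ² on per-stratum allele-count tables — and relies on three assumptions:
alleles within a genotype are exchangeable (HWE within strata), population
structure is adequately captured by a discrete partition of samples, and
residual inflation is well described by a single multiplicative factor on
the χ² statistic (genomic control). The stratification is learned from the
data: complete-linkage clustering of pairwise identity-by-state distances,
with K chosen to minimise the inflation factor λ. Only strata containing
both phenotypes contribute to the statistic, so ties in λ are broken
toward the K that keeps more samples in such strata, then toward smaller
K. λ values are compared after rounding to two decimals, the precision at
which inflation factors are conventionally reported; differences below
that are estimator noise at these variant counts.

## Filters

All exclusion thresholds are strict inequalities; a call or site exactly
at a threshold is kept. Per-genotype: DP < 4 **or** GQ < 30 (the
conservative reading of a joint low-quality rule, switchable to AND),
DP ≥ 1.65 × the sample's mean autosomal depth (computed on pre-filter
calls, since per-sample depth is a property of sequencing, not of site
QC), heterozygous with min(AD) < 2, heterozygous with ref-read fraction
outside [0.25, 0.75] (the band is symmetric, so which allele is in the
numerator is inconsequential). Per-site: indels, multiallelics, MQ < 50,
MQ0F > 0.1, distance ≤ 3 bp to the nearest base of an indel span (the
distance convention is ambiguous in common usage; nearest-base is the
conservative choice), outside the mapability mask (BED, 0-based half-open;
the single conversion to 1-based VCF coordinates lives in one function),
post-filter missingness > 20% of samples. Per-sample: > 30% missing
genotypes; the mitochondrial contamination flag (fraction of mito sites
with minor-read fraction > 0.20 exceeding 5% of informative sites) is
advisory and never auto-drops a sample — the aggregation fraction is this
package's choice, as the rule is usually applied with judgment. Frequency
filters are inclusive: MAF ≥ 5% for association, minor allele count ≥ 1
for the selection scans.

## Windowed statistics

Windows are counted in variants (size, step), with one trailing short
window emitted and flagged `partial`; coordinates are reported both as
0-based variant indices and 1-based bp of the first/last variant. Hudson's
F<sub>ST</sub> uses the unbiased per-site numerator/denominator and
combines them as a ratio of averages within windows; a site contributes
only when both populations have ≥ 2 called alleles, and a window whose
summed denominator is zero is NaN, never 0. Negative window values are
reported as-is (small-sample behaviour of an unbiased estimator); only the
branch-length transform T = −ln(1−F<sub>ST</sub>) clips its argument below
1−10⁻⁶. Heterozygosity is *observed* heterozygosity (fraction of called
genotypes that are heterozygous); expected heterozygosity is available as
a separate function for comparison. Nucleotide diversity is the ratio of
summed pairwise differences a(n−a) to summed pairwise comparisons
n(n−1)/2 over all sites in a region *including invariant sites*, which is
what makes it a per-site rate under missing data.

## Permutations

Significance of the CMH scan comes from shuffling phenotype labels
independently within each cluster (preserving per-cluster case counts), so
the permutation null respects the stratification. The add-one estimator
p = (1+R)/(1+N) is reported in two forms. The pointwise form compares each
variant with its own permutation distribution; it is exact per variant but
necessarily flags ~V/(N+1) null variants per scan when thresholded at
1/(N+1)-resolution across V variants — a whole-genome "nothing anywhere
else" readout cannot come from it. The family-wise (max-T) form compares
each variant with the genome-wide maximum statistic of every permutation;
the pipeline's `significant` flag uses it with the conventional p < 10⁻⁴
threshold at 10,000 permutations. Ties between permuted and observed
statistics are counted as exceedances by default, which is valid but
conservative on discrete allele-count data (the null mean of p is ~0.52
at these sample sizes); a mid-p option (ties at half weight) restores
uniformity and is what the calibration diagnostics use.

## The simulator

The generator emulates the statistical structure the analyses assume, not
the biology that produced it. Demes drift from a common ancestor under the
Balding–Nichols model: ancestral frequency ~ Beta(0.8, 0.8), deme
frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with mean p and variance
F·p(1−p), one F per deme (F = 0 copies exactly). Rows of the population
list that share a deme label share a frequency draw, so a deme can contain
both phenotype groups — this is what makes phenotype *confounded with*
rather than *identical to* structure, as in real cohorts, and is required
for any stratified test to have informative strata. The default cohort
mirrors the study shape: japan (14 gamecocks + 19 nongame, F = 0.08),
world (34 + 9, F = 0.10), ethiopia (34 nongame, F = 0.12) — 48 cases vs
62 controls; 2,000 variants on a 2 Mb chromosome (≈ the study's ~1
variant/kb density at desk scale).

The selected locus overrides the deme frequency by phenotype group
(0.895 in gamecocks, 0.037 in nongame and outgroup birds). Linkage is a
soft sweep on one ancestral "game" haplotype h\*: every haplotype carrying
the game allele copies h\* at a linked variant with probability equal to a
weight that decays linearly from 1 at the locus to 0 at the block edge
(±50 kb by default). This produces the three signatures the scans look
for — allele-frequency differentiation, reduced gamecock diversity
concentrated near the locus, and LD between the locus and its block —
while leaving nongame birds on background haplotypes. Read evidence:
DP ~ Poisson(12) (the study's median depth), het AD ~ Binomial(DP, ½),
homozygote error reads ~ Binomial(DP, 0.005) on the other allele (so the
allele-balance filter has realistic near-misses), GQ = min(99, 6·DP) — a
crude monotone depth→confidence map whose slope is set so that at 12×
depth only genuinely low-depth calls (DP ≤ 4) fall under the GQ < 30
filter; a steeper penalty (e.g. 3·DP) masks ~a quarter of all calls at
this depth and the 20% site-missingness rule then removes nearly every
site. Missingness is 2% per call, independent.

What the simulator does **not** reproduce: recombination maps and distance-
dependent background LD, linked selection outside the one block, allele-
frequency spectra shaped by demographic history, sequencing-error genotype
calls, batch effects between cohorts, relatedness within demes, sex
chromosomes, multiple chromosomes. Passing tests therefore demonstrate
that the statistics and their calibration behave correctly under the
stated model, not that the pipeline is robust to every pathology of real
resequencing data.

## Numerical choices and degenerate inputs

Undefined values are NaN, never silently 0: windows with empty
denominators, FST with both populations fixed, variants where every
stratum is degenerate (T ≤ 1 or a zero margin), r² of a monomorphic
variant. Genomic control floors λ at 1 (never inflates significance);
λ = median χ²/0.4549364231. CMH uses the hypergeometric variance
(T−1 denominator), so at K = 1 it equals ((T−1)/T)× the Pearson χ²
exactly — an identity the tests assert. LD pruning sweeps every pair
closer than the window span in position order and drops the lower-MAF
member (tie: later position), so the advertised postcondition — no
surviving pair within a window above the r² threshold — holds by
construction and is audited exhaustively in tests. PCA imputes missing
dosages to the variant mean, standardises by 2p̂ and √(2p̂(1−p̂)), drops
monomorphic variants, eigendecomposes the sample covariance, and fixes
signs so each axis's largest-magnitude coordinate is positive. The exact
Mann–Whitney path computes the full permutation distribution of the rank
sum by dynamic programming over doubled midranks (valid under ties) when
n_A·n_B ≤ 400; otherwise the tie-corrected normal approximation without
continuity correction.

## Problem sizes

Desk-scale defaults keep every experiment re-runnable in minutes: null
calibration uses 4,000-variant cohorts for λ (the median-based estimator
has SE ≈ 0.03 there) and 200 × 500-variant cohorts for pooled type-I
error; the uniformity diagnostic uses ~2,000 post-filter variants, where
the 0.05 KS bound is far above uniform sampling noise; locus recovery runs
100 independent 2,000-variant cohorts with 10,000 permutations each,
vectorised across variants and chunked across permutations. Window sizes
(50 variants, step 10) are chosen so a window is about half the linked
block's variant count, the same ratio the study-scale windows bear to its
selected region.

## Known limitations

The IBS/complete-linkage stratification is a hard partition; admixed
samples sit in exactly one stratum. Genomic control corrects only
uniform inflation, not locus-specific confounding. The contamination flag
needs AD at mitochondrial sites and says nothing without them. The
simulator's single swept haplotype makes in-block variants either swept or
background; real sweeps leave recombination mosaics. Ancestry proportions
are consumed, not fitted: model-based admixture decomposition is outside
this package's scope, and the ancestry contrast operates on an externally
produced (or synthetic) Q table.
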