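# Methods

This note documents the models, rules, and numerical choices behind each
holosym module, what the synthetic generators do and do not emulate, and
the known limitations.

## Holobiont partitioning

A holobiont RNA-seq assembly mixes host and symbiont contigs. Assignment
uses tabular alignment hits (12-column outfmt-6) of the contigs against
four databases: a cnidarian *holobiont* database, cultured *ex-hospite*
symbiont sequences, *in-hospite* symbiont sequences, and *aposymbiotic*
cnidarian sequences. A hit counts only if its alignment length is ≥ 100
(column value taken at face value, whether residues or bases) and its
percent identity ≥ 80 — both boundaries inclusive, and a contig "maps to"
a database when at least one hit survives. Then:

* coral = holobiont \ ex-hospite, symbiont = in-hospite \ aposymbiotic;
* contigs in both fractions are ambiguous and removed from both, making
  the final fractions disjoint by construction.

The fixed pipeline order is: length filter (≥ 500 bp retained) → hit
parsing → fraction assignment → SILVA rRNA removal per fraction → isoform
collapsing → annotation cleanup. rRNA removal precedes collapsing because
the fraction bookkeeping is defined on pre-collapse contigs. The SILVA
screen accepts its own thresholds in `RunConfig`
(`silva_min_aln_len`/`silva_min_pident`, defaulting to the main parse
thresholds) since rRNA screens sometimes use different alignment settings.

Isoform collapsing keeps the longest contig per cluster, with length ties
broken toward the lexicographically smallest contig ID so reruns are
identical. Annotation cleanup removes algal carryover from the coral
fraction by description keywords ("chloroplastic" — also matched in the
transposed spelling "chroloplastic" seen in annotation sources — and
"chlorophyll", case-insensitive substrings) and cnidarian carryover from
the symbiont fraction by source taxon (*Acropora millepora*,
*Nematostella vectensis*).

Percentages in the ledger round half-up (58.5% → 59%). N50 is the length
L such that contigs of length ≥ L, taken longest-first, cover at least
half the assembled bases; L50 is the size of that cover; GC excludes
ambiguity codes from numerator and denominator.

## Clone detection

Variant filters (all boundaries inclusive): every sample covered at depth
≥ 10 with a called genotype, site QUAL ≥ 30, exactly one alternate allele,
ref and alt single bases. Because the depth rule requires all samples
covered, no missing genotypes survive, and the pairwise distance — the
count of loci at which two samples' unordered diploid genotypes differ —
is always defined. Distances are clustered by complete linkage
(deterministic: ties in the merge order break toward the smallest cluster
labels) and rendered as Newick.

Clone calling needs a reproducible rule rather than visual inspection of a
dendrogram: a pair is clonal when its distance is ≤ τ × median of all
pairwise distances, τ = 0.25 by default. The rule is scale-invariant
(proportion vs count distances give identical calls) and requires ≥ 3
samples so a background median exists; if *every* pair falls below the
threshold there is no background and the call errors out rather than
guessing. Clone groups are connected components of flagged pairs; one
member per group is retained, chosen uniformly at random under the given
seed. With 5,000 loci, moderate allele frequencies, and ≤ 1% genotyping
error, a clone pair sits two orders of magnitude below the background
median, so detection is essentially deterministic (the acceptance suite
measures ≥ 99% sensitivity with zero false pairs over 200 simulations).

## Differential expression

Counts are modelled per gene as NB(mean μ_ij = s_j q_ij, variance
μ + α μ²) with log2 q = Xβ, where X encodes an intercept, genet (colony)
block dummies, and the symbiotic-state indicator. Size factors s_j are
median-of-ratios over genes expressed in every sample, rescaled to
geometric mean 1. Genes with fewer than 10 total counts are dropped first
(inclusive boundary). The state coefficient β_state is the log2 fold
change, positive = higher in symbiotic branches.

Fitting is IRLS on the log link, run vectorized across genes, with step
halving so the NB log-likelihood never decreases; non-converged genes get
missing p-values and are excluded from the multiple-testing adjustment.

Dispersion estimation, the small-sample crux:

1. a preliminary Poisson fit gives covariate-conditional means, so genet
   block variance is not absorbed into the dispersion;
2. the raw per-gene α solves the Pearson moment equation
   Σ_j (K−μ)²/(μ+αμ²) = n − p (floored at 1e-8, capped at 100);
3. raw dispersions are shrunk on the log scale toward a lowess trend of
   log α against log mean expression. The shrinkage weight is not fixed:
   the spread of log raw dispersions around the trend is decomposed into
   sampling noise — trigamma((n−p)/2), the log-scale variance of a
   chi-square-type estimator with n−p df — plus genuine gene-to-gene
   variation (the "prior variance"), and the blend weights the raw value
   by (n−p)/(n−p+d₀) with prior df d₀ = 2·trigamma⁻¹(prior variance).
   This is the moderated-variance construction familiar from
   empirical-Bayes expression analysis.

The Wald statistic is referred to a t distribution with n − p + d₀ df
(normal when the dispersion is fixed or the prior df is infinite). The
point of the scheme is self-calibration: when dispersions are effectively
shared across genes, d₀ → ∞, shrinkage is strong and the reference is
normal; when they are heterogeneous, d₀ is small, per-gene estimates
dominate and the heavier-tailed reference absorbs their noise. Under the
simulated study conditions (10 samples, 6 parameters) this yields a raw-p
type-I error within 0.05 ± 0.015 while a fixed 50/50 blend with a normal
reference was anticonservative (~0.09) and with a t(n−p) reference
overconservative (~0.03). BH adjustment and the FDR < 0.1 call follow.

The regularized log transform used for ordination is the shifted log
T = log2(K/s + 1) — deliberately not a re-derivation of the full
shrinkage-based transform, since only the sample geometry feeds PCA and
PERMANOVA and the shifted log stabilizes variance outside the low-count
regime. PCA follows the `prcomp` convention (genes centered, not scaled;
scores are projections onto right singular vectors). PERMANOVA partitions
the Gower-centered squared Euclidean distance matrix sequentially (genet,
then state), with pseudo-F per term and p = (1 + #{F_perm ≥ F_obs})/(1 +
n_perm) under free row permutation (default n_perm 9999; the calibration
suites use 199 to stay fast). All filtered genes enter the ordination. The
paired mapping-fraction comparison is a one-tailed paired t-test on
per-colony differences.

## Rank-based enrichment

Gene scores are −log(p)·sign(log2FC), p floored at 1e-300; only ranks
matter downstream, so the log base is irrelevant and any strictly
monotone rescaling of scores leaves results unchanged. Per class, a
two-sided Mann-Whitney U compares member vs non-member scores:

* exact enumeration of all C(n, k) member assignments when both groups
  have ≤ 8 genes, computing the two-sided tail of the member midrank sum
  (valid under ties), p = 2·min(P(S ≤ s), P(S ≥ s)) capped at 1;
* otherwise the normal approximation with tie correction and continuity
  correction.

The effect summary is the delta rank (mean member rank − mean non-member
rank, ascending average ranks); by rank-sum conservation the member and
complement deviations from the grand mean cancel exactly. Classes are
testable with ≥ 5 scored members covering ≤ 10% of scored genes (both
configurable; conventional bounds for this family of rank tests — very
small classes are underpowered, very large ones are uninformative).
Unannotated genes stay in the complement: they inform the background
ranking. GO divisions (BP/MF/CC) are tested and BH-adjusted separately;
KOG classes (one per gene) form a single family. GO-graph ancestor
propagation is out of scope — annotations are tested as given. An
optional pre-test merge unions classes whose member sets have Jaccard
similarity ≥ 0.75, with single-linkage (transitive) closure; off by
default.

Cross-taxon comparison inner-joins enrichment tables on class ID, flags
classes with p < 0.05 in every dataset, and reports both Pearson and
Spearman correlations of delta ranks over shared classes (the Pearson
value is sensitive to a few strongly enriched classes; Spearman is the
robust summary).

## Synthetic data

Generators are pure functions of (parameters, seed), each on its own RNG
stream, and every generator returns a truth record sufficient to score
recovery. Defaults encode the study conditions: six colonies (five genets
after clone removal), one symbiotic and one aposymbiotic sample per genet,
NB dispersion 0.1, genet effect SD 0.3 on the log2 scale (genet as the
dominant variance component), planted log2 fold change 2, clone genotyping
error 0.5%, 5,000 SNP loci. Hit-table generation builds membership sets
with *exact* requested overlap counts (plus sub-threshold distractor
hits), so the partition bookkeeping can be checked against the published
set sizes identically rather than approximately.

What the generators do **not** emulate: read-level sequencing (no FASTQ,
mapping ambiguity, or positional bias), correlated gene-gene expression,
GC- or length-dependent coverage bias, linkage between SNP loci, and GO
hierarchy structure (class memberships are independent draws). Passing
tests therefore demonstrate correctness of the statistical machinery and
the bookkeeping under the assumed models, not robustness to artifacts of
real libraries; headline biological results that depend on the original
raw sequencing data (e.g. exact DEG counts or SNP totals) are outside
what synthetic inputs can reproduce.

## Numerical choices and degenerate inputs

* Inclusive thresholds everywhere a rule is worded as "at least"/"minimum".
* Half-up rounding for reported percentages.
* IRLS: ridge 1e-10 on the normal equations, linear predictor clipped to
  ±30, convergence at max |Δβ| < 1e-9 within 60 iterations.
* Deterministic tie-breaks: isoform representatives by smallest ID,
  cluster merges by smallest labels, clone-group traversal in sorted
  order.
* Errors rather than guesses on: empty contig sets, GC without sequences,
  all-genes-filtered, no gene expressed in all samples, a confounded
  PERMANOVA term, fewer than 3 samples for clone calling, a degenerate
  all-clonal background, zero-variance paired differences, p-values
  outside (0, 1].

## Problem sizes in the test and acceptance suites

Simulation-based checks use 2,000 genes × 10 samples for DE calibration,
500 null datasets × 199 permutations for PERMANOVA, 200 seeded replicates
of 6 samples × 5,000 loci for clone recovery, and ≥ 500 random instances
for the exact-MWU oracle — sizes at which Monte-Carlo error is well below
the tested tolerances while the whole suite runs in a few minutes on one
CPU. The exact partition arithmetic runs at the full published set sizes
(~1.3M contigs, ~160k hits) since it is set logic, not simulation.

## Known limitations

* The NB test is a Wald test; genes with extreme count outliers are not
  down-weighted (no outlier replacement or independent filtering).
* The exact MWU path enumerates only up to 8v8; mid-size classes rely on
  the (tie-corrected) normal approximation.
* Clone calling assumes clones are *rare*: if most samples were mutually
  clonal the background median itself would be contaminated.
* The cluster map for isoform collapsing must come from an upstream tool
  (or assembler isoform IDs); no sequence clustering is performed here.
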