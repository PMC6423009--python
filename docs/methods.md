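# Methods

This note documents the statistical models implemented in `clonarch`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about behaviour on real data.

## CCF model and clonality rule

A somatic SNV carried by a fraction `c` of tumor cells (the cancer cell
fraction, CCF) at mutant multiplicity `m`, in a genomic region of tumor
total copy number `q_t`, in a specimen of purity `p`, has expected variant
allele fraction

    v(c) = c · p · m / (p · q_t + 2 (1 − p)).

The posterior over `c` uses a binomial likelihood `Binom(alt; depth, v(c))`
with a uniform prior, evaluated on a 0.01-spaced grid.  The grid extends to
`c_max = 1 / v(1)`, the largest CCF compatible with VAF ≤ 1: sampling
fluctuations push the raw estimate of a truly clonal mutation above 1 about
half the time, and truncating the prior at 1 would systematically shave
that mass off.  The reported posterior lives on [0.01, 1]: mass above 1 is
folded into the top grid point, the point estimate is the posterior mean
clamped to ≤ 1, and `P(CCF ≥ 0.95)` integrates everything from 0.95
upward.  An event is **clonal** iff `P(CCF ≥ 0.95) > 0.5` (strict), applied
identically to SNVs and copy-number events.

Multiplicity is a rounded point estimate `m = clamp(round(v̂ · (p·q_t +
2(1−p)) / p), 1, q_t)` rather than a quantity integrated over; this is a
simplification relative to full allele-specific inference and is the main
source of CCF bias at high multiplicity.  SNVs in homozygous-deleted
regions (`q_t = 0`) are skipped with a warning.

**Operating characteristics.**  The clonal/subclonal decision boundary
sits where the posterior median reaches 0.95, i.e. within roughly half a
binomial standard deviation of the expected alt count.  At depth ~100 the
CCF posterior of a clonal mutation has a standard deviation of 0.10–0.24
(depending on purity), so ~30–35% of truly clonal mutations fall below the
boundary and are labelled subclonal; subclonal mutations with CCF ≤ 0.4
are essentially never mislabelled.  This asymmetry is intrinsic to the
`P(CCF ≥ 0.95) > 0.5` definition at exome-scale depth — it is why observed
cohort-level clonal fractions (here ~57% with 75% planted clonal; ~68% in
published exome cohorts) undershoot the true clonal fraction — and no
unbiased posterior can remove it without a clonality-weighted prior, which
the cited literature does not use.  The acceptance suite therefore reports
clonal recall as a measured quantity; the subclonal recall ≥95% property is
asserted.

## Read filters and event definitions

SNVs are kept when tumor and germline depth are ≥10×, the germline has ≤2
variant reads, tumor VAF ≥ 10% and germline VAF ≤ 2%.  Samples with purity
below 20% are excluded (0.20 itself is kept).  If a gene carries ≥2
non-silent SNVs in one patient, all of that gene's SNVs in that patient are
removed from gene-level clonality analysis (silent SNVs do not trigger the
rule).  Genes must be non-silently mutated in ≥3% of samples and arm
events altered in ≥10% to enter cohort-level analyses.

Segments are amp/del relative to the rounded sample ploidy.  Segment
clonality applies the 0.95 threshold directly to the annotated per-segment
CCF (a point value stands in for a posterior when only an annotation is
available).  An arm is clonal (subclonal) when clonal (subclonal) altered
length exceeds 50% of the arm — strictly — and the arm CCF is the median
of the contributing segments (midpoint convention for even counts).  When
both arms of a chromosome carry a same-direction event the pair is
reported as one whole-chromosome event with length-weighted fractions; amp
and del candidates on the same arm are resolved toward the larger altered
fraction.

## Mutational signatures

Substitutions are folded to the pyrimidine strand and binned into the
standard 96 trinucleotide channels.  Extraction is NMF under the Frobenius
objective by exact block-coordinate alternating nonnegative least squares
(HALS-style column/row updates).  Each block update is an exact constrained
minimizer, so the objective is non-increasing by construction — a property
the test suite asserts per iteration; naive projected ALS (solve, then clip
negatives) does not have it.  Defaults: 50 random restarts, tolerance 1e-8
on the relative objective decrease, 2,000 max iterations; signature columns
normalized to sum 1 with exposures rescaled compensatorily.

The number of processes is chosen by bootstrap stability: each sample's
catalog is resampled (multinomial), factorized, and the pooled bootstrap
signatures are clustered by k-means on cosine distance into k groups.
`stability(k)` is the **minimum per-cluster mean silhouette** (the weakest
cluster governs, since a spurious extra component shows up as one unstable
cluster among stable ones); for k=1 it is the mean pairwise cosine of the
bootstrap signatures.  The chosen k* is the largest k with stability ≥ 0.85 (the
threshold was calibrated on planted one-, two- and three-process cohorts),
subject to the mean reconstruction error not increasing.  The
threshold and resample count (default 100) are exposed parameters.

Reference matching reports the argmax-cosine reference column with both
cosine and Pearson values and flags cosine < 0.80 as unmatched; no
assignment is forced.  Clonal-vs-subclonal enrichment refits exposures on
the pooled clonal and subclonal catalogs by NNLS (rescaled so attributed
counts sum to the stratum totals) and tests each signature's 2×2 table
(this signature vs others × clonal vs subclonal) with a two-sided Fisher
exact test, BH-FDR across signatures.  Stratum-level refit was preferred
over per-mutation maximum-posterior assignment because the tested quantity
is the relative contribution of each process per stratum.

## Permutation enrichment test

For an event with `n = n_clonal + n_subclonal` mutations, each permutation
draws `n` labels without replacement from the cohort pool and compares the
drawn clonal count with the observed one — at fixed `n` this ordering is
identical to comparing clonal/subclonal ratios and avoids zero
denominators.  The default p-value is `(b + 1)/(B + 1)` with the ≥ tail
(valid, slightly conservative); `tie_break="ge"` gives the raw unbiased
Monte-Carlo tail frequency, `"gt"` the strict-inequality convention, and
`"randomized"` the randomized tie-break that is *exactly* uniform under
the null.  The last exists because permutation p-values of a discrete
statistic are stair-step conservative — the CDF deficit equals the largest
hypergeometric atom (~0.1 at event size 50) — so distribution-level
uniformity checks must randomize ties; the package's significance
decisions use the conservative default.

## Temporal ordering

Each patient with `c` clonal and `s` subclonal frequent events contributes
exactly `c·s` directed edges (clonal → subclonal).  Pairs with ≥5 edges
are oriented by a two-sided binomial sign test at p = 0.5; events are
classified early/late when their out- vs in-degree is significantly
enriched (binomial test, BH-FDR, α = 0.05), intermediary otherwise.  The
binomial sign test was adopted as the simplest test consistent with
degree-enrichment ordering; samples are not down-weighted for contributing
multiple edges (an option weights each sample's edges by `1/(c·s)`).  The
significant-direction subgraph is checked for cycles, which are reported,
never suppressed — contradictory orderings are real signal of inter-patient
heterogeneity.  CCF rankings use bootstrap percentile intervals over
samples (default 1,000 resamples).

## Consensus-NMF subtyping

The event-CCF matrix (rows: prognosis-associated events from the
univariate screen; columns: samples; 0 where absent — NMF needs complete
nonnegative data) is factorized with Brunet KL multiplicative updates from
50 random starts.  Each run hard-assigns samples to their dominant basis
component; the consensus matrix is the co-clustering frequency; the final
assignment cuts the average-linkage dendrogram of 1 − consensus into k
groups, and membership weights are each sample's normalized mean consensus
with the groups (argmax of the weights is the cluster; ties break to the
lowest index).  Rank selection computes the cophenetic correlation per
k ∈ 2..6 and takes the k before the first strict decrease, falling back to
the maximum with a warning if the coefficient never decreases.

## Survival and immune analysis

Kaplan–Meier curves use the product-limit estimator and groups are compared
with the log-rank test; Cox models use the Efron tie correction with age,
sex, ordinal T stage and Fuhrman grade as the adjustment covariates.  The
univariate screen compares carriers vs non-carriers per event (optionally
split into clonal and subclonal carrier strata), skips events with fewer
than 5 carriers, selects at unadjusted p < 0.05 (the FDR column is always
emitted) and feeds the selection to subtyping.

ssGSEA ranks each sample's genes, weights set-member positions by
`rank^0.25`, and integrates the difference between the in-set and
out-of-set cumulative distributions; the score depends only on
within-sample ranks, hence is exactly invariant to monotone transforms of
expression.  Raw integrated scores are reported alongside per-gene-count
scaled and min-max normalized variants, since normalization conventions
differ between implementations.  Score ratios (Th17/Th2, CD8/Treg) shift
both scores by the cohort minimum over the two sets plus a small epsilon
before dividing, because ssGSEA scores may be negative; the ratio is
invariant to common shifts by construction.  The shipped immune gene sets
are synthetic placeholders with invented gene names — users reproducing a
published immune analysis must supply the published sets.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants, per sample: purity ~ U(0.3, 0.9); ploidy ≈ 2;
Poisson(90) passenger SNVs, clonal (CCF 1) with probability 0.75 and
otherwise CCF ~ U(0.1, 0.6); alt counts binomial at the model-expected VAF
with Poisson(100) depth; trinucleotide contexts drawn from three planted
processes (CpG C>T, asymmetric C[T>A]N, broad T>C) with per-sample
Dirichlet exposure variation (identical per-sample mixtures would make the
catalog matrix rank-1 and unrecoverable by any factorization); driver genes
and arm events at ccRCC-like frequencies whose clonality realizes their
timing class (early → clonal, late → subclonal, intermediate → either);
three molecular subtypes with distinct event profiles and hazard
multipliers 2.0 / 1.0 / 2.7; exponential survival with uniform
administrative censoring; and log-normal expression with subtype shifts on
immune-set genes.  Sample sizes in the test and acceptance runs (60–400
samples, 20 seeds, 30–50 NMF runs, 50–100 bootstrap resamples, 1,000–5,000
permutations) were chosen to give stable Monte-Carlo estimates at
interactive runtimes.

Deliberate simplifications: point mutations are placed in copy-neutral
regions (multiplicity is exercised analytically, not through the
generator); no indels, no focal SCNAs, no read-level artifacts, no
subclonal phylogenies (each subclonal event draws its CCF independently
rather than nesting); germline alt reads are zero, so the germline filters
are exercised by fixtures rather than by the generator.  Passing the
planted-recovery suite therefore demonstrates correctness of the
estimators under the stated statistical model, not robustness to mapping
artifacts, subclonal structure misspecification or purity estimation
error in real cohorts.

A planted-partition CCF-matrix generator (`make_planted_ccf_matrix`)
provides the block-structured clusters used to benchmark subtyping
recovery: three profiles marked by near-exclusive event blocks, present
events clonal with probability 0.5 and subclonal CCF ~ U(0.3, 0.8).  The
full-cohort route (screen → matrix → NMF) is exercised end to end in the
acceptance script, where its adjusted Rand index is reported as a measured
quantity; cluster separability there is limited by the planted event
frequencies themselves (a Bayes-optimal classifier on the same presence
patterns reaches ARI ≈ 0.92).

## Numerical conventions

Grid step 0.01 with strict inequalities at the 0.5 probability and 0.95
CCF thresholds; BH step-up FDR throughout; medians use the midpoint
convention; NMF restarts keep the best objective; all randomness flows
from a single seed per entry point (no hidden reseeding), and identical
seeds give byte-identical outputs.
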