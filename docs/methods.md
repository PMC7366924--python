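# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, stage by stage.

## Data model and conventions

Genotypes are diploid biallelic calls in {0, 1, 2} counting the **minor**
allele, with −1 for missing.  Orientation is fixed once, at load or
generation time (ties on allele counts break to the lexicographically
smaller allele code); every statistic downstream is invariant to allele
flipping, so the convention only matters for file round-trips.  All
genomic coordinates are 1-based and inclusive (PLINK/GFF convention).
Monomorphic sites read from PED carry an unknown minor allele (code "0")
and all-reference calls, matching PLINK's treatment of MAF-0 sites.

## Hybrid screen

Per individual, the statistic is the percentage of unambiguously mapped
reads assigned to the alternate reference genome.  Flagging uses Tukey's
far-out fence, Q3 + 3·IQR, with quartiles by linear interpolation on
order statistics (the numpy/R type-7 default); the comparison is strictly
greater.  The quartiles and fence are echoed in the report so a reader
using hinge-based quartiles can audit the difference.  The screen runs
before genotype QC, because introgressed individuals distort every
frequency-based filter downstream.  Quartiles are computed jointly over
the cohort, not per population.

## QC filter cascade

Order: individual missingness → MAF → SNP missingness → relatedness.
The missingness filters use strict inequality ("more than" 25 %); the MAF
filter keeps sites at exactly the threshold.  The order is observable:
MAF is computed before low-call-rate SNPs are removed, and the report
records each step's removals so the order can be verified.  Relatedness
uses the identity-by-state distance, 1 − mean((2 − |g_i − g_j|)/2) over
pairwise-complete SNPs; pairs closer than the cutoff (default 0.05,
read as a *distance*) are pruned greedily, removing the member with
higher missingness (ties: lexicographically later id) until no pair
remains.  On a clique of k near-duplicates this removes k − 1, the
minimal vertex cover.  A Hardy–Weinberg / linkage hook is deliberately
not part of the default cascade: the intended workflow tests and retains
(an optional exact-test + Benjamini–Hochberg step would slot between MAF
and relatedness, and is out of scope here).

## Diversity and differentiation

* **H_E** is the unbiased gene diversity (2n/(2n−1))(1 − p² − q²) with n
  the non-missing diploid count at the SNP; **H_O** is the heterozygote
  fraction; **F_IS = 1 − H_O/H_E**, undefined (and excluded from means)
  where H_E = 0.  Group summaries are mean ± SD *over SNPs*.
* **Allelic richness** uses Hurlbert rarefaction at g allele copies,
  AR = Σ_a [1 − C(N−N_a, g)/C(N, g)], with g defaulting to the smallest
  non-missing allele count over all groups and SNPs.  Because a biallelic
  SNP has AR ∈ [1, 2], AR − 1 ∈ [0, 1] is reported alongside; published
  tables in this field sometimes print the AR − 1 style quantity.
* **Weir–Cockerham θ** (1984) is computed per SNP from the a, b, c
  variance components and combined across loci as the ratio of sums —
  the standard multi-locus estimator, robust to rare alleles.  Negative
  estimates are reported as computed.  Permutation significance shuffles
  individuals between the two groups; p = (1 + #{perm ≥ obs})/(1 + B).
* **AMOVA** decomposes haplotype allele indicators into three levels
  (among populations / among individuals within populations / within
  individuals) per SNP via the moment equations, summing components over
  SNPs; percentages are components over their total.  The within-
  individual sum of squares per heterozygote is 0.5, which ties the
  decomposition to observed heterozygosity.  The among-population and
  among-individual levels get permutation p-values by permuting
  individuals among populations — a genotype-level approximation to the
  haplotype permutation schemes of dedicated AMOVA software, adequate for
  the among-population test that matters here.  Components match an
  independent pairwise-squared-distance oracle to 1e-10 in the tests.
* **Welch's t** uses the Welch–Satterthwaite degrees of freedom and a
  two-sided p from the t distribution.

Missing data are handled per SNP with pairwise-complete counts
throughout; no imputation enters any estimator (PCA is the exception and
says so below).

## Structure

PCA mean-imputes missing calls per SNP and centres columns without
variance scaling — the default of the common R workflow for SNP PCA; the
percent-variance figures depend on this choice.  Axis signs follow the
largest-magnitude loading.

The ancestry model maximizes the binomial likelihood
Σ_ij [g_ij log(Σ_k q_ik f_kj) + (2−g_ij) log(Σ_k q_ik (1−f_kj))] over
non-missing entries by EM.  EM updates are monotone in the likelihood
(asserted in tests); three random starts guard against local optima;
probabilities are clipped to [1e−9, 1−1e−9].  K = 1 is closed-form.
Model choice masks non-missing genotype entries in five folds; the CV
error is the RMSE between masked genotypes and their expectation 2·QF.
This masked-prediction RMSE is **this package's definition** of the CV
error — dedicated ancestry software defines its CV error through its own
internals, so the absolute numbers are not comparable across tools, but
the argmin over K is, and that is what the pipeline uses.

## Selection scan

The outlier model is the classic logistic decomposition of
locus-by-population F_ST: logit(F_ij) = α_i + β_j, with a multinomial-
Dirichlet (beta-binomial, in the biallelic case) likelihood for group
allele counts around an ancestral frequency p_i.  Priors: α_i ∼ N(0, 3²)
when included (the wide SD admits strong selection), β_j ∼ N(−1, 1.8²),
p_i uniform.  A reversible-jump move toggles each α_i using the prior as
proposal, so the jump acceptance is the likelihood ratio divided (birth)
or multiplied (death) by the prior odds for neutrality (default 10).
The q-value of locus i is the mean posterior neutrality probability
among loci with inclusion probability ≥ that of i (ties share the
last tied rank's value); outliers satisfy q ≤ FDR.  Chain defaults are
desk-scale (burn-in 2000 sweeps, 2000 samples thinned by 5);
`ChainParams.full()` mirrors the classical tool's schedule and
`ChainParams.fast()` is for tests — the scaled-down chains are not
equivalent to the full schedule and are labelled as such.  Groups
default to continents, the contrast of interest in range-wide surveys.

Gene-window annotation reports any gene whose interval overlaps the
closed window [max(1, pos − 200000), pos + 200000] by ≥ 1 base, on the
same scaffold only.

## Migration surface

A triangular lattice clipped to the habitat polygon approximates the
requested deme count (a warning notes when polygon geometry prevents
±10 %).  Samples attach to their nearest deme centre by great-circle
distance.  Observed dissimilarity is the mean squared genotype
difference over pairwise-complete SNPs, averaged into deme pairs.
The model expectation between demes is the effective resistance on the
graph with edge conductance (m_u + m_v)/2, plus (q_a + q_b)/2; within a
deme it is q_a.  Resistances come from the pseudoinverse of the weighted
Laplacian; disconnected graphs are rejected structurally.

Inference is random-walk Metropolis over per-deme log₁₀ m and log₁₀ q
with (i) a Gaussian smoothing prior on neighbouring demes' log-rates
(τ = 0.7 in log₁₀ units), (ii) a Gaussian likelihood on the upper
triangle of deme-mean dissimilarities with the noise variance profiled
(plugged in as the mean squared residual, floored), and (iii) weak
anchors on the overall levels.  Two design simplifications relative to
the original effective-migration-surface method are deliberate: the
Voronoi-tile prior is replaced by the Laplacian smoothing prior, and the
Wishart likelihood by the profiled Gaussian.  Both preserve the
qualitative surface — which is all that is identifiable here anyway —
at a fraction of the implementation and compute cost; this is a
simplification, not a re-implementation of the original tool.  The
absolute migration scale is not identifiable from dissimilarities up to
the weak anchors, so every reported surface is normalized per draw to
zero mean log₁₀ m; corridors/barriers are demes whose posterior
probability of lying above/below 0 exceeds the classification threshold
(default 0.9).  Proposal scales adapt toward ~30 % acceptance during
burn-in only.  Desk-scale defaults (50 000 iterations, 2 chains; tests
and the acceptance script use 15 000–25 000 on ~24-deme grids) give
replicate-seed surface correlations above 0.9 on the test fixtures;
cluster-scale analyses of ~500-deme grids would need the full
10⁷-iteration schedules of the dedicated tool.

## Demographic preparation

Locus selection takes a uniform random sample (without replacement)
among loci with 4–6 segregating sites and ≥ 75 % individual presence —
the composition that balances coalescent information against alignment
reliability for short RAD loci.  The clock calibration measures, per
locus, the mean per-site difference of each ingroup sequence against the
outgroup (IUPAC heterozygote vs a matching outgroup allele counts 0.5,
else 1 — the counting rule is this package's choice, as published
procedures rarely state one), averages within SNP class (4, 5, 6) and
then across classes, and converts with rate = d̄/T · g (T the
interspecific split time in years, default 4.4 × 10⁶; g the generation
time in years, default 5).  **No factor of 2** divides the divergence
between the two lineages: that is the published procedure this stage
mirrors, reproduced verbatim and deliberately not "corrected" — users
comparing against a 2T convention should halve the rate.  NEXUS export
writes one DATA block per locus (datatype DNA, missing `?`, gap `-`);
absent individuals are omitted by default or written as all-missing rows
on request, and the manifest carries the calibrated rate.

## Synthetic data: what it emulates, and what it does not

* **Island model** — Balding–Nichols: population allele frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ∼ U(maf range),
  genotypes Binomial(2, freq); F = 0 short-circuits to identical
  frequencies.  This gives analytic F_ST control with no external
  simulator, at the cost of no linkage, no site-frequency-spectrum
  realism, and exchangeable loci.  Missingness is uniform at random
  (`geno_missing_rate`); a fraction `ind_missing_rate` of individuals
  additionally get ~50 % of calls masked, giving the QC stage planted
  `--mind` violations.  Populations cycle through African and Asian
  country codes so continent groupings exist.
* **Relatives** — the second member of each pair becomes a copy of the
  first with each non-missing call re-drawn (to a different value) with
  probability `copy_error`; pairs may not overlap.
* **Read assignments** — totals Poisson(mean_reads), alternate counts
  Binomial(total, f) with f elevated in planted hybrids.  Real
  per-individual read depths for such screens are study-specific and not
  published; the default mean of 10⁵ is an arbitrary round number, large
  enough that the percent statistic's binomial noise is negligible
  relative to the 1 % baseline.
* **Spatial grid** — per SNP, latent deme values follow a Gaussian
  Markov random field with precision L_m + diag(1/q) (L_m the same
  migration-weighted Laplacian the inference stage uses), centred on the
  logit of a random ancestral frequency and mapped through the logistic;
  genotypes are binomial.  This preserves the monotone distance–
  dissimilarity relationship the surface estimator needs while being
  orders of magnitude faster than forward simulation; it is not a
  coalescent model and its q parameter is a variance scale, not an
  effective size.  Barrier/corridor test conditions use q = 10 and a
  background m = 2 with a two-deme-wide band at m = 0.02 (barrier) or
  m = 4 (corridor): with mean-of-endpoints edge conductances, a band
  narrower than the lattice spacing barely reduces path conductance, so
  contrasts are drawn at band widths ≥ 2 lattice steps.  These values
  were fixed from the analytic GMRF covariance (neighbour vs cross-band
  latent-difference variance) before any inference was run.
* **RAD loci** — segregating sites get minor-allele counts from a folded
  neutral (1/i) spectrum; each individual is present with probability
  `presence`.  The `outgroup_divergence` parameter targets the
  **measured** mean ingroup–outgroup per-site divergence: because
  segregating sites already contribute (the outgroup carries the
  ancestral/major base), the generator plants fixed differences at a
  rate reduced by each locus's realized polymorphism contribution,
  clamping at zero (with a warning) when polymorphism alone exceeds the
  target — as at divergence 0, where no fixed differences are planted
  and the small residual measured divergence is the polymorphism floor.

All generators derive their randomness from a single integer seed and
are bit-reproducible.  Passing tests on these generators demonstrates
estimator correctness and operating characteristics under the stated
models; they do not demonstrate robustness to linkage, allele-calling
error, reference bias or non-equilibrium demography, none of which the
generators emulate.

## Pipeline

Stages run in the fixed order hybrid screen → filter → stats →
structure → scan → migration surface → demographic prep; each consumes
the previous stage's outputs, and the JSON run report embeds the config,
per-stage child seeds (global seed plus fixed offsets), counts and wall
times, so a run is reproducible from its report alone.  Exit codes:
0 ok, 1 user error, 2 data error.

## Problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen to make each statistical check decisive at a few minutes of
compute: 2×200 individuals × 5000 SNPs for F_ST recovery (Monte-Carlo
SE ≈ 0.002, against a ±0.02 band), 1000-locus scans with 2×30
individuals, 24-deme grids with 4 samples per deme × 500 SNPs, and
300-locus RAD pools.  Larger sizes change the runtimes, not the
conclusions.
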