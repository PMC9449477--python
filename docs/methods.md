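# Methods

## Problem setting

Three herring population groups co-occur in the study area outside their
spawning seasons: an autumn-spawning group (`6aN_Aut`), a winter-spawning
group (`6aS`) and a spring-spawning group (`6aN_Sp`). Survey and commercial
catches are mixtures, so individuals genotyped on a 45-SNP discrimination
panel must be assigned back to a population of origin against baselines built
from spawning-condition (maturity stage 3) fish collected on known spawning
grounds. The panel's markers sit in 14 locus blocks on 8 chromosomes; linked
markers are retained deliberately as redundancy against missing genotypes.

## Genotype calling

Calls derive from the allele-1/allele-2 read-count ratio r (r = +inf when
the allele-2 count is zero; hom2 is still reachable via r = 0 when allele-1
is zero). Zones are closed on the called side:

| call | zone |
|---|---|
| hom1 | r ≥ 5.0 |
| het | 0.3 ≤ r ≤ 3.33 |
| hom2 | r ≤ 0.2 |
| NA | (0.2, 0.3), (3.33, 5.0), or total depth < 10 reads |

The printed zone endpoints leave tiny numeric gaps (e.g. 3.33–3.34); the
half-open convention above resolves every gap to NA, the conservative choice.
The completeness filter keeps individuals with ≥ 40 of 45 genotypes (the
"greater than 89%" criterion is implemented as the count, ≥ 40, which is the
unambiguous reading). Per-marker threshold overrides are supported, and a
diagnostic (`propose_ratio_zones`) suggests boundaries from the observed
log-ratio histogram, but defaults are never silently overridden.

Demultiplexing matches 11 bp barcodes by Levenshtein distance (≤ 1 edit by
default, via edlib); ties at the minimum distance are discarded, never
guessed. Reads sort hierarchically into five categories (no barcode / one
barcode / two barcodes and no, non-matching, or matching primers); only the
last category is counted.

## Baseline statistics

*HWE.* Exact conditional test on the Levene distribution
P(h | n1, n2) ∝ n! 2^h / (n11! h! n22!), enumerated for sample sizes ≤ 500;
above that a seeded Monte Carlo shuffle of the 2n alleles is used. The
two-sided test is the probability test (sum of outcomes no more probable than
the observed); deficit/excess variants are tails in the heterozygote count.
Monomorphic loci return p = 1 with a flag.

*LD.* Genotypic (phase-free) G-test on the up-to-3×3 genotype contingency
table of a locus pair; the null distribution permutes one locus's genotypes
across individuals. p = (1 + #{G_perm ≥ G_obs}) / (B + 1). Under simulated
independence the p-values are uniform (KS-checked in the test suite).

*F_ST.* Weir & Cockerham (1984) variance components a (among populations),
b (among individuals within populations), c (within individuals), combined
across loci as θ = Σa / Σ(a+b+c). Missing genotypes are excluded pairwise
per locus; loci with fewer than two called individuals in any group are
dropped from a pair with a warning; negative estimates are reported as
computed. Permutation p-values shuffle individuals between the two groups of
a pair; 95% CIs bootstrap loci with ratio-of-sums recombination. The
estimator variant is declared in the output metadata because the original
desktop tools do not document theirs; parity beyond ~0.01 with legacy
software is not promised.

*Multiple testing.* Sequential Bonferroni is implemented as Holm's
step-down: the i-th smallest p is significant iff p < α/(m − i + 1) and all
smaller p-values passed. Note 0.04 < 0.05/1, so in a family
{0.001, 0.02, 0.04} at α = 0.05 all three survive.

*PCoA.* Classical metric MDS: double-centre the squared distances,
eigendecompose, order axes by eigenvalue, report all eigenvalues but drop
non-positive axes from the coordinates. This is hand-rolled rather than
delegated because pairwise F_ST matrices can carry small negative
off-diagonal entries that strict distance-matrix containers reject.

## DAPC and cluster discovery

Dosages (0/1/2, count of allele 1) are mean-imputed per marker and centred;
scaling is off by default since dosage variance is bounded. DAPC is PCA to
n_pcs followed by LDA on the scores; with full-rank PCs and two classes it
reproduces plain LDA posteriors (oracle-tested against a textbook Gaussian
LDA). The PC count is chosen by repeated stratified holdout:
RMSE = sqrt(mean((1 − success)²)), smallest n_pcs on ties.

Cluster discovery runs K-means (10 restarts, Lloyd, tol 1e-8) on PC scores
for each K and scores BIC(K) = n·ln(W_K/n) + K·ln(n) (spherical Gaussian
approximation; W_K = total within-cluster SS); the smallest K wins ties. Two
properties of this formula matter in practice. First, at K = n the formula
degenerates (W = 0 → BIC = −inf), which is why the candidate range is
restricted to [1, n−1]. Second, an overfitting split of a well-separated
cluster removes roughly 0.64·λ₁/(K·d) of W (λ₁ the top within-cluster
eigenvalue, d the retained dimensionality), against a penalty of ln(n)/n per
point — so reliable automatic K recovery needs enough retained dimensions
relative to sample size. The validation fixtures use 30-dimensional blobs
with 50 points each, where recovery is 100/100; on real SNP baselines the
criterion tends to over-split populations into sub-clusters, which is
exactly why cluster-to-proxy mapping exists: clusters whose known-origin
composition exceeds 80% for one population are merged into a proxy named for
it, and sub-threshold clusters become explicit mixed proxies named by their
top two populations.

## Hierarchical assignment

Each level is strictly binary. Level 1 contrasts `6aN_Aut` against the
pooled `6aS`+`6aN_Sp`; Level 2 splits the pool. Approach 1 uses the
predefined population labels; Approach 2 replaces them with cluster proxies.
Per iteration: a balanced training set (n_train per group, sampled without
replacement; the remainder tests), a locus subset (top ⌈fraction·L⌉ by
training-split F_ST, or uniform random; ≥ 1 locus floor), then
impute → centre → PCA (training-fitted) → RBF SVM. Probabilities are Platt
scaling fitted on cross-validated decision values, with the final SVM refit
on all training data — calibrated probabilities, not margins, feed the
decision table. The F_ST locus ranking is recomputed inside every iteration
from the training split only, so no test individual influences feature
selection, PCA or the SVM (leakage is the conservative reading to guard
against; the training-only ranking is asserted in the test suite).

Defaults mirror the standard workflow: 100 Monte Carlo iterations; training
sizes 200 per group at Level 1 (the study design explored 200–800 at Level 1
and 50–200 at Level 2); cost 1 with gamma 0.33 (Level 1) and 0.5 (Level 2)
as grid-search results, re-tunable via `tune_svm` (ties resolve to the
smallest cost, then gamma).

Final calls apply the decision table at threshold P = 0.67 (an assignment
twice as likely as its alternative), with ≥ comparison so exactly 0.67 is
assigned: a confident Level-1 autumn call is final; a confident Level-1
mixed-side call proceeds to Level 2; below threshold at Level 1 is NA; a
confident Level 2 call is final; below threshold at Level 2 falls back to
the mixed label (`6aS/6aN_Sp`). Unknowns must have ≥ 60% of the panel
genotyped (the locus-sensitivity analysis shows accuracy degrading below
~60% of loci); individuals under that floor are NA with reason
`insufficient-loci`. Threshold sweeps recompute calls from stored
probabilities without retraining, so the unassigned proportion is monotone
in the threshold by construction.

## Synthetic data model

The generator defines the study conditions rather than emulating any
particular dataset:

- **Allele frequencies.** Each locus block b has a differentiation delta_b
  (default 0.5 everywhere); population p (of r) is shifted by
  delta_b · p/(r−1) from a base frequency (drawn Uniform(0.2, 0.5) per block
  unless given). All markers in a block shift together — one latent shift
  per (block, population) — reproducing block-level LD without simulating
  haplotypes. With three populations this yields expected pairwise W&C
  F_ST ≈ 0.12 (adjacent) to ≈ 0.42 (extremes), about 0.2 on average, i.e. a
  strongly informative panel.
- **Closed form.** The large-sample limit of the W&C estimator for known
  frequencies is θ∞ = s²/(p̄(1−p̄) + s²/r) per locus (s² the (r−1)-denominator
  frequency variance), combined across loci by ratio of sums; simulated
  estimates converge to it (rel. 5% at n = 2000/population in the tests).
- **Genotypes.** Binomial(2, freq) dosages (HWE within populations) with a
  Bernoulli missing mask (default 1%).
- **Reads.** Depth ~ NegativeBinomial(mean 100, shape 2.0) — over-dispersed
  as amplicon data are; Poisson would understate depth variance. Allele-1
  reads are Binomial(depth, q) with q = 1−e, e, or 0.5 by true genotype
  (error default 0.5%, symmetric so het stays at 0.5); a 2% dropout rate
  forces zero-coverage cells.
- **Mixtures.** Origins drawn i.i.d. from the specified proportions;
  genotypes from the origin's frequencies.

Seeding: every operation derives its stream from (seed, fixed offset) via
`numpy` SeedSequence, so stages re-run independently and bit-identically.

What the generator does **not** model: migration and admixed individuals,
age/length structure, coalescent history, genotyping batch effects, null
alleles, and within-population temporal drift. Passing tests therefore
demonstrate correctness of the machinery and calibration of the statistics
under idealized population structure — not that any real baseline separates
this cleanly; on real data the Level-2 contrast in particular is known to be
much weaker than Level 1.

## Validation choices and problem sizes

The standard synthetic baseline is 3 populations × 300 individuals ×
45 markers with 1% missing data. Acceptance-level checks use: an exhaustive
caller grid over all zone boundaries; full enumeration of the Levene
distribution for all tables up to n = 100; KS uniformity of 1000 LD
p-values (199 permutations each); 50 random small instances for the
F_ST-oracle identity at 1e-12; 100 seeded three-blob runs for K recovery;
100 Monte Carlo iterations for hierarchical self-assignment (observed ≈ 0.98
against the ≥ 0.90 expectation); and a 500-individual 60/30/10 mixture
checked against per-component 95% binomial sampling bounds around the
realized origin counts (the comparison isolates assignment error from the
multinomial sampling noise already present in the draw). Pipeline runs are
verified byte-identical under a fixed config.

## Known limitations

- The HWE Monte Carlo branch and the permutation tests give discrete,
  slightly conservative p-values; resolution is 1/(B+1).
- The BIC criterion over-splits non-spherical genotype clouds (see above);
  the proxy-mapping step absorbs this by design, and six-or-so clusters for
  three populations is the expected behaviour, not a defect.
- GENEPOP export is limited to biallelic two-digit coding; population names
  are positional on import (`pop1`, `pop2`, ...) as the format carries none.
- Numerical parity with the legacy desktop tools (Genepop, MSA, GenAlEx,
  adegenet, assignPOP/e1071) is approximate by nature: estimator variants
  and RNG streams differ even where the statistics agree.
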