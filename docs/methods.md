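# Methods

## Model

An ancient inversion suppresses recombination between orientations, so
chromosomes in the inverted segment coalesce within J divergent haplotype
groups (J = 2–4 supported), each group carrying a single orientation
(standard N or inverted I) unless the inversion is recurrent. Diploids
occupy the J(J+1)/2 unordered group pairs ("haplotype-genotype" classes).
Because the classes differ additively in allele content, they separate in
the leading principal coordinates of any reasonable genotype distance:
3 collinear clusters for J = 2, a 6-cluster triangle for J = 3, a
10-cluster tetrahedron for J = 4, heterozygous clusters at the midpoints
of their homozygous pairs.

The classifier itself is deliberately simple: per class k, the
ρ²-weighted average over scorable SNPs of the frequency of the subject's
observed genotype in that class,

H_k = Σ_{i∈L} f_ki(s_i) ρ_i² / Σ_{i∈L} ρ_i²,

with the argmax over classes giving the call. For probabilistic
genotypes the observed-genotype frequency is replaced by its expectation
under the posterior triple. The published form of the probabilistic
score prints a different index range in the denominator than in the
numerator; we read both as the same scorable-site set L, since otherwise
one-hot posteriors would not reduce to the hard score. The site set L is
determined **per class**: a site enters class k's numerator and
denominator only if the subject's genotype is non-missing, the site's
weight is positive, and class k has frequency data there. This keeps
sparse (exome-like) queries scorable without biasing any class.

## Builder pipeline

1. **Distance.** Mean per-site Manhattan distance on genotype codes,
   pairwise-complete over missing data. No distance is canonical for
   this step; the Manhattan mean reproduces the additive cluster
   geometry (heterozygous classes exactly midway between homozygous
   ones, in expectation) and tolerates missingness. Sample pairs with no
   shared sites (only possible under extreme missingness) get the global
   mean distance, with a warning.
2. **Embedding.** Classical MDS (principal coordinates) via
   eigendecomposition of the double-centered squared-distance matrix;
   negative eigenvalues are clipped. Axis signs are fixed by making each
   axis's largest-magnitude coordinate positive, so results are fully
   deterministic.
3. **Clustering.** For each candidate J in ascending order, a Gaussian
   mixture with J(J+1)/2 full-covariance components is fitted on the
   first 1/2/3 axes (J = 2/3/4) with 20 k-means++ restarts under a fixed
   seed. A candidate passes the **pattern test** if some subset of J
   centroids forms a simplex whose remaining centroids match the pairwise
   midpoints (assignment by the Hungarian algorithm) with maximum
   relative deviation ≤ `tol_equidistance` (default 0.35 — loose enough
   for sampling noise at n ≈ 100–200, configurable), and the homozygous
   clusters are separated by ≥ 3 pooled within-cluster standard
   deviations. The separation requirement rejects degenerate "patterns"
   fitted to a single undifferentiated blob (zero divergence). Among
   passing candidates, the lowest BIC — computed from the hard
   assignments in a common axis space so that models fitted on different
   axis counts are comparable — wins; ties go to the smallest J. If no
   candidate passes, the region is declared unmappable: the divergent-
   haplotype structure the method requires is absent.
4. **Group naming.** Homozygous clusters are labeled A–D by descending
   size; heterozygous labels follow from the midpoint matching. Naming
   is therefore deterministic but arbitrary with respect to any external
   naming; `evaluation.class_assignment_accuracy` compares assignments
   up to a bijection of group symbols.
5. **Status mapping.** Each group is assigned N or I by majority vote of
   its labeled homozygous members (NN votes N, II votes I; an NI label on
   a homozygote is discordant and casts no vote). Groups without
   homozygote votes are resolved iteratively through heterozygous labeled
   samples. If a group with ≥ 5 votes has majority fraction < 0.7, the
   haplotype evidently occurs on both orientations and the build fails
   with the recurrent-inversion diagnosis; an exact tie among fewer votes
   raises an ambiguity error listing the samples. Concordance (the
   percent of labeled samples whose mapped genotype equals their label)
   is recorded in the panel.
6. **Frequencies and weights.** f_ki(x) uses a per-class, **per-site**
   denominator M_{k,i} (non-missing members of class k at site i), the
   natural extension of the per-class count to incomplete reference
   data. No smoothing: an unseen genotype has frequency exactly 0 and
   contributes nothing to that class's score — with several SNPs this is
   self-correcting, and it keeps the single-reference regime exact.
   ρ_i² is the maximum over groups of the squared Pearson correlation
   between the SNP's codes and the group dosage (0/1/2 copies of the
   group in each sample's class); for J = 2 this equals the LD R²
   between the SNP and inversion-allele dosage. Zero-variance sites get
   weight 0; an all-zero weight vector is a degenerate panel and an
   error.

## Harmonization policy

Queries are matched to panel sites by (chrom, pos), with id as fallback.
Swapped ref/alt flips codes (x → 2−x); opposite-strand reports of
unambiguous alleles are complemented and matched; strand-ambiguous sites
(A/T, C/G) that do not match as-is are dropped — a swap there is
indistinguishable from a strand flip, and silent miscoding is worse than
losing a site. Irreconcilable alleles are dropped and counted. The
operation is idempotent. Genotype-probability triples are renormalized
when their sum is within 1e-3 of 1 (dosage-format rounding) and treated
as missing otherwise. SNPs with call rate < 0.9 across the cohort are
discarded before scoring (the conventional pre-scoring filter; the
threshold is strict, so a rate of exactly 0.9 is retained).

## Classification policy

An exactly tied maximum, or a margin (best minus second-best score)
below `min_margin` (default 0: no quality threshold unless requested),
yields NO_CALL with a diagnostic reason rather than an arbitrary call.
Classes that cannot be scored for a sample (no data overlap) are
excluded from the argmax rather than scored 0, which would otherwise
produce spurious NO_CALLs on sparse input. Per-sample failures in cohort
scoring become NO_CALL results and never abort the cohort. All cohort
reductions are computed per sample with shape-independent summation, so
results are bit-identical across batch sizes and sample orderings.

## Synthetic cohorts

The generator produces the statistical structure the classifier assumes,
directly: J ancestral haplotypes differing pairwise at
⌈divergence·n_sites⌉ sites (for J ≥ 3, private derived blocks of
⌈d/2⌉ sites per group give pairwise differences of 2⌈d/2⌉ ≈ d);
each chromosome copies its group's ancestral haplotype with per-site
mutation probability theta; diploids draw two chromosomes by group
frequency; missingness is i.i.d. Defaults: J = 2, 100 SNPs, divergence
0.3, theta 0.01, group frequencies giving an inverted-allele frequency
of 0.4, 200 samples. Trios transmit one uniformly chosen chromosome per
parent, without recombination or de novo mutation. Degradation modes
emulate low SNP coverage (uniform site subsampling over the
10/20/50/75% grid) and imputation uncertainty (one-hot triples mixed
with the uniform distribution). `ancestral_seed` lets independent
cohorts share the same underlying inversion. Recurrence mode assigns
orientation at random to chromosomes of the first group, reproducing
the recurrent-inversion failure the builder must detect.

What the generator does **not** emulate: within-group recombination and
LD decay, allele-frequency spectra from demography, genotyping error
correlated with allele frequency, population structure and admixture.
Passing tests therefore demonstrate correctness of the algorithms under
the divergent-haplotype model, not performance on cohorts whose
haplotype variability exceeds the reference panel's — the known hard
case for this method family. Recurrence detection happens at the
label-mapping stage (conflicting experimental labels within one
haplotype group), since the cluster geometry of a recurrent inversion
can be indistinguishable from a mappable one.

## Evaluation conventions

Leave-one-out keeps cluster assignments from the full-data model
(labels are experimental, not re-estimated) and rebuilds frequency
tables and weights per holdout. NO_CALL counts as an error in accuracy
but is excluded from Mendelian denominators: accuracy judges the
classifier, transmission errors judge called genotypes. Genotype
proportions get Wilson score intervals; Hardy–Weinberg uses the exact
conditional test on heterozygote counts (no mid-p). Inheritance
encodings (additive / dominant / recessive) are exported for external
association tools; the association model itself is out of scope.
Robustness replicates in which the subsampled panel has no informative
site (possible at 10% coverage of a 100-SNP region) count as accuracy 0
for that replicate.

## Problem sizes

The test suite and the acceptance script use cohorts of 200 samples and
100 SNPs, 200 replicates for coverage curves, 100 trios, 1,000
randomized panels for oracle equivalence, and 40 seeded replicates for
the J-recovery rate; these sizes make every quantity stable at the
asserted thresholds while keeping a full run in tens of seconds.

## Known limitations

- J > 4 haplotype groups are not supported (the pattern catalogue ends
  at the tetrahedron).
- X-linked scoring accepts hemizygous {0,2} codes and the label table
  accepts N/I, but no sex-aware plausibility flagging is implemented.
- The BIC comparison across candidate J uses hard assignments; extremely
  overlapping candidate patterns could in principle prefer the wrong J
  before the pattern test excludes one of them.
- PLINK and snpMatrix ingestion, phasing, and imputation itself are out
  of scope; input is VCF with GT (and optionally GP).
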