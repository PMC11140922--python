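# Methods

This document records the statistical methods implemented in `flightsift`,
the modelling assumptions behind the synthetic data generator, and the
numerical design choices that matter for reproducing the results.

## Synthetic cohort model (`synth`)

Allele frequencies follow a two-level Balding–Nichols hierarchy: ancestral
frequencies `p ~ Uniform(0.05, 0.95)` per locus, lineage frequencies drawn
from `Beta` with parameters `p(1-F)/F` at `F = fst_lineage`, and colony
frequencies nested inside lineages at `F = fst_colony`. Moths are drawn as
full-sib families (`sibs_per_family`, default 5): two parental genotypes per
family from the colony frequencies, offspring by independent gamete sampling.
The default design (8 colonies, 300 moths) is the study condition; tests and
the acceptance script construct explicit variant configurations (e.g.
structureless cohorts) where a property requires them.

Flight is a logistic liability: `liability = ±offset (lineage) +
Σ β (dosage − 2p) + N(0,1)`, `P(fly) = expit(liability)`, and flyers map to
ordinal scores {3, 4, 5} with weights (0.08, 0.12, 0.80), non-flyers to
{0, 1, 2} mirrored. Forewing length is Gaussian with lineage-specific means
plus additive locus effects. Causal loci are drawn among common variants
(ancestral frequency in [0.2, 0.8]) so that planted signal is detectable in
principle. Genotype missingness is uniform at `missing_rate`; sequencing
depth is Poisson.

Inbred pedigrees are simulated as two-haplotype lines: an ASM flyer ×
ESM non-flyer cross propagated for `inbred_generations` with per-locus
crossovers, producing parents that are opposite homozygotes at informative
loci and progeny whose genotypes follow the recorded haplotype bookkeeping.
The truth record lists the loci that satisfy the full co-segregation pattern,
so filter output can be compared exactly.

## Variant QC (`variant_qc`)

Six rules in fixed order, with explicit inequality conventions:

1. biallelic sites (optionally SNPs only);
2. Hardy–Weinberg exact test in ASM controls, drop if `p < alpha`. The exact
   test is the Wigginton enumeration of heterozygote counts conditional on
   allele counts; the implementation in floating point is unit-tested against
   an exact-rational (`fractions.Fraction`) reimplementation;
3. minor-allele-frequency conjunction: drop only when global MAF < 0.10
   **and** ESM MAF < 0.30 (rare-overall but ESM-common variants are the
   interesting ones and are kept);
4. locus missingness > 0.5 **or** mean depth < 5, both strict;
5. complete-LD pruning: within each contig, randomly discard one member of
   every pair with `|r| = 1` on pairwise-complete dosages, iterating until no
   such pair remains;
6. sample missingness > 0.5, strict.

The acceptance test checks rules 1–4 and 6 against brute-force loop
reimplementations for exact equality on 100 random matrices with planted
violations. Rule 5 needs care: with missing genotypes, pairwise `|r| = 1` is
**not transitive**, so an equivalence-class oracle is wrong. The oracle
instead verifies the defining invariants of a correct prune — no surviving
within-contig pair in complete LD; every removed locus had a complete-LD
partner — plus exactly-one-survivor on a planted missingness-free triple.

## Structure (`structure`)

KING-robust kinship: `φ̂ = (N_het,het − 2 N_opp-hom) / (N_het(i) + N_het(j))`
over pairwise-complete loci, computed with indicator matrix products. A
maximal unrelated set is found greedily (repeatedly drop the sample with the
most pairs above the 0.025 threshold). PCA is fit on the unrelated set with
loci standardized as `(dosage − 2p̂) / sqrt(2 p̂ (1−p̂))` and related samples
projected onto the loadings (the PC-AiR idea). `pc_adjusted_kinship`
residualizes genotypes on the PCs before re-estimating kinship (the PC-Relate
idea), and `kinship_factors` extracts leading eigenvectors of the kinship
matrix for use as extra covariates.

## Association scan (`gwas`)

Flight scores 0–5 are binarized at 3 (0–2 vs 3–5). The per-locus test is the
1-df GLM score test: fit the null model (intercept + covariates) once per
missingness pattern, then for each locus

```
U = x'(y − μ₀)/a,   V = [x'Wx − x'WZ (Z'WZ)⁻¹ Z'Wx]/a,   stat = U²/V
```

with `W` the variance-function weights and `a` the dispersion (binomial:
`W = μ(1−μ)`, `a = 1`; gaussian: `W = I`, `a = σ̂²`). The genomic inflation
factor is `median(stat) / χ²₁⁻¹(0.5)`. QQ frames are ordered
most-significant-first. `model_grid` runs the scan across a PC grid and
selects the largest converged model; `adjust_p` provides Benjamini–Hochberg
(default) and Bonferroni. `ld_annotate` assigns genes to outliers that are
inside a gene span or in strong LD (`r ≥ 0.90`) with an in-gene marker, at
`p < 0.05`.

A dispersion bug was caught by the unit suite and is worth recording: the
gaussian null fit originally used weights `1/σ²` while `U` and `V` were also
divided by `a = σ²`, double-counting dispersion and making the statistic
scale-dependent. The fixed statistic equals `n·r²` for an intercept-only
null and is invariant to rescaling `y`.

## Inbred co-segregation filter (`inbred`)

QC first: genotypes with depth < 10 are masked (≥ 10 kept, inclusive), loci
with heterozygosity > 0.93 or genotyping rate < 0.70 dropped. The
conjunction filter then keeps loci where, simultaneously, every flyer is
heterozygous or homozygous for the flyer allele, no non-flyer carries two
flyer alleles in the disqualifying configuration, and the pedigree parents
are opposite homozygotes; `mode="union"` accepts any single pattern.
`segregation_summary` reports the mean and SD of the per-locus allele
frequency difference of the flyer-fixed allele between phenotype groups
(e.g. diffs {0.9, 1.0} → mean 0.95, SD ≈ 0.0707).

## Enrichment (`enrichment`)

GO term enrichment is the hypergeometric upper tail `sf(k−1, M, n, N)`
(a 5-gene term fully contained in a 5-gene candidate set over a 20-gene
universe gives exactly `1/C(20,5)`). Terms are mapped to 12 keyword
categories by case-insensitive substring (optionally word-boundary) matching
of name + definition. Category over-representation uses a one-tailed binomial
test with `p₀` the category's proportion among all annotation terms, BH
adjustment across categories.

**Calibration design (acceptance criterion).** The binomial test is
discrete, so its empirical type-I error can only land on achievable levels
≤ α. The calibration simulation therefore uses enriched-set sizes of
500–1500 and background proportions 0.2–0.4, where the achievable levels
cluster near 0.05 and an empirical rate in [0.04, 0.06] is attainable; the
design was fixed from this discreteness analysis before running the check.

MCL is hand-implemented on a dense numpy matrix (no pre-installed package
provides it): self-loops at each node's max incident weight, column
normalization, then alternating expansion (matrix square) and inflation
(elementwise power 2.0, renormalize) with pruning at 1e-6 until stable;
clusters are connected components of the attractor support.

**Oracle sizing.** The brute-force modularity-optimal partition used as the
MCL oracle enumerates set partitions (restricted-growth strings, ≤ 4 blocks)
and is feasible only to ~10 nodes; the acceptance check uses 9-node planted
3-block graphs (within the criterion's ≤ 15-node bound), plus an exact
recovery check on the canonical 15-node 3×5-block graph.

## Profiler (`profiler`)

`DAPCClassifier` is a scikit-learn estimator: mean imputation and scaling
statistics computed on the training fold only, PCA to `n_pcs`, then LDA.
The leakage guard is structural (no test-fold statistics ever enter the
fit) and is unit-tested. `xval_npcs` picks the retained PC count by repeated
stratified validation; `replicate_profiling` draws stratified training sets,
fits, predicts all held-out moths, and tests the success count against
chance with a one-tailed binomial (null = test-set majority-class proportion,
the conservative choice, or 0.5).

**Adaptive PC grid.** The original default grid (1, 2, 4, 6) truncated the
model space below the panel rank: for a 12-marker panel of independent
equal-effect loci the discriminant direction spreads across all 12 PCs, and
cross-validation consistently chose the grid maximum while success stalled
at 0.74 against 0.90 achievable by plain LDA. The default grid is now a
doubling sequence (1, 2, 4, …) extended to `min(n_markers, n_train −
n_classes)`; cross-validation still performs the selection.

## Reproducibility

Every stochastic step takes an explicit seed; derived seeds stay below 2³¹.
The pipeline manifest records a SHA-256 digest per artifact, and the test
suite asserts digest-level determinism across repeated runs.
`scripts/acceptance.py --seed S --out F` recomputes all headline quantities
from scratch in about two minutes.

## Limitations

- The generators are stylized: no LD within contigs beyond planted
  duplicates, no genotyping-error model, Poisson depth independent of
  genotype, and a liability model with a single shared effect size per trait.
- PCs do not absorb close kinship; under the default family design the
  flight scan retains GIF ≈ 1.2–1.8 depending on covariates. The package
  reports this rather than correcting it with a mixed model, which is out of
  scope.
- The MCL modularity oracle caps at 4 blocks and ~10 nodes; larger graphs
  are checked by planted-partition recovery only.
- The category test treats terms as independent; overlapping gene content
  between terms is handled downstream by MCL clustering, not by the test.
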