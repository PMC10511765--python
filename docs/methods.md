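# Methods

This note documents the models behind `cassacore`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer should know about.

## The pipeline

A germplasm bank holds N accessions genotyped at L biallelic SNPs (diploid
dosages 0/1/2) and phenotyped over years and trials for quantitative and
qualitative descriptors. The goal is a core subset — a sampling intensity
of 10% by default — that represents the complete collection, plus evidence
that it does. The pipeline stages are: phenotype consensus → distance
matrices → AN/EN subset optimization → six-strategy build with ≥2-vote
consolidation → diversity evaluation.

## Consensus phenotyping

Qualitative descriptors use the mode over observation years. Ties break to
the lowest class code: the choice is arbitrary, but determinism is required
for reproducibility, and the lowest code is stable under adding empty
classes.

Quantitative traits use the all-random mixed model
`y = 1μ + Zg + Wb + Ti + e` with independent normal effects for genotype
(σ²g), block nested in trial (σ²b), genotype×trial interaction (σ²i) and
residual (σ²e). A single global intercept is the only fixed effect. Trials
are the year×location "environment" unit; with a single trial the
interaction is not identifiable and is fixed at 0 (reported as such).

Variance components are estimated by EM-REML. EM is slower than
average-information REML but monotone, keeps every component non-negative
at every iterate, and is robust on the small, sometimes degenerate fixtures
this package must handle (noise-free data, zero-heritability traits).
Convergence is declared when all free components change by < 1e-6
relatively (components that have collapsed below 1e-8 of the phenotypic
variance are treated as zero and excluded from the test), with a 500-
iteration cap; a non-converged fit returns the last iterate with a warning.
The mixed-model equations are solved by Schur complement on the
genotype×trial block, which is diagonal, so one EM sweep costs a single
dense factorization of the (intercept + blocks + genotypes) system — about
10 ms at N = 300 with 6 records per accession.

BLUPs are used raw (no de-regression, no intercept added): every
downstream consumer (Gower distance, Shannon–Weaver binning, PCA) is
invariant to a common shift, and shrinkage is uniform in balanced designs.

## Distances

- **Gower** is computed as the availability-weighted mean of per-variable
  dissimilarities (the printed similarity form is used as its complement).
  Quantitative ranges R_j are frozen from the complete collection even when
  scoring subsets, so core and complete distances stay on one scale.
  Constant traits (R_j = 0) are dropped with a warning; a pair sharing no
  observed variable is an error rather than a silent 0.
- **Modified Rogers** is evaluated on within-individual allele frequencies
  p = dosage/2. For biallelic loci the double allele sum collapses to
  `sqrt((1/L) Σ Δp²)`; the explicit 2L-coordinate form is retained behind a
  flag and tested equal to 1e-12.
- **Czekanowski (Manhattan)** reads the 1/2L normalization as a mean over
  the 2L allele coordinates, giving range [0, 1] and, for biallelic loci,
  `(1/L) Σ |Δp|`. By Jensen's inequality it never exceeds Modified Rogers.
- **Blended** pooled-data distance is `w·Gower + (1−w)·Czekanowski` with
  w = 0.5. The even split is an explicit assumption — the pooled strategy
  does not prescribe a weighting — and is configurable.

Dosage orientation (ALT vs REF counting) is configurable and irrelevant to
all four distances for biallelic loci.

## Core selection

AN (average accession-to-nearest-entry, minimized) averages over **all**
accessions, entries contributing zero — this matches the criterion's name
and the A-NE convention of core-selection software; averaging only over
non-entries is available as a flag. EN (average entry-to-nearest-entry,
maximized) requires ≥2 entries, hence core sizes are clamped to ≥2;
otherwise the size is ⌈fraction·N⌉ (0.10 × 1486 → 149).

The optimizer is parallel tempering over fixed-size subsets: 4 replicas on
a geometric temperature ladder from 1e-4 to 1e-1 (objective scale), 50,000
Metropolis steps per replica, single-swap moves (one selected for one
unselected accession), replica exchange every 100 steps with the standard
two-replica acceptance, and an early stop after 10,000 steps without a
best-ever improvement. Energies are the objective (AN) or its negative
(EN) so all chains minimize. The best subset ever visited is returned, so
the result is never worse than the initial state. All budgets are exposed
in `OptimizerConfig`; the defaults solve every exhaustively checkable
instance (N ≤ 12) to optimality and dominate 1,000-subset random baselines
at N = 200–400. Greedy and uniform-random baselines are provided for
validation only.

## Build and consolidation

The six strategies pair distances with criteria: Gen(AN|EN) on Modified
Rogers, Phen(AN|EN) on Gower, GPm(AN|EN) on the blended distance. Each
method runs once with its own recorded seed (stored in the selection
metadata so any column can be regenerated independently). The consolidated
collection keeps accessions with ≥ min_votes = 2 votes; the vote threshold
is exposed. An UpSet-style intersection table (exclusive counts,
never-selected count, full pattern counts) summarizes overlap.

## Evaluation battery

Diversity statistics assume a single population per collection (each
collection is scored on its own), so the harmonic sample size ñ reduces to
the collection size. Per-locus `Fis = 1 − Ho/Hs` is averaged over loci
polymorphic within the collection; monomorphic loci are excluded from the
Fis summary and counted. Summary Fis is the mean of per-locus Fis, not
`1 − mean(Ho)/mean(Hs)` — the two differ and the per-locus convention is
the one consistent with collection-level reports of this kind. Allele
retention counts ≤2 alleles per biallelic locus.

Shannon–Weaver indices are normalized by ln of the *declared* class count
(absent classes enter with p = 0 under 0·log 0 := 0), so core and complete
indices are comparable; quantitative traits use six equal-width bins over
the complete collection's observed range, with out-of-range values clamped
to edge bins. Changes beyond ±10% are flagged.

The mean/variance comparison implements the ±5% mean and +50% variance
conventions as relative-difference flags, not hypothesis tests — no test
statistic is prescribed for them. Cohen's kappa on binary selection vectors
follows the original estimator, with identical vectors defined to return
exactly 1 even when chance agreement is 1 (both-empty selections). PCA
standardizes quantitative traits, one-hot encodes and centers qualitative
ones, and centers dosages for the genotype space; quadrant shares on
PC1×PC2 are computed by sign.

## Synthetic germplasm

The generator emulates the structure the analysis assumes:

- **Genotypes**: K subpopulations with Balding–Nichols allele frequencies
  (Beta around a U(maf_min, 0.5) ancestral frequency with an Fst-like
  differentiation parameter), Hardy–Weinberg draws, then heterozygote
  forcing with probability `h_excess` at polymorphic loci. Defaults
  N = 300, L = 500, K = 3, differentiation 0.05, maf_min 0.05,
  h_excess 0.3, missing rate 0.02. The forcing mechanism is the simplest
  that reproduces the negative within-collection Fis (≈ −0.25 at the
  defaults) typical of clonally maintained outcrossers; h_excess = 0.3
  was chosen from the closed-form relation
  Fis ≈ 1 − (h + (1−h)·2pq̄) / 2p′q′ to land near the −0.2 to −0.25 regime.
- **Quantitative trials**: an additive genetic value over 50 causal loci,
  standardized to σ²g, plus block, genotype×trial and residual noise at
  declared variances (defaults 1.0 / 0.25 / 0.25 / 1.0; 3 trials × 2
  blocks), matching the mixed model exactly.
- **Qualitative descriptors**: latent class per accession from a declared
  frequency vector, observed per year with a misclassification rate spread
  uniformly over the other classes (defaults 3 years, 5%). The default
  scenario includes one descriptor with a rare class at frequency 0.0188
  (~28 carriers in a 1,486-accession bank) to probe class-loss behavior.

Not emulated: linkage disequilibrium, pedigree/clonal genealogy, dominance
or epistasis, GBS read-level error, geographic structure, and trait
correlations. Tests passing on this generator therefore demonstrate
correctness of the algorithms under the assumed model, not robustness of
core selection to, e.g., LD-driven redundancy patterns in real panels.

All generators are bit-reproducible for a fixed seed.

## Problem sizes

The test suite and the acceptance script run at desk scale: N = 200–500
accessions and L = 100–500 SNPs, with 10–20 seed replicates for stochastic
checks and optimizer budgets of 5,000–20,000 steps per replica where many
runs are needed. These sizes were chosen so the full battery runs in
minutes while leaving every statistical check well-powered; all of them are
ordinary configuration, and the defaults scale to bank-sized inputs
(N ≈ 1,500, L ≈ 20,000) without code changes.

## Known limitations

- EM-REML can need hundreds of iterations near variance boundaries; the
  cap returns a flagged last iterate rather than failing.
- The blended-distance weight and the AN entry-inclusion convention are
  assumptions exposed as configuration (see above).
- `mean_impute` is plumbing to keep distance kernels defined; statistical
  imputation is expected upstream.
- Allele counting is strictly biallelic (≤2 per locus); multi-allelic
  records are skipped (or rejected) at VCF ingestion.
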