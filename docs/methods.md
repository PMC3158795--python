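# Methods

This note documents the models, the synthetic-data generator, the numeric
choices and the known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Quality control

Filters run in a fixed order: individuals below the 95% call rate first,
then — on the remaining samples — SNPs below the 98% call rate, SNPs with
Hardy–Weinberg goodness-of-fit p below 1e-10, and SNPs with minor allele
frequency below 2%. The order matters (a sample with sparse missingness
can rescue a SNP's call rate) and is fixed so reports are deterministic;
the filter is idempotent by construction. HWE uses the 1-df chi-square
goodness-of-fit test against expectations at the sample allele frequency;
at a 1e-10 cutoff the difference from an exact test is immaterial for
filtering. Monomorphic SNPs return p = 1 (they cannot violate HWE) and are
instead removed by the MAF filter.

Genotypes are stored as minor-allele counts; the minor allele is always
recomputed from sample frequency on load (ties at exactly 0.5 broken by
lexicographic allele order), so PLINK and text representations of the same
data load identically.

## Trait preparation

The pipeline is fixed: covariate adjustment → rank-based inverse-normal
transform → polygenic mixed model, each stage recording provenance.

* Covariate adjustment is OLS on intercept + age + sex + BMI (+ cohort
  indicator when a multi-cohort table is supplied). Rank-deficient designs
  raise an error naming the collinear column.
* The rank transform maps value i to `Φ⁻¹((rank_i − 0.5)/n)` with average
  ranks for ties. The offset and tie rule are stated here because they are
  the reproducibility-relevant choices; the transform is invariant to any
  strictly monotone re-expression of the input.
* The kinship matrix is the genomic relationship matrix from standardized
  genotype columns (missing entries mean-imputed per SNP), on the scale
  where full sibs average 0.5 and the diagonal is ~1. An IBS-style matrix
  is not offered; for correction purposes the two are equivalent and the
  GRM keeps a single contract.
* The polygenic model `y = μ + g + e`, `cov(g) = h²σ²K`, is fitted by
  REML. `K = U diag(d) Uᵀ` is decomposed once and cached; the likelihood
  is profiled over h² ∈ [0, 0.999] on a 0.01 grid followed by bounded
  golden-section refinement to 1e-6 (tests verify agreement with a dense
  0.001-grid search to 0.005). The association trait is the environmental
  residual `y − μ̂ − BLUP(g)`, computed in the eigenbasis as
  `(1−h²)/w_i · r_i` with `w_i = h²d_i + 1 − h²`. If all eigenvalues are
  equal (identity-like kinship) the variance split is unidentifiable: h²
  is reported as 0 with a flag and the residuals are the centered input.

The single-SNP scan regresses the residuals on the additive genotype code
and refers `n·r²` to a 1-df chi-square — a score-test approximation to a
family-based mixed-model score test. With the trait pre-corrected this is
slightly conservative (see Limitations). The genomic inflation factor λ is
the no-intercept regression slope of ordered observed on expected 1-df
chi-square quantiles.

## The pair engine

Each SNP pair is reduced to 3×3 joint-genotype tables of counts, trait
sums and trait sums of squares, obtained for a whole block of pairs from
three matrix products over 0/1 genotype-indicator matrices (missing
genotypes have all-zero indicators, which implements pair-wise
complete-case analysis for free). From the tables:

* `RSS_full` (Model 1) comes from the nine cell means;
* `RSS_main` (Model 2) adds the weighted residual of the cell means around
  the 5-parameter main-effects fit, solved in closed form from the 3×3
  summaries (a batched 5×5 normal-equation solve; the design is positive
  definite whenever all nine cells are occupied);
* `RSS_null` (Model 3) from the overall mean.

`F_pair = ((RSS_null − RSS_full)/8)/(RSS_full/(n−9))`, `F_int` analogous
with 4 df. Pairs with an empty joint class — including any SNP with fewer
than three observed genotype levels — are skipped, as are pairs with
`n ≤ 9` (no residual df). Degenerate cases: an (essentially) constant
trait returns p = 1; a perfect cell-mean fit returns the −log₁₀ cap.
−log₁₀ p is computed from the F log-survival function and capped at 320 to
avoid floating-point zeros. Results are independent of the block size
(asserted in tests), and the fast path is verified against naive factorial
least squares to 1e-8 relative error on 200 random fixtures.

Thresholds reproduce the printed Bonferroni convention: the pair count is
rounded to two significant figures and the SNP count to one (so 300,000
SNPs → 4.5e10 pairs → 11.95, and 7 focal SNPs → 7.62); exact-count
variants are also emitted and differ by <0.01 on the −log₁₀ scale. The
SNP–genome scan flags a pair as significant when both −log₁₀ p values
exceed the SNP–genome threshold.

The Kolmogorov–Smirnov calibration experiment samples a set of SNPs,
computes all their pair-wise −log₁₀ p_int with the observed trait and with
a seeded permutation of it (skip patterns depend only on genotypes and are
shared), and compares the two samples with the two-sample KS test. Note
the pair statistics share one trait vector and overlapping SNPs, so they
are mutually dependent: with few sampled SNPs the nominal KS p-value is
anti-conservative, and single runs fluctuate. Tests therefore assert the
median over a few seeded runs.

## Annotation, enrichment, replication, variance explained

* Annotation: nearest gene on the same chromosome by distance to the
  closer transcription boundary (0 inside the gene), within an inclusive
  20,000-bp window; exactly one gene per SNP; equidistant ties broken by
  lexicographically smaller symbol and flagged ambiguous. Linkage
  disequilibrium is deliberately ignored.
* Enrichment: plain upper-tail hypergeometric per GMT term against a fixed
  background, terms intersected with the background first, reported below
  p < 1e-3. No ontology-hierarchy propagation: term maps are taken as
  given. Cross-population comparison intersects the significant term lists
  and, per replicated term, the contributing genes.
* Replication: the exact discovery pair is tested first at nominal 0.05.
  If it is skipped or not significant, the fixed SNP is also tested
  against the other SNP's map-order neighbours up to two positions away on
  the same chromosome ("adjacent" is map order, not base pairs), and the
  threshold becomes 0.05 divided by the number of tests actually
  performed; the smallest interaction p is reported.
* Variance explained: the standardized trait (covariate-adjusted, unit
  variance) is fitted with the polygenic mixed model plus the pairs'
  joint-genotype factors as fixed effects; 1 minus the REML residual
  variance (genetic + environmental) is the fraction explained. A
  main-effects-only refit defines the marginal component; the interaction
  component is the difference. Pairs with an empty joint class are
  dropped; rank-deficient fixed-effect designs (pairs sharing a SNP) are
  handled through the SVD with the rank entering the REML df.

## The synthetic cohort generator

The generator produces what the analysis assumes, with defaults emulating
a small isolate study cohort: n = 1201, trait mean 5.32 / SD 1.42 mg/dL,
trait–BMI correlation ≈ 0.38, polygenic heritability 0.325.

* Genotypes are drawn per SNP from HWE at a MAF sampled from a configured
  range. Relatedness is modelled by non-overlapping sibships: two latent
  parents per family drawn from HWE, children by Mendelian transmission,
  giving realized genomic relationships of ~0.5 between sibs. A
  `sibship_fraction` controls how much of the cohort is in families.
* The covariate-adjusted part of the trait lives on a unit-variance scale:
  a polygenic value built from per-SNP infinitesimal effects on the
  simulated genotypes (so realized kinship and the generative model agree),
  scaled to sample variance exactly h²; planted two-locus effects; and
  Gaussian noise absorbing the remainder. Age (uniform 18–90), sex
  (Bernoulli ½) and BMI (normal 26, 4) effects are added on top — the BMI
  slope default yields the target trait–BMI correlation — and the total is
  affinely rescaled to the requested mean/SD.
* Planted effects are 3×3 joint-genotype matrices in adjusted-trait SD
  units. The pure-interaction constructor uses the additive-by-additive
  form `c(g₁−2p₁)(g₂−2p₂)`, double-centered against the HWE genotype
  frequencies: weighted (not plain) centering is what makes per-SNP
  additive regression slopes vanish, and the two coincide at MAF 0.5. A
  variant adds an additive marginal effect on the first SNP; under HWE the
  two components are orthogonal, so target variance fractions add.
* Missingness is applied to the observed matrix only; the trait is
  generated from the complete underlying genotypes.

Two generator defaults are deliberate emulation choices rather than
arbitrary: about 30% of individuals sit in full-sib pairs, and the default
panel is 6000 SNPs. Both were set so the pipeline reproduces the emulated
study's documented behaviour that the polygenic correction barely deflates
the association statistics (inflation factor ≈ 1): residual-based
(GRAMMAR-style) statistics deflate noticeably when the GRM is
rank-deficient (panel smaller than the sample) or when every individual is
closely related, neither of which holds in the real setting, where the
panel exceeds the sample size ~250-fold. At the chosen defaults λ ≈ 0.9 —
mildly conservative; the residual gap to 1 is the part of the
approximation desk-scale simulation cannot remove (see Limitations).

What the generator does not emulate: linkage disequilibrium (SNPs are
independent), X-chromosome inheritance, genotyping error, allele-frequency
drift between cohorts, and real pedigree depth beyond sibships. Passing
tests therefore demonstrate the statistical machinery — calibration under
the null, recovery of planted signal at the study's effect sizes — not
robustness to LD-induced redundancy or population stratification.

## Problem sizes used by tests and the acceptance script

Null calibration uses 300 SNPs × 600 samples (≈45k pairs); the recovery
scenario uses the full emulated cohort (n = 1201, 6000-SNP panel, planted
marginal 4.4% + interaction 3.4%, MAF 0.3) across 20 seeds; the KS
summary in the acceptance script is the median over five runs of 150
sampled SNPs each (single runs are heavy-tailed under the shared-trait
dependence described above); the skipped-pair accounting uses a 600-SNP
panel with MAF down to 2%. These sizes were chosen so the whole suite
runs in minutes while keeping every inference (KS, binomial type-I bands,
seed-averaged recovery) adequately powered.

## Limitations

* The single-SNP scan on pre-corrected residuals approximates the
  family-based score test; it is mildly conservative (λ slightly below 1)
  and the same shrinkage touches the pair tests. Planted interactions at
  the study's magnitude sit close to the 7.62 detection threshold, with
  seed-to-seed detection rates around 60–90% — mirroring the borderline
  significances the threshold was designed around.
* The F tests assume homoscedastic normal residuals; the rank transform
  enforces marginal normality but heavy joint-genotype sparsity (MGC of a
  few individuals) still makes single extreme cells influential. The skip
  rule removes only fully empty cells.
* Enrichment treats genes independently (no gene length or SNP-density
  correction) and the hypergeometric assumes an unstructured background.
* `variance_explained` attributes variance by model nesting; with pairs
  sharing SNPs the marginal/interaction split depends on that nesting
  convention.
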