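# Methods

This note documents the models, numerical choices and limitations behind
`raven`. Everything stated here is computed by the package's tests or
acceptance script; nothing is quoted from external results.

## Effect-variant calling

Scores are signed JSD values: the magnitude is the Jensen–Shannon
divergence between predicted chromatin-accessibility profiles for the
reference and alternate allele; the sign is the direction of the
predicted accessibility change (a convention this package fixes
explicitly, since a JSD by itself is unsigned). Scores exist only for
variants inside a cell type's accessibility peaks.

For each cell type the positive and negative tails are thresholded
independently on the ranked score curve. Both axes are normalized — rank
by `i/(n−1)`, score magnitude by min–max — and the inflection point is
the index maximizing the perpendicular distance `|x + y − 1|/√2` from
the chord joining the endpoints. Choices worth noting:

* **Both axes are normalized** before the distance computation. This
  makes the threshold invariant under positive affine rescaling of the
  score axis (tested property).
* **"Beyond" is strict** (`score > elbow`, `score < knee`); the
  threshold-rank variant itself is not an effect variant.
* **Ties** in the maximal distance break toward the larger magnitude,
  which yields the more conservative (smaller) effect set.
* Degenerate tails — fewer than three points, all equal, or exactly
  linear (all points on the chord) — raise typed errors; during
  classification such a tail simply produces no calls in that direction.

The rare-variant enrichment statistic is a two-sided Fisher exact test on
the 2×2 table (rare/common × top-|score|/rest), with the sample odds
ratio and a Woolf logit 95% CI (0.5 continuity correction when a cell is
zero). Rank-sum comparisons use exact enumeration when `n·m ≤ 100` and
there are no ties, otherwise the tie-corrected normal approximation.
Allelic imbalance at a het site is a two-sided exact binomial test of
the alternate read fraction.

## Regulatory-element → gene mapping

Tier 1 — **ABC**: `ABC(E,G) = A_E · C_{E,G} / Σ_e A_e · C_{e,G}` over
candidate peaks of the cell type whose midpoint lies within 5 Mb of the
gene's TSS; activity is the pseudobulk accessibility signal, contact the
normalized 3D contact frequency. Pairs without a measured contact fall
back to a distance power law `offset/(d + offset)` with a 5-kb offset
(configurable, on by default). Links at score ≥ 0.02 qualify; a peak
takes its maximum-score gene, ties broken by nearest TSS.

Tier 2 — **correlation links**: Pearson r between peak accessibility and
gene expression across matched samples (≥ 3), for pairs with TSS within
±250 kb of the peak midpoint; p-values from the t distribution on n−2
df, BH-adjusted across all tested pairs; the gate is signed r ≥ 0.4 and
FDR ≤ 0.01. A query peak without ABC links takes the gene of the
correlation-linked peak with the greatest physical overlap (intersection
length in bp), then the strongest r.

Tier 3 — **proximity**: nearest TSS if within 25 kb (distances are
measured |midpoint − TSS| on 0-based half-open BED coordinates);
otherwise the peak is unassigned and its variants are excluded
downstream.

Effect variants inherit their containing peak's assignment and collapse
to unique (gene, variant, cell type) triplets; peak-level rows can be
retained for peak-level testing units.

## Burden and specificity

Per (gene, cell type), the burden statistic is the number of unique
effect variants, reported alongside `count / n_peaks` (peaks mapped to
the gene in that cell type). The null reassigns every effect variant to
a peak of the cell type uniformly at random — preserving per-gene peak
counts — and recounts; the empirical p-value uses the add-one estimator
`(#{null ≥ obs} + 1)/(B + 1)`, which cannot return zero and is valid for
BH correction (applied within cell type, flag at FDR ≤ 0.1). A
peak-width-stratified reassignment is not implemented; the uniform
scheme is the documented default.

Specificity per gene uses the count vector `x` over the k evaluated cell
types (those with pseudobulk CPM ≥ 1 for the gene, inclusive):
top-share `max x_i / Σ x_i` and
`τ = (1/(k−1)) Σ (1 − x_i / max_j x_j)`. The null scatters the gene's
Σx variants uniformly over the k cell types (equivalently, shuffles
labels preserving the per-gene count), 10,000 permutations by default;
cutoffs are the 95th percentiles, exceedance is strict (conservative on
discrete nulls), and the gene is flagged specific when *either*
statistic exceeds its cutoff (the two flags are also available
separately). The proportion of specific genes is summarized with a
normal-approximation 95% binomial CI clamped to [0, 100].

## Rare-variant association (SKAT / burden / SKAT-O)

Testing units group the variants of all regulatory elements mapped to a
gene (or one peak) per cell type, after two filters: reference MAF
< 0.01, and |score| in the top quantile per cell type (default 1%, with
the quantile scope configurable; acceptance simulations use the
generator's tail fraction so the filter targets the planted outlier
component). Weights are `Beta(MAF; 1, 25) · |score|/max_unit|score|` —
the standard rare-variant Beta weight times a normalized impact term;
zero-MAF entries are floored at half the smallest nonzero MAF in the
reference table. The functional form is a documented choice (exponents
configurable), not a claim about any particular published weighting.

The null model is logistic IRLS (tolerance 1e−8, ≤ 50 iterations) on
intercept + sex + five genetic PCs, with typed errors for rank-deficient
designs and separation (diverging linear predictor or fitted
probabilities pinned at 0/1).

With residuals `r = y − μ̂`, `V = diag(μ̂(1−μ̂))` and
`P₀ = V − VX(XᵀVX)⁻¹XᵀV`:

* `Q_skat = rᵀ G W² Gᵀ r`, null distribution `Σ λ_k χ²₁` with λ the
  eigenvalues of `W Gᵀ P₀ G W`;
* `Q_burden = (Σ_j w_j g_jᵀ r)²`, a 1-df scaled χ² with scale
  `wᵀ(GᵀP₀G)w`;
* `Q_ρ = (1−ρ) Q_skat + ρ Q_burden` over the grid
  {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}.

The eigen computations factor through
`Z = V^{1/2}(GW − X(XᵀVX)⁻¹XᵀV GW)`, so `ZᵀZ = W Gᵀ P₀ G W` without any
n×n matrix. Missing dosages are mean-imputed per variant.

**Mixture tail probabilities.** `P(Σλχ²₁ ≥ q)` is computed by Ruben's
series of central χ² survival functions with `β = λ_min` (all series
coefficients non-negative; the residual coefficient mass bounds the
truncation error; tolerance 1e−12, ≤ 600 terms). Spectra too
ill-conditioned for the series fall back to numerical inversion of the
characteristic function (Imhof's integral, accuracy ~1e−7) and, as a
last resort, the Liu moment-matching approximation. Inputs are
normalized by the leading eigenvalue first, making the result exactly
invariant under joint rescaling of weights. Note that the
moment-matching approximation agrees with the exact value to ~1e−4 only
in the tail; at the distribution center its error is of order 1e−2 by
construction, so strict exact-vs-approximate agreement is only asserted
in the small-p regime.

**SKAT-O omnibus.** Per-ρ p-values come from the mixture method on the
ρ-kernel eigenvalues (ρ clamped at 0.999 for the Cholesky factor). The
omnibus p integrates the minimum-p statistic over the shared burden
component: `Q_ρ` decomposes into `(1−ρ)·κ + τ(ρ)·η₀` with η₀ a 1-df χ²;
conditional on η₀ = x the remaining part is a mixture whose survival is
evaluated by the (fast, vectorized) moment matching, with a variance
rescaling for the neglected cross term. The integral is computed on a
trapezoid grid after substituting `x = u²`, which removes the χ²₁
density singularity. The result is always capped at
`min_ρ p_ρ × |grid|`, so the Bonferroni bound holds by construction and
is also available alone (`bonferroni_only=True`).

**Small-sample caveat.** P-values are asymptotic; the moment-based
small-sample adjustment for binary phenotypes is deliberately not
implemented. At n ≈ 10–12 the asymptotic p can exceed the exhaustive
permutation p by several tenths at the distribution center (permutation
distributions are highly discrete there); in the tail (p ≲ 0.2) the two
agree to within ~0.1 on the tested fixtures, and the type-I error of
SKAT-O at n = 500 is calibrated (0.04–0.06 at α = 0.05 over 2,000
simulations).

λ_gc is `median(χ²(p))/0.4549364` and is reported as a diagnostic only;
no genomic-control correction is applied. Because λ is median-based, it
is only centered at 1 when the p-value distribution is smooth near 0.5:
with common variants the null λ sits within [0.9, 1.1] (tested), while
with very rare variants the discreteness of the kernel statistic shifts
the median and λ drifts by ±0.1–0.2 even under a perfectly null model —
which is precisely the behavior the diagnostic exists to surface. Multiple testing is two-tier
BH: within cell type, and pooled across all cell-type-specific tests.
Control matching samples exactly `ratio` controls per case within sex,
without replacement, with a shortfall error naming the deficient sex.
Replication lookup BH-corrects only over the searched discovery hits and
distinguishes "untested" from "not replicated".

## Differential expression

TMM: reference = sample whose 75th count percentile over library size is
closest to the mean; M/A values on genes nonzero in both; 30% trim on M
and 5% on A (rank-based, each side); factor = 2^(precision-weighted
mean M) with delta-method weights; factors rescaled to geometric mean 1
(asserted exactly in tests). A pure depth change yields unit factors; a
single outlier gene is trimmed away and only its small library-
composition effect remains.

The NB GLM uses a log link with offset `log(lib × TMM)`, fitted by
batched IRLS across genes (shared design, per-gene weights
`μ/(1+φμ)`, tiny ridge for stability). The LRT on a design column is
`2(ℓ_full − ℓ_reduced)` against χ²₁ at fixed dispersion, BH-adjusted;
non-converged genes are flagged and excluded from the FDR. At
φ → 0 the fit reproduces the closed-form Poisson deviance difference to
1e−3 on integer fixtures.

Dispersion: the common value maximizes the Cox–Reid adjusted profile
likelihood (−½ log det XᵀWX) on a 25-point log grid over
[1e−4, 4]; tagwise values shrink per-gene pseudo-likelihood moment
estimates toward the common value on the log scale (weight 0.5,
configurable). Recovery: Poisson data give < 0.05; φ = 0.4 data recover
within [0.2, 0.6] at 500 genes.

Covariate screening: PCA on log2-CPM of the 2,000 highest-variance
genes; a covariate enters the design when any of the top 5 PCs shows
|r| ≥ 0.4 with p ≤ 0.05 (inclusive; both thresholds configurable — the
laxer rule of screening on the p-value alone corresponds to r_min = 0).

The permutation DEG burden shuffles disease labels across samples
(covariates fixed), re-runs the differential test, and counts FDR < 0.05
genes; empirical p uses the add-one estimator and the fold enrichment is
observed over null mean. **Dispersions are held fixed across
permutations** (re-estimating per shuffle is ~two orders of magnitude
slower); this can make the null slightly anti-conservative and is the
package's documented trade-off. B defaults to 1,000 at desk scale and is
a parameter. The cross-region overlap statistic counts genes significant
in ≥ 2 regions against the per-permutation analog. Stage trajectories
code I/IIa/III/IV as 1–4, test the stage coefficient by LRT, and
classify significant genes from per-stage mean log2-CPM: non-decreasing
with ≥ 1 strict increase → monotonic increase; mirror for decrease;
otherwise "other".

## Familial segregation

Genotypes are dosages 0/1/2 with −1 as the missing code. QC masks a
genotype when GQ < 20, DP < 10, or (hets only) the alternate-read
fraction leaves [0.2, 0.8]; all bounds inclusive on the keep side.
Variants with post-masking call rate < 0.95 are dropped (0.95 retained).
QC is idempotent.

Dominant: every genotyped affected carries ≥ 1 alternate allele, no
genotyped unaffected carries any, and the maximum reference-population
AF ≤ 0.01. The "maximum credible population AF" construct is
approximated by the maximum AF across the supplied reference
populations. Missing genotypes neither satisfy nor violate carrier
requirements unless `strict` is set. Recessive: the homozygous branch
requires all affected hom-alt, no unaffected hom-alt, and a reference
homozygote count ≤ 1; the compound-het branch pairs variants within one
gene, each het in all affected, excluding pairs shown to be in cis by
parental transmission and flagging phase-unknown pairs rather than
dropping them. X-linked inheritance is not modeled; non-autosomal
variants pass through with a warning.

Candidates are intersected with per-cell-type peaks, kept when beyond
the cell type's effect thresholds, annotated with the peak's target
gene, and ranked by descending |score|.

## Synthetic cohort generator

No public generative model exists for the cohorts this package targets;
the generator's distributions are explicit stand-ins chosen to exercise
every pipeline contract. Defaults (all in `CohortConfig`):

* **Genome**: one 10-Mb chromosome; 60 genes; 240 peaks of 500 bp, most
  within 20 kb of a TSS, ~10% placed in a gene-free desert so their
  nearest TSS is > 25 kb (exercising the proximity drop rule).
* **Variants**: 4,000; two-thirds inside peaks; AF mixture with 90% rare
  (Beta(0.8, 3) scaled into (0, 0.01]) and 10% common (Beta(1.2, 3)
  scaled into (0.01, 0.5]); genotypes Binomial(2, AF) per sample
  (Hardy–Weinberg, no linkage). The true AF doubles as the
  reference-population lookup table.
* **Scores**: per cell type, only in-peak variants are scored; magnitude
  is an exponential bulk (scale 0.01) or, with probability 0.05, a
  shifted exponential tail (0.15 + Exp(0.05)); sign symmetric. At least
  one tail variant per scored cell type is guaranteed so planted truth
  always resolves.
* **Phenotype**: logit P(case) = β₀ + Σ β_g·carrier_g + 0.25·sex +
  0.1·ΣPC, with β₀ bisected so the mean case probability hits the
  configured fraction. Spiked genes (default one, β = 2) are chosen to
  maximize their rare tail variants under the same deterministic
  ABC+power-law assignment the pipeline reconstructs, so truth and
  analysis agree on gene identity; risk is carried by rare effect
  variants only.
* **Pseudobulk**: NB counts, dispersion 0.15, lognormal library sizes
  (~2×10⁵), 30 + 30 samples; planted DE genes (logFC 1 by default) and
  stage-monotone genes (per-stage log-step 0.5); disease samples draw a
  Lewy stage uniformly, controls sit at stage I.
* **Pedigree**: two founders (ungenotyped in the emitted pedigree — the
  affected-only family situation) and 3 affected + 1 unaffected
  children; gene-dropping per variant; the causal variant is the rare
  tail variant with the top score, planted het in the father and forced
  into all affected and out of unaffected siblings; GQ/DP/AD emitted
  with a configurable corruption rate (default 0).

Every generator is a pure function of (config, seed); per-stage salts
keep the streams independent.

**What passing tests do and do not show.** The generator has no linkage
disequilibrium, no population stratification beyond synthetic PCs, no
sequence context, one chromosome, and independent variants; power and
calibration results on it validate the statistical machinery and the
plumbing between stages, not performance on real cohorts with LD,
relatedness, or confounded covariates.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen as the package's
defaults: 2,000 null simulations for type-I calibration (n = 500, 20
variants), 100 pipeline replicates at n = 2,000 for power, 40 pedigree
seeds, 10,000 permutations for the burden and specificity fixtures, and
B = 200 for the DE label-permutation burden. All are parameters and
scale up linearly.
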