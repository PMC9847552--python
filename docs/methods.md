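# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the known limitations of `pleioscan`.

## Harmonization

Two summary-statistics tables are inner-joined on variant id. The second
trait's alleles are aligned to the first's: identical pairs pass through,
swapped pairs (a1↔a2) flip the sign of the second effect, strand flips are
resolved through base complements, and any other allele combination is
dropped. Palindromic variants (A/T, C/G) are dropped outright: without allele
frequencies the strand cannot be resolved, and a silently wrong orientation
would corrupt the concordance calls that the locus-direction analysis rests
on. Coordinates are GRCh37, 1-based; region masks are closed intervals with
containment `start ≤ pos ≤ end`.

When a variant's stored beta/se disagrees with its p-value by more than 10%
relative on the z-scale, the p-value is treated as authoritative and the
z-score is re-derived as `sign(beta)·Φ⁻¹(1 − p/2)`. Public summary files
frequently round betas to a few digits while keeping full-precision p-values,
and every downstream quantity except the concordance sign is computed from z
or p. Duplicate variant ids keep the record with the smallest standard error.
Effect sizes are assumed on the log-odds scale for both traits, but only the
sign enters concordance, so scale mismatches are tolerated.

## Genetic correlation

The estimator is a full-likelihood treatment of the standard polygenic
z-score model on a block-diagonal LD reference. Assumptions: standardized
genotypes; infinitesimal per-SNP causal variance `h_t²/m` (unconditionally
across the mixture); no sample overlap between the two GWAS; no confounding
inflation (intercepts fixed at one). Under these,

- `cov(z_t) = a_t R² + R` with `a_t = n_t h_t²/m`,
- `cov(z_1, z_2) = c R²` with `c = √(n_1 n_2) r_g √(h_1² h_2²)/m`.

The cross-covariance has no `+R` term precisely because the samples do not
overlap. Each block is eigendecomposed (`R = U Λ Uᵀ`, scores `w_t = Uᵀ z_t`),
which reduces the likelihood to independent 2×2 bivariate normals per
eigencomponent. Eigenvalues are floored at 1e-8 to guard rank-deficient
blocks. Masked (MHC/MAPT) variants are excluded before decomposition.

`(h_1², h_2², r_g)` is estimated by L-BFGS-B within bounds
`h² ∈ [1e-6, 1]`, `r_g ∈ [-1, 1]`, objective tolerance 1e-8, started from
LD-score-regression moment estimates (OLS of `z²` on the LD score for each
trait, of `z_1 z_2` for the cross term) plus two deterministic perturbed
restarts; the best converged optimum wins and a boundary optimum is flagged.
`r_g` is a direct parameter, so its standard error is read off the inverse of
the numerically differentiated observed information (central differences,
step 1e-4) and the p-value is the two-sided Wald test `2Φ(−|r_g|/se)`. A
likelihood-ratio alternative was considered and not implemented: the Wald
triple (estimate, se, P) matches how genetic correlations are conventionally
reported. If the covariance of an eigencomponent goes indefinite (only
possible outside the parameter bounds), the objective returns +inf rather
than raising, keeping line searches safe. When the LD score is constant
across variants (e.g. an identity reference), the moment regression is
degenerate and an intercept-free mean-based fallback
`h² = (mean(z²) − 1)·m/(n·mean(ℓ))` is used for initialization.

## Conditional and conjunctional FDR

The cFDR uses the pure empirical-cdf form with the null proportion set to 1,
which is conservative; no estimated-π₀ variant is provided. Counts are
accumulated over 100 LD-pruning iterations (greedy pass over a uniformly
random permutation, a variant retained iff its r² with every already-retained
variant is below 0.05), and summed across iterations before the ratio is
formed. Ratio-of-sums was chosen over mean-of-ratios because it is stable
when individual pruned subsets are small; each iteration k uses seed
`seed + k`, so the whole procedure is reproducible. Ties in p-values are
handled by using `≤` in all counts; no randomized tie-breaking is needed.
Values are capped at 1 and no cross-SNP monotonization is applied. When a
SNP's joint count is zero, its cFDR is set to 1 — the conservative choice —
which means a masked SNP more extreme in both traits than every retained
variant also reports 1 rather than an extrapolated value.

MHC and MAPT variants never enter the pruned subsets (their extended LD would
make pruning unreliable) but are still scored as queries against the unmasked
counts; this post-hoc evaluation gives every variant in the input a conjFDR.
The production computation aggregates per-variant integer retention weights
and counts tail/dominance sums with sorted prefix sums; it is exactly equal —
integer counts, then one multiplication — to the O(n²·K) double loop, and the
test suite asserts bitwise equality against an independently written double
loop on random universes.

Conditional Q–Q curves reuse the same pruned subsets. For each conditioning
threshold `t` in {1, 0.1, 0.01, 1e-3, 1e-4, 1e-5} (decades down to 1e-5, the
level at which conditioning saturates in this kind of analysis), the observed
`−log10 p` of the primary trait is evaluated at 200 equally spaced quantile
levels within the stratum `p_secondary ≤ t` and averaged over iterations; the
expected axis is `−log10` of the matching uniform quantiles. A threshold whose
stratum is empty in every iteration is reported absent rather than as a
degenerate curve.

## Loci and direction

Clumping follows the FUMA default procedure with its documented defaults
(r² ≥ 0.6 to join a clump, r² < 0.1 between lead SNPs, 250 kb interval
merging), applied to pleiotropic SNPs only: locus intervals are spanned by
conjFDR-significant variants, not by sub-threshold candidates. Greedy
selection is ordered by (conjFDR, p1·p2, position), which makes the output
invariant to input row order. Every locus overlapping the MHC interval is
merged into a single locus flagged `is_mhc` (overlap suffices; a straddling
locus is absorbed).

A member SNP is concordant when `β₁·β₂ > 0`. The three-bin direction rule —
≥ 90% concordant members → concordant, ≤ 10% → antagonistic, else ambiguous —
is evaluated in exact integer arithmetic (`10·n_c ≥ 9·n_t`, `10·n_c ≤ n_t`),
so boundary ratios classify deterministically with no floating-point edge
cases: exactly 10% is antagonistic and exactly 90% concordant.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets: two
non-overlapping case–control GWAS on a shared panel. Per SNP a mixture
component is drawn — null, trait-1-only, trait-2-only, shared — and causal
effects are zero-mean normal with variance `h_t²/(m·π_t)` (`π_t` the trait's
total causal probability), so `E[Σβ²] = h²` exactly and the likelihood above
is correctly specified under the simulator. Shared-component pairs are
bivariate normal with correlation `rho_shared`; antagonistic pleiotropy is
obtained with `rho_shared < 0`. The true genome-wide effect correlation has
the closed form `π₁₁·ρ / √(π_c1·π_c2)`.

LD is AR(1) within blocks (`r(i,j) = ρ^|i−j|`), chosen for closed-form
positive definiteness and realistic decay; blocks are placed on chromosomes
1–22 round-robin with 10 kb SNP spacing. Summary statistics follow
`z_t = √n_t·R·β_t + ε_t`, `ε_t ~ MVN(0, R)` independently per trait (no
sample overlap), with `β̂ = z/√n`, `se = 1/√n`, `p = 2Φ(−|z|)`.

Defaults (m = 20,000; blocks of 50 at ρ = 0.8; n = 50,000 per trait;
h² = 0.4; 5% of SNPs causal per trait of which 2 points shared at
`rho_shared = 0.9`, true r_g = 0.36) describe a well-powered pair with
moderate polygenicity. The real analyses this emulates have weaker
correlation (r_g ≈ 0.06) and larger panels; the defaults trade that scale for
test power at desk size.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: allele-frequency variation (genotypes are
implicitly standardized; only signs, z-scores and p-values feed the
pipeline), case–control liability-threshold ascertainment, sample overlap,
population stratification or other confounding (no intercept inflation),
realistic LD-block size heterogeneity, and indels/multi-allelics.

## Problem sizes used in validation

The automated validation suite runs the conservativeness check (no truly
shared SNPs) at m = 20,000 over 20 seeds with the full 100 pruning
iterations; conditional Q–Q enrichment at m = 20,000 with 100 iterations;
and genetic-correlation recovery at m = 8,000, n = 50,000 over 10 seeds,
with null calibration over 50 replicates at the same size. Oracle-equality
and invariant checks use random universes of 130–500 variants where the
O(n²·K) reference is cheap.

## Known limitations

- The cFDR is conservative by construction (π₀ = 1, B = 0 → 1); its selected
  fraction under the null is controlled but its values are upward-biased.
- Intercepts of the likelihood are fixed at one; confounded or
  sample-overlapping GWAS will bias both h² and r_g.
- The post-hoc conjFDR for masked regions borrows the unmasked counts; it is
  an operational convention, not an LD-aware imputation.
- Locus intervals are defined by pleiotropic SNPs only, so they are narrower
  than definitions that extend to sub-threshold candidate SNPs.
- Gene annotation, eQTL mapping and pathway analysis are out of scope; loci
  are reported by interval and lead SNP.
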