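# Methods

## Model

The marginal density of SNP z-scores is a two-component Gaussian mixture

    f(z) = π₀ φ(z; 0, σ₀² + σ₁²) + π₁ φ(z; 0, σ₀² + σ₁² + σ₂²),

with σ₁² = σₐ²·N·H and σ₂² = σᵦ²·N·H.  The generative reading is
z = δ + ε with ε ~ N(0, σ₀²) independent of δ, δ = √(N·H)·(a + b·1[sparse]),
a ~ N(0, σₐ²), b ~ N(0, σᵦ²), a ⟂ b, and Pr(sparse) = π₁.  Assumptions
worth making explicit:

- per-allele variances σₐ², σᵦ² are independent of allele frequency
  (effects enter only through N·H);
- z-scores are treated as independent after LD pruning — residual LD is
  absorbed qualitatively, not modelled;
- σ₀² is a free parameter (≥ 1 under substructure/genomic inflation), so
  no genomic-control correction is applied to input z-scores;
- effective sample size: case-control substudies use
  N_eff = 2/(1/N_cases + 1/N_controls) (so a balanced study of N subjects
  has N_eff = N/2); quantitative traits use N_eff = N.

The posterior of δ given z is again a two-arm mixture with weights
(1 − tdr, tdr), arm means μ_u = z·σ₁²/(σ₀²+σ₁²),
μ_s = z·(σ₁²+σ₂²)/(σ₀²+σ₁²+σ₂²) and variances σ_u² = σ₀²σ₁²/(σ₀²+σ₁²),
σ_s² = σ₀²(σ₁²+σ₂²)/(σ₀²+σ₁²+σ₂²).  Replication-sample predictions
rescale the arms by √(N_r/N_d) and re-add σ₀² of noise; multistage
(combined-dataset) predictions meta-combine stages with weights
w = √(N/(N_d+N_r)), which keeps the combined score on the mixture's
√N scale (w_d² + w_r² = 1).

## Numerical choices

- tdr is computed in log space (a logistic of the difference of arm
  log-densities); the naive ratio underflows beyond |z| ≈ 8.
- The one-tailed convention is used throughout: z_t = Φ⁻¹(p_t) < 0
  (z_t = −5.33 for p_t = 5×10⁻⁸, not the two-tailed −5.45).  Replication
  means "same sign as the discovery score and one-tailed p below p_t";
  the rate folds the arm means to −|m| exactly as the closed form
  requires.  QQ curves use two-tailed p-values.
- The overestimation factor z²/E(δ²|z) is a domain error at z = 0 rather
  than a silent infinity.
- Heterozygosity is clipped to [1e−12, 0.5] inside variance scaling;
  monomorphic SNPs are expected to be removed by QC (MAF > 0.005).
- For optimization the variances are transformed to log scale and π₁ to
  logit scale, making the Nelder–Mead search unconstrained while the
  public types carry natural-scale values.

## Empirical estimation pipeline

Substudies are split into complementary discovery/replication sets at
target N_eff fractions 0.1–0.9.  Split construction is randomized greedy:
shuffle studies, add to the discovery side until the target share is
first met or exceeded, accept if the achieved share is within ±25%
relative of the target, else redraw (the tolerance is a design choice;
any "approximately the target fraction" rule gives equivalent fits since
model curves use the achieved N_d, N_r, not the target).

Per realization, SNPs are randomly LD-pruned at r² ≥ 0.8 by a
random-order greedy maximal-independent-set pass over the strong-LD
graph; the retained representative of each LD block is therefore random
and independent of z, deliberately avoiding winner's curse.  The pruning
is re-randomized per repetition.

Per-side z-scores are meta-analyzed with sample-size weights
(z = Σ√N_i z_i / √ΣN_i over studies with data), which preserves the √N
scaling of δ so combined scores follow the mixture at N = ΣN_i.
Discovery scores are binned into 200 half-open bins on [−6, 6] (last bin
closed; |z_d| beyond the range excluded), recording per bin the count,
mean replication z, mean squared replication z, replication fraction,
and mean heterozygosity.

## Fitting

The cost is the count-weighted sum of squared differences between the
empirical per-bin replication mean/second moment and the model's
E(z_r|z_d) and E(z_r²|z_d), summed over fractions, repetitions, and
bins; both moment terms are needed (the mean alone leaves the variance
parameters poorly determined).  Model curves are evaluated at bin
centers using the count-weighted mean H of the SNPs in the bin — the
cheapest faithful resolution of per-SNP versus bin-level heterozygosity,
defensible because predictions vary only weakly with H within a bin.
Minimization is Nelder–Mead (relative cost tolerance 1e−6, ≤ 2000
evaluations per start, 5 starts by default: the nominal start
π₁ = 0.01, σ₀² = 1, σₐ² = 1e−5, σᵦ² = 1e−4 — order-of-magnitude neutral
between phenotypes of high and low polygenicity — plus seeded jittered
restarts on the internal scale).

Confidence intervals are a parametric bootstrap: regenerate cohorts from
the fitted parameters at matching scale, refit each starting from the
fit, take 2.5/97.5 percentiles on the internal log/logit scale, and map
back (hence asymmetric natural-scale intervals).  This is a declared
substitute for closed-form error propagation, labelled as such in the
fit report; with fewer than 20 replicates the percentiles are noisy, so
the half-widths are inflated 1.5× and a warning is issued, and the
interval is always clipped to contain the point estimate.

When σᵦ² = 0 the two arms coincide and the model is degenerate in π₁;
the fit then reports essentially arbitrary π₁ with a flat cost in that
direction.  This degeneracy is asserted, not hidden, by the test suite.

## Synthetic data

The generator draws MAF ~ Uniform(0.005, 0.5) by default (the MAF law of
real imputed panels is not modelled; it is configurable), shared
per-SNP (class, a, b) across substudies, and independent ε per substudy.
Substudy layouts use lognormal size unevenness (σ = 0.6 on the log
scale) normalized to an exact total N_eff, emulating meta-analyses of
many unequal cohorts.  Optional LD blocks attach tag SNPs to a causal
member: a tag with signed attenuation r carries r·δ and noise correlated
at r with the causal member's, so the implied pairwise r² table is
consistent with the attenuations and total-LD (TLD) filtering
experiments can be run end to end.  No haplotype structure, population
stratification, or case-control liability model is simulated — passing
tests therefore demonstrate internal consistency of the method under its
own generative assumptions, not robustness to real-data LD or
ascertainment effects.

## Projection

S(N; z_t) — the fraction of the additive tagged variance carried by
sparse SNPs reaching significance — is simulated directly: sparse SNPs
draw δ_c ~ N(0, (σₐ²+σᵦ²)·N·H̄) and ε ~ N(0, σ₀²), and S is the ratio of
Σδ_c² over significant SNPs to the total, with numerator and denominator
averaged over repetitions (default 20 repetitions of 10⁵ SNPs; ubiquitous
draws for the non-sparse class never enter the ratio).  The mean
heterozygosity H̄ must be supplied (or computed from data); S depends on
the signal-to-noise ratio (σₐ²+σᵦ²)·N·H̄/σ₀², so curves for different H̄
collapse when plotted against that quantity.  Sample sizes reaching a
target S (default 0.90 for "approaching full explanation" — a package
choice, configurable) are read off a monotone-smoothed log-spaced curve.

## Problem sizes

Validation experiments run at desk scale: 3×10⁵ independent SNPs, nine
discovery fractions × 10 repetitions, 10⁶-draw Monte-Carlo oracles.
These sizes give parameter-recovery precision of roughly 0.1% on σ₀²,
a few percent on σₐ² and σᵦ², and ~15% on π₁ at the high-polygenicity
configuration — comfortably inside the empirical sampling variability a
real ~10⁶-SNP meta-analysis would exhibit.

## Known limitations

- Heterozygosity-dependent per-allele variances are out of scope.
- LD is generated only at the block-attenuation level needed for the
  TLD experiments; no realistic LD panels.
- The liability-scale conversion of S and case-control ascertainment
  corrections are not implemented.
- π₁ is weakly identified at very low polygenicity (its interval spans
  an order of magnitude even at large SNP counts); the product π₁σᵦ² is
  much better determined than either factor.
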