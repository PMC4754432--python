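# gwasmix

Gaussian mixture modelling of GWAS summary statistics: polygenicity
estimation, winner's-curse-corrected effect sizes, replication
probabilities for split and multistage designs, and projections of the
chip heritability explained by genome-wide-significant SNPs.

## The model

A genome-wide association study reports, for each SNP, a Wald statistic
z = β̂/se(β̂).  `gwasmix` models the marginal distribution of these
z-scores as a four-parameter, two-component Gaussian mixture:

    f(z) = π₀ φ(z; 0, σ₀² + σ₁²) + π₁ φ(z; 0, σ₀² + σ₁² + σ₂²)

with z = δ + ε, where ε ~ N(0, σ₀²) is the non-replicating noise
component (σ₀² can exceed 1 under population substructure) and δ is the
replicating genetic effect, which scales as √(N·H) in the effective
sample size N and SNP heterozygosity H = 2p(1−p):

- σ₁² = σₐ²·N·H — variance of *ubiquitous* small effects carried by
  essentially all SNPs (weak LD with causal variants);
- σ₂² = σᵦ²·N·H — additional variance of *sparse* large effects carried
  by a fraction π₁ of SNPs (strong LD with causal variants).

π₁ is the **polygenicity index**.  The four parameters are
(π₁, σ₀², σₐ², σᵦ²).  All quantities of practical interest follow in
closed form: the local true discovery rate tdr(z) = Pr(sparse | z), the
posterior of δ given z (a two-arm Gaussian mixture, giving shrunken
"adjusted" effect sizes E(δ|z) and E(δ²|z)), the predicted replication
z-score distribution for an independent sample of size N_r, replication
rates R(z_d; z_t), and combined-dataset (multistage) significance
probabilities.

Parameters are estimated without genotype data: the available substudies
are repeatedly divided into complementary discovery/replication sets at
nine effective-sample-size fractions, SNPs are randomly LD-pruned
(r² ≥ 0.8), discovery z-scores are binned (200 bins on [−6, 6]), and the
per-bin replication mean and second moment are matched to the model's
predictions by Nelder–Mead least squares.

## Worked example

Generate a synthetic meta-analyzed GWAS (3×10⁵ SNPs, 20 substudies of
uneven size totalling N_eff = 38,163) from a known parameter set, run the
full split/bin pipeline, and refit the parameters:

```python
import gwasmix as g
from gwasmix import fitting

params = g.ModelParams.from_sigmas(0.037, 1.014, 0.0057, 0.020)
studies = g.make_studies(20, 38163, seed=1)
cohort = g.generate_cohort(params, studies, m_snps=300_000, seed=1)
realizations = g.realized_curves(cohort.table, studies, n_reps=10, seed=1)
result = fitting.fit(realizations, seed=1)
print(result.params.as_sigma_tuple())
```

This prints (values regenerated by the code above):

```
fitted: pi1=0.0320  sigma0=1.0133  sigma_a=0.00575  sigma_b=0.0204
```

i.e. the pipeline recovers the generating values (0.037, 1.014, 0.0057,
0.020) — about 3% of SNPs carry sparse effects.  The fitted model then
answers the questions a study designer cares about:

```python
z_d, n_d, n_r, het = 5.5, 19081, 19082, 0.25
g.expected_replication_z(z_d, n_d, n_r, result.params, het)   # 3.67
g.replication_rate(z_d, n_d, n_r, result.params, het,
                   g.p_to_z_one_tailed(0.05))                  # 0.931
g.overestimation_factor(5.33, result.params,
                        g.SnpContext(n_eff=25000, het=0.25))   # 1.81
g.simulate_S(result.params, 38163, -5.33, 0.25,
             m_snps=300_000, reps=20, rng=1)                   # (0.127, 0.002)
```

A SNP observed at z_d = 5.5 in a split-half discovery sample is expected
to replicate at only z_r ≈ 3.7 (winner's curse), yet replicates at
p < 0.05 with probability 0.93; a naive β̂²-based variance estimate at
the significance threshold overstates the SNP's contribution 1.8-fold;
and genome-wide-significant sparse SNPs currently capture ≈ 13% of the
additive tagged (chip-heritability) variance at this sample size.

The same operations are exposed as a CLI (`gwasmix simulate | prune |
split | curves | fit | predict | project | qq`); see `gwasmix --help`.

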