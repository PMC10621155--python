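# Methods

`hoofgen` implements a multi-country quantitative-genetic analysis of
categorical hoof-conformation scores (foot angle, FA; claw set, CS) in two
linked beef-cattle populations, together with a synthetic-data generator
that reproduces the statistical structure such an analysis assumes. This
note documents the models, the generator, the numerical choices and the
limits of what the test suite demonstrates.

## The model family

Every analysis is a linear multi-trait repeatability animal model

    y = X b + Z a + W pe + e

* `y` — one row per score record. Scores on the 5–9 scale are analysed as
  linear (Gaussian) responses; no threshold model is fitted.
* `b` — fixed effects: contemporary-group (CG) classes per response plus a
  linear age covariate per response. In joint-country (JC) models the age
  slope is nested within country, because the two recording systems differ
  in age-at-scoring profiles.
* `a ~ N(0, Σ ⊗ K)` — additive genetic effects; `K` is the pedigree
  relationship matrix `A` or, in single-step analyses, the combined matrix
  `H`.
* `pe ~ N(0, Q ⊗ I)` — permanent-environment effects absorbing
  between-record, non-genetic animal variance.
* `e` — residuals with event-wise covariance `R` (both traits scored at a
  visit share a residual draw).

Scenario families re-map records onto responses:

| family | responses | Σ | Q, R |
|---|---|---|---|
| WC (within-country) | FA, CS of one country | 2×2 full | 2×2 full |
| MC (multi-country)  | FA_US, CS_US, FA_AU, CS_AU | 4×4 full | block-diagonal per country; cross-country entries are structural zeros |
| JC (joint countries) | FA, CS pooled over countries | 2×2 full | 2×2 full |
| AC (across-country) | MC structure; the target country's phenotypes are masked in the training (partial) data | | |

Single-trait (`-ST`) variants keep one trait per country slot. The
cross-country genetic correlations of the MC model quantify
genotype-by-environment interaction between the two recording systems.

## Variance-component estimation

REML is computed on the dense phenotype covariance
`V = Σ∘A_rec + Q∘(same animal) + R∘(same event)` over the recorded
animals (the exact marginal likelihood of the mixed model; at desk scale
this is much cheaper than repeated sparse-inverse trace computations).
The optimiser is average-information (AI) Newton with:

* **Cholesky parameterisation** of each free covariance block, so
  estimates are positive semidefinite by construction. Structural zeros
  (MC cross-country blocks of `Q` and `R`) are excluded from the
  parameter vector and never updated.
* Exact first derivatives and the exact AI matrix, assembled from the
  projection matrix `P`.
* **Levenberg–Marquardt damping**: when a proposed step fails to improve
  the restricted likelihood (typical near a singular block), the damping
  is raised tenfold and the step recomputed; if ten attempts fail, one
  closed-form **EM step** is taken (monotone in the likelihood).
* A floor of 1e-3 on Cholesky diagonals (standardised scale, i.e. a
  variance floor of 1e-6): a component heading for zero pins there
  instead of crawling asymptotically. A warning reports pinned variances.
* Convergence when the largest relative parameter change falls below
  `tol` (default 1e-8) or the likelihood gain drops below 1e-8. Responses
  are standardised to unit variance during the fit and components
  rescaled on output.

`method="em"` runs pure EM-REML (used in tests for the monotonicity
property). Standard errors come from the inverse AI matrix at the
optimum; derived parameters (h² = σ²a/(σ²a+σ²pe+σ²e),
repeatability = (σ²a+σ²pe)/total, genetic correlations) get delta-method
standard errors with a numerically differentiated Jacobian.

Prediction uses Henderson's mixed-model equations with sparse `A⁻¹`
(Henderson's rules with inbreeding) or `H⁻¹ = A⁻¹ + [0 0; 0 Gb⁻¹ −
A22⁻¹]`, solved directly (SuperLU; factorisation retained for
prediction-error-variance queries) or by Jacobi-preconditioned conjugate
gradients (`tol` 1e-12). Theoretical accuracies use exact PEVs,
`r = sqrt(1 − PEV/((1+F)σ²a))` — no large-scale approximation.

## Genomic machinery

* `G` is VanRaden method 1: `Z Z' / (2 Σ p(1−p))`, frequencies observed,
  missing dosages mean-imputed at `2p`.
* Blending `G_b = 0.90 G + 0.10 A22` (defaults as in routine use).
* APY inverse: seeded random core unless ids are given; non-core
  conditional variances are computed exactly per animal. With the core
  equal to the whole set the result is the direct inverse.
* LD: with simulated data true phase is retained, so `r` is the
  haplotype-level allelic correlation (signed LD = r, carrying the sign
  of `D = f(AB) − f(A)f(B)`); for unphased dosage input a composite-`r`
  fallback is used and labelled. Distance bins are half-open 100-kbp
  intervals. Phase consistency between populations is the per-bin Pearson
  correlation of per-pair signed LD over SNP pairs present in both (bins
  with fewer than 3 shared pairs are reported missing); a
  `binned-curve` mode correlating the two binned mean curves is provided
  as an alternative reading.
* PCA of `G` is an exact symmetric eigendecomposition (% variance =
  eigenvalue / trace).
* LD pruning: sliding 10-SNP windows, step 1; in each window any pair
  with r² > 0.20 loses the lower-MAF SNP (tie: the later position),
  rescanning until stable.

## ssGWAS

Two-stage, as in routine pipelines: variance components first, then GEBVs
from the MME, then SNP effects back-solved with equal weights,
`u = (1/k) Z' G_b⁻¹ â_g`. Sampling variances propagate the prediction
error covariance `C` of the genotyped animals' additive effects:
`Var(u_j) = z_j' G_b⁻¹(σ²_a G_b − C)G_b⁻¹ z_j / k²`, with
`p = 2(1 − Φ(|u|/sd))`. SNPs with non-positive variance are flagged with
p = 1. Significance labels use the fixed thresholds 1e-6 (strong) and
1e-4 (moderate) exactly as printed, not recomputed from the SNP count.
Candidate windows span ±100 kb around significant SNPs, intersected
inclusively with a user-supplied gene table (1-based inclusive
coordinates). Using the data-estimated σ²_a (not an external value) is
what keeps the null test statistic calibrated replicate by replicate.

## The synthetic-data generator

The generator emulates two country populations bred from one founder
pool:

* **Founder haplotypes** are thresholded from a latent Gaussian that
  mixes two autoregressive scales: a short-range component
  (`ld_strength`, default 2×10⁵ bp) and a long-range component (scale
  2×10⁷ bp, weight 0.15–0.40) representing the heavy tail of LD that a
  finite, recently expanded ancestral population carries across
  chromosome arms. The short-range scale is calibrated so the 0–100 kb
  bin averages r² ≈ 0.23, matching the observed adjacent-SNP LD in the
  populations being emulated.
* **Pedigree**: per country and generation, offspring draw sires from a
  domestic pool or, with a per-country probability (default 0.27 US /
  0.13 AU, the observed phenotyped-animal shared-sire fractions), from a
  shared pool used by both countries. Dams are domestic, with a capped
  number of progeny; an optional shared-dam stream emulates
  embryo-transfer exchange. `single_population` draws all sires from one
  joint pool (the JC truth).
* **Genotypes** by gene dropping with Poisson(`morgans_per_chrom`)
  crossovers; an unknown parent's gamete is drawn from founder allele
  frequencies.
* **True values**: pedigree mode samples `a_i = 0.5(a_s+a_d) + m_i` with
  Mendelian variance `0.5(1−(F_s+F_d)/2)Σ` (Meuwissen–Luo inbreeding);
  genomic mode assigns multivariate effects to QTL so `Var(a) = Σ` in
  expectation and sets `a = Zβ` exactly.
* **Phenotypes**: latent record = CG effect + age slope × age + a + pe +
  e; 10% of animals are scored twice (new residual and age, same pe),
  giving the observed 1.1 records per animal. Thresholds cut the latent
  scale into scores 5–9 (the AU preset's cut points make its
  distribution right-skewed, the US preset's more symmetric); with
  thresholds disabled the latent value is returned directly.

Per-trait latent variance is normalised to ≈1; only the ratios are
contractual. CG effect standard deviation (0.3) and age slopes
(0.001–0.002 score units/day) are set near the published fixed-effect
coefficients but are not contractual.

**Presets.** The named presets encode study conditions whose true
variance ratios equal the published estimates: `paper-wc-us`
(h² 0.22/0.21, rep 0.32/0.30, r_g 0.50), `paper-wc-au` (0.24/0.26,
0.30/0.35, 0.46), `paper-mc` (cross-country r_g 0.61 FA / 0.76 CS),
`paper-mc-genomic` (genomic truth, 0.76/0.78), `paper-jc` (one
population recorded in two countries, h² 0.24/0.25) and
`paper-popstruct` (two populations split from one founder pool three
generations back with heavy ongoing germplasm exchange — 90% shared-sire
usage plus a 30% shared-dam stream standing in for the cumulative
multi-generation gene flow that links the real populations). Quantities
the sources do not pin down were chosen once as realistic defaults and
are non-contractual: within-country pe correlation 0.30, residual
correlation 0.20, additive cross-country cross-trait correlation 0.40.

## Problem sizes and what the tests show

All recovery experiments run at desk scale: 1,500 phenotyped
animals/country over three generations for within-country fits,
600/country for multi-country fits, 1,200–2,000 SNPs on 1–3
chromosomes, 5–8 seeded replicates per condition. These sizes keep the
full reproduction script and test suite in the tens of minutes on one
CPU and were chosen deliberately:

* Variance-ratio REML estimates (h², repeatability, r_g) pick up
  finite-sample biases of a few hundredths below ~1,200–1,500
  phenotyped animals (an interaction between the weakly identified
  permanent-environment block — only 10% of animals have repeat records
  — and its PSD boundary). We verified with oracle draws from the
  model's own covariance that the engine is exactly consistent, mapped
  the calibration against data size and pedigree depth over 20-replicate
  batches, and set the preset scale at the smallest design where the
  estimates are unbiased within ±0.02.
* The cross-country genetic correlations are intrinsically imprecise at
  desk scale: with the shared-sire fractions fixed at the observed
  27%/13%, the information is bounded by the shared sires' progeny
  cross-products, giving a per-replicate sampling SD near 0.4 at
  600 animals/country however the shared progeny are arranged. The
  multi-country presets therefore include a common pre-split breeding
  generation (unrecorded ancestry, consistent with the much higher
  pedigree-wide sharing of the real populations), which removes the
  small-sample attenuation, and the reproduction script averages eight
  replicates. The reported means are unbiased but carry standard errors
  of roughly 0.15.

The contracts are on replicate means within two empirical standard
errors — they demonstrate that the estimators are unbiased for the
generating parameters and that the machinery is internally consistent,
not that a desk-scale dataset measures these parameters precisely.
Passing tests on synthetic data say nothing about model adequacy for
real foot scores: the generator has no genotyping error, no selection,
no recorder/management confounding beyond random CG effects, a single
global age distribution per country, and an idealised two-scale LD
process.

## Known limitations

* The repeatability structure is weakly identified at 1.1
  records/animal; pe components sit at the PSD boundary in a noticeable
  fraction of desk-scale replicates (handled by the boundary pinning,
  and visible as across-replicate spread in h² splits).
* Dense-`V` REML scales as O(n³) in the number of records; it is a
  desk-scale engine, not a million-record one (that is what
  MME-iteration packages are for).
* `A22⁻¹` and APY core inversion are direct dense inverses; no
  Colleau-style indirect products.
* The AC scenario's third population is a minimal stand-in: target-only
  animals sired from the shared pool with unknown dams.
* Unknown-parent groups and meta-founders are not modelled.
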