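# Methods

`kernelgp` implements grain-yield (GY) prediction for a multi-environment
spring-wheat panel with three sources of similarity between entities, all used
as covariance (kernel) structures of random effects in linear mixed models:

* **G** — genomic relationship among genotypes, `G = W W' / n_g`, where `W` is
  the column-standardized matrix of quality-checked biallelic SNP calls (coded
  0/2, heterozygotes treated as missing) and `n_g` the number of genotypes.
* **K_E** — environmental covariance among trials, `K_E = P P' / n_e`, where
  `P` stacks the per-environment genotype BLUE vectors (environments as rows,
  columns standardized per genotype over environments).
* **K_M** — multispectral relationship among the genotypes of one environment
  and camera, `K_M = C C' / n_g`, where `C` holds the per-genotype BLUEs of
  each raw reflectance band at each flight date (columns standardized).
  Band, date and RGB subsets of the columns give the single-band, single-date
  and simulated-RGB-camera variants; K_M is never pooled across environments.

Prediction models are `y = μ1 + Σ_t u_t + e`, with `u_t ~ N(0, K_t σ²_t)` over
one to three of {genotype×G, genotype×K_M, environment×K_E} and `e ~ N(0, Iσ²)`.

## REML engine

One engine serves both the plot-level trial models and the kernel models.
Every random term enters in loading form `F_t` with `Z_t K_t Z_t' = F_t F_t'`
(indicator matrices for iid design factors; `Z_t L_t` with `K = L L'` by
eigendecomposition, dropping modes below 1e-10 of the top eigenvalue, for
kernels).  The restricted likelihood is profiled over β and the residual
variance and maximized over the variance ratios `γ_t = σ²_t/σ²` with the
Woodbury identity, so an evaluation costs O(q³) in the total number of loading
columns rather than O(n³) in records.

* one ratio: grid scan (step 1 on log γ, with γ=0 as an explicit candidate)
  followed by bounded Brent refinement;
* several ratios: iterated coordinate descent (same 1-D search per
  coordinate, up to six sweeps) then Nelder–Mead polish from the
  coordinate-descent point and from an equal-ratio start, keeping the better.

Ratios are searched on log γ ∈ [−12, 12].  Beyond e±12 the restricted
likelihood is flat to working precision while the profiled quadratic form
suffers catastrophic cancellation, so the bound doubles as a numerical guard;
variances at the bound behave as boundary (0 or "all-kernel") fits.  A fit is
declared converged when a final coordinate-refinement pass improves the
criterion by less than 1e-6.  A response explained exactly by the fixed
effects short-circuits to the OLS solution with all variances zero.

BLUPs are computed for *every* id carried by a kernel, observed or not, by
keeping their loading rows in the system (equivalent to joint-normal
conditioning through the kernel cross-covariance); this one code path serves
both cross-validation scenarios.  A dense-factorization restricted
log-likelihood (`loglik_oracle`) and dense conditional-mean predictions are
kept as independent oracles in the test-suite; the two routes agree to 1e-6
on random instances.

## Trial models and BLUEs

Adjusted genotype means treat genotype as fixed (cell means) and the design
factors as random: replicate, block-in-replicate and field column at
environment scope; year crossings of those at location scope; location and
year×location crossings at global scope.  Broad-sense heritability is
`H² = σ²_G / (σ²_G + σ²_e / r)` on an entry-mean basis with `r` replicates,
with `σ²_G` from refitting the same model with genotype random.  Band
responses use the identical environment-scope model per (camera, date, band).
Designs shared by many band responses reuse cached cross-products and warm-
start the optimizer from the previous band's ratios.

Genotypes present in a single replicate are retained; an estimability error is
raised only when the genotype/replicate incidence graph is disconnected.
Knife-edge QC fractions (a MAF of exactly 0.05, 10% missing exactly) are
resolved to the intended side of the thresholds with a 1e-9 epsilon.

## Synthetic study

The generator reproduces the design of the emulated field programme; its
defaults are the study conditions, not tuning knobs:

* **Panel and markers.** 300 inbred lines descending from 30 founders: per
  marker an allele frequency is drawn from (0.01, 0.5), founder haplotypes are
  Bernoulli draws at that frequency, and each line is a random biparental
  mosaic (independent inheritance per marker).  The family relatedness this
  creates is what gives G predictive structure — with unrelated lines the
  genomic kernel approaches the identity and out-of-sample accuracy collapses,
  which is a property of the model, not a bug of the fit.  1% of calls are
  recoded heterozygous and 2% missing so marker QC is exercised; 20 000
  markers by default.
* **Environments.** Eleven year/location trials with the genotype counts
  (98–296) and heritability targets (0.63–0.92) of the emulated programme,
  alpha-lattice with 2 replicates, block size 6 (a final partial block is
  allowed when the genotype count is not divisible by 6), ~24 field columns.
  Mean yields differ by environment (baselines 505–789 g·m⁻², one high-yield
  Staur season included), which is what the environment kernel can exploit.
* **Genetic values.** `g_env = W(√ρ b_common + √(1−ρ) b_env)` on standardized
  calls, rescaled per environment to a genetic SD of 40 g·m⁻²; ρ = 0.77 is the
  target mean pairwise correlation of true values.  BLUE-level correlations
  are attenuated by ≈ √(H²_i H²_j) ≈ 0.78 and therefore sit near 0.6 — an
  unavoidable consequence of measurement error that real data sidestep only
  through shared non-genetic trends.
* **Trials.** Plot value = baseline + g + replicate + block + column + error,
  with the error variance set from the realized genetic variance so the
  expected entry-mean H² hits the target; design-effect SDs default to
  15/12/10 g·m⁻².
* **Reflectance.** Per plot, flight and band:
  baseline(band) + λ_band(stage)·g̃ + κ_band·z + design effects + noise, with
  g̃ the standardized genetic value, z a per-genotype band-specific latent
  trait, and growth stages defined by fractions of the sowing→maturity window
  (vegetative < 0.45, heading < 0.60, grain filling < 0.85, maturation
  beyond).  λ peaks during grain filling and nearly vanishes after maturity;
  NIR is configured with the weakest loadings and the largest noise, so it is
  the least heritable and least predictive band at every date.  Flight
  schedules mirror the emulated seasons: five environment/camera combinations
  with 4, 7, 8, 12 and 22 missions spread late May–late August.

What the generator does **not** emulate: linkage maps and LD decay (inheritance
is independent per marker), spatial autocorrelation beyond a column gradient,
lodging/phenology events, genotype-specific phenology shifts of the loading
profile, and any raster-level imaging step (reflectance is generated at plot
level).  Passing tests therefore demonstrate correctness of the estimation
machinery and the qualitative behaviour of the kernels under a compound-
symmetry G×E world, not field-data effect sizes.

## Cross-validation and metrics

Single-environment: an 80/20 genotype split of one BLUE vector per iteration.
Multi-environment: two environments and 20% of the genotype union drawn per
iteration; the test set is their intersection (double-blind), the training set
is the complement genotypes in the complement environments, and mixed records
are discarded.  Test fractions round to the nearest integer with a minimum of
one.  Metrics are Pearson r and RMSE on both sets; iterations with a
degenerate vector contribute no correlation (counted) but still an RMSE.
Models are refitted from scratch on every training split; all randomness
derives from the base seed through named streams, making entire runs
bit-reproducible.  K_E is built once from all environments' BLUEs (including
future test environments), mirroring the emulated protocol; the leakage this
implies for multi-environment prediction is deliberate and documented rather
than corrected.

## Campaign drivers and problem sizes

`run_model_comparison`, `run_band_importance`, `run_timing_importance` and
`run_minimal_setup` iterate kernels over the factor grids (model × K_M origin,
band × origin, flight date, camera setup).  "July flight" means calendar month
7; the date is drawn once per origin (seeded), then cross-validated.
`run_headline_suite` packages the four campaigns at 50 CV iterations with two
reflectance origins (the 12-flight and 22-flight seasons) — the package's
scaled-down protocol, chosen so a full pass completes in minutes on one core;
the full 200-iteration, five-origin protocol is a parameter change.

## Known limitations

* Variance-ratio optimization is derivative-free; worst-case fits with three
  kernels use a few hundred likelihood evaluations.
* K_E's per-genotype standardization makes it a *deviation* covariance: with
  few environments its rows are nearly mean-centered, giving negative
  off-diagonals between dissimilar trials.
* Heterogeneous residual variances per environment, spatial AR1 models,
  marker-effect (SNP-BLUP) parameterizations and Bayesian kernel regression
  are out of scope.
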