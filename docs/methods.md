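# Methods

## Model

The package tests associations between an outcome trait Y, observed only
through GWAS summary statistics, and complex traits imputed from genotypes
through linear weights (polygenic scores). For one imputed trait
T̂ = XW and the regression Y = α + γT̂ + δ, the OLS estimator is
γ̂ = cov(T̂, Y)/var(T̂) with se(γ̂) ≈ sqrt(var(δ)/(N·var(T̂))). Substituting
the per-SNP OLS identities β̂ⱼ = cov(Xⱼ, Y)/var(Xⱼ) and
se(β̂ⱼ) ≈ sqrt(var(Y)/(N·var(Xⱼ))) turns the trait-level z-score into a
weighted sum of SNP-level GWAS z-scores:

    Z = γ̂/se(γ̂) = Σⱼ Wⱼ · (sd(Xⱼ)/sd(T̃)) · Z̃ⱼ .

Note the **standard-deviation** ratio: the √var(Xⱼ) factor is forced by the
se(β̂ⱼ) substitution. (Writing the scaling matrix with variances instead of
standard deviations is a common transcription slip; the OLS-oracle tests in
this package pin the square-root form down numerically — the variance form
fails them by orders of magnitude.)

Panel quantities: var(Xⱼ) is the sample variance of the reference-panel
dosages; var(T̂) is approximated by var(T̃) with T̃ = X̃W, the trait imputed
on the panel — algebraically identical to WᵀD̃W but O(nK) instead of O(M²).

For K jointly modelled traits with weights W* and panel imputed-trait
covariance C (U := C⁻¹), the conditional z-scores are

    Zₖ = (1/√Uₖₖ) · [ U (W*)ᵀ diag(sd(Xⱼ)) Z̃ ]ₖ .

Two approximations underlie both tests and define their validity regime:

1. var(δ) ≈ var(Y): the imputed traits (jointly) explain little outcome
   variance. This is conservative — it can only overstate the se.
2. Panel second moments stand in for cohort second moments, which requires
   matched ancestry.

## Reported scales

var(Y) is unobservable from z-score summary statistics, so the standardized
outcome convention var(Y) = 1 is adopted. z and p are unaffected. Two effect
scales are reported: `gamma_hat` = Z·se (per unit of the *raw* imputed
trait) and `gamma_std` = Z/√N (per standard deviation of the imputed trait).
`gamma_std` is the scale on which a simulated standardized PRS effect ρ is
recovered, and the scale on which estimates are comparable across traits.
N is the per-variant median GWAS sample size (meta-analyzed GWAS have
heterogeneous per-SNP N); it can be overridden.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| p-value threshold | 0.01 | SNP inclusion for marginal PRS (p ≤ threshold, boundary retained) |
| LD clump r² | 0.1 | squared dosage correlation above which a neighbour is absorbed (strict >) |
| clump radius | 1 Mb | window around each index SNP, same chromosome |
| ridge condition limit | 1e10 | condition number of cov(T̃) above which a ridge is applied |
| ridge magnitude | 1e-6 × mean diag | added to cov(T̃) diagonal when near-singular (logged) |
| Bonferroni family | explicit m | e.g. 0.05/1738 for a biobank-wide scan |
| FDR level | 0.05 | Benjamini–Hochberg step-up |
| cluster count k | 15 | representative clusters for conditional analysis (e.g. 48 hits → 15) |
| linkage / distance | average / 1 − \|corr\| | so anticorrelated trait mirror-images share a cluster |

Clumping follows PLINK semantics: greedy by ascending p (ties broken by
(chrom, pos) for determinism), r² always against the current index SNP,
never transitively. Harmonization matches variants on (chrom, pos) with
allele verification (IDs drift between builds), flips signs for swapped
allele pairs, resolves strand complements, and drops A/T and C/G
(strand-ambiguous) variants by default since frequencies are not uniformly
available for a rescue. p-values are computed from the normal in log space,
so |z| > 38 yields a correct `log10_p` and a clipped-subnormal `p` instead
of zero.

## The simulation worlds

Real inputs at the scale the method targets (a 62k-individual cohort,
thousands of biobank trait GWAS) are access-controlled, so validation runs
on generated data.

**Genotypes.** Per LD block and haplotype, a latent Gaussian with
exchangeable correlation c (default 0.4) is thresholded at each variant's
MAF quantile (MAF ~ U(0.05, 0.5)); dosage = sum of two haplotypes. This
gives O(n·M) cost and controllable LD. It does **not** emulate realistic
human LD decay, MAF spectra, or long-range structure — conclusions about
those features cannot be drawn from green tests here; the clumping radius
semantics are exercised by construction, not by realism.

**Phenotype settings.** (1) pure N(0,1) noise; (2) dense polygenic trait,
Y = √h²·std(Xβ) + √(1−h²)·std(ε) with h² = 0.1 and β i.i.d. normal;
(3) Y = ρ·std(P) + std(Xβ + ε), the PRS and background normalized
separately so ρ ∈ {0.005, 0.008, 0.01, 0.015, 0.02} is a standardized
effect; (4) pairs Tᵢ (polygenic, h² = 0.1) and Yᵢ = γᵢTᵢ + εᵢ with
γᵢ ~ N(0, 2) and var(εᵢ) = var(Tᵢ), analysed across two half-cohorts
(T GWAS on one half, Y GWAS on the other) through the full
PRS-construction + testing pipeline.

**Choosing miniature sizes.** The dimensionless quantity n·h²·ℓ/M (ℓ = an
LD factor ≈ 1 + (blocksize−1)·r̄²) controls the *true* association between
a dense polygenic trait and any fixed PRS. At biobank scale it is ≈ 0.005,
which is what makes setting-2 traits effectively null; a naive miniature
(n = 5000, M = 1000) puts it at ≈ 0.5 and the "nulls" genuinely associate.
Calibration and power runs therefore use worlds chosen by this scaling
argument (calibration: n = 800, M = 16,000, blocks of 8; power: n = 4,000,
M = 12,000), fixed a priori, not tuned on outcomes. Oracle-equivalence runs
use n = 5,000, M = 1,000 in 50 blocks with 20 PRS traits of 50 SNPs.

**Monte-Carlo design.** The power curve uses common random numbers (one
background per replicate reused across the whole ρ grid) so the
non-decreasing-power comparison is within-replicate, and antithetic
background pairs (B, −B) so the background's first-order contribution to
the mean recovered effect cancels; the reported MC standard error is the
plain per-replicate one and is therefore conservative.

## Numerical choices

- Sample (co)variances use denominator n−1 throughout; zero-variance
  dosage columns give r² = 0 in clumping and are flagged in GWAS output
  (β = 0, se = ∞, p = 1).
- Missing dosages are mean-imputed per variant (preserves the mean and
  keeps variances defined); all-missing variants are dropped.
- z is authoritative over p when both are present and inconsistent beyond
  1e-4 relative (p recomputed, logged); missing z falls back to beta/se.
- Near-singular trait covariances (condition number > 1e10, e.g.
  duplicated traits): ridge with magnitude 1e-6 × mean diagonal, or a hard
  error naming the most collinear pair when the ridge is disabled.
- Weight tables without effect sizes fall back to z-score weights, flagged
  `standardized`; z and p of downstream tests are invariant to any positive
  rescaling of a weight column.
- Internal coordinates are 1-based, both ends inclusive; BED is converted
  at the boundary (start+1..end). Region exclusion treats both printed
  boundary positions as inside.

## Limitations

- The training GWAS behind the weights and the outcome GWAS must be
  independent; no sample-overlap correction is attempted. Overlap inflates
  test statistics.
- Panel-moment estimation assumes ancestry match; no cross-ancestry
  adjustment.
- Marginal PRS only (any external linear weight file is accepted; joint
  LD-aware weight estimation is out of scope).
- Fixed-effects IVW meta-analysis only (two-study designs); no
  heterogeneity model.
- Quantitative-trait simulations only; no liability-threshold case-control
  generation.
- Low PRS predictive accuracy behaves like measurement error: power drops,
  type-I error does not inflate.
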