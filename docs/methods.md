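# Methods

This note documents the models, defaults and numerical choices behind
`nephroage`, and what the synthetic validation studies do and do not show.

## Synthetic cohort model

The generator produces genotype, methylation and expression data under a
linear-Gaussian structural model on the transformed analysis scales, so
that the downstream linear estimators are consistent for the recorded
generative coefficients ("truth record").

**Genotypes.** Each variant's MAF is drawn uniformly from `maf_range`
(default (0.05, 0.5]: common variants). Two haplotypes per sample are
generated per LD block by first-order copying: the allele at variant j is
copied from variant j−1 with probability `ld_decay`, else drawn fresh as
Bernoulli(MAFⱼ). Dosage is the haplotype sum, giving Hardy–Weinberg
marginals and tunable adjacent-variant correlation (haplotype allele
correlation ≈ `ld_decay` at equal MAFs). Blocks are mutually independent.
This is deliberately not a coalescent model — it is a desk-scale device
producing the two features the pipeline needs: realistic dosage marginals
and controllable local LD for pruning and proxy-instrument behavior.

**Methylation.** logit(m) = intercept + Σ effects + factor loadings + ε,
ε ~ N(0, `noise_sd_methylation`), returned as beta values through the
inverse logit (hence strictly inside (0, 1)). CpG intercepts are
N(−1, 0.5), putting typical betas in the 0.1–0.5 band.

**Expression.** log2(TPM) = intercept + Σ effects + factor loadings + ε,
ε ~ N(0, `noise_sd_expression`), exponentiated to a TPM-like scale. Gene
intercepts are N(4, 1) (typical TPM ≈ 16); genes without declared effects
form the null background.

**Centering of effect sources.** Every effect source (age, sex, dosage,
methylation beta, log2 expression) enters centered at its sample mean.
Slopes — the quantities downstream estimators recover — are unchanged by
this; intercepts keep their interpretation as population means. Without
centering, several positive SNP effects plus an age effect on one CpG push
the logit far from the intercept and saturate the beta scale, destroying
the very signal being modeled.

**Hidden technical factors.** k standard-normal per-sample scores with
N(0, loading-SD) per-feature loadings added to both omics layers
(defaults 0.3 on log2 expression, 0.15 on logit methylation). They exist
to give the factor estimator real structure to recover and to make
"analyze without adjusting" visibly miscalibrated — as it is: the type-I
study is only calibrated when estimated factors join the covariates.

**Covariates and traits.** Age is uniform over `age_range` (default
28–87 years, matching the span of the cohorts the pipeline is sized for;
uniform rather than bell-shaped to spread leverage across the range). Sex
is Bernoulli(`sex_fraction`, default 0.65 male). eGFR (ml/min/1.73 m²)
declines linearly at 0.8 per year — the canonical ≈8 per decade — around
an intercept of 120, with residual SD 12. Ordinal 0–3 histology grades
(glomerulosclerosis, interstitial fibrosis, tubular atrophy,
arterial/arteriolar narrowing) come from thresholding an age-driven latent
Gaussian at fixed cumulative proportions chosen to mirror a typical
nephrectomy-cohort grade distribution (e.g. roughly 38/53/9/0 % for
glomerulosclerosis). Thresholds are applied at the latent's empirical
quantiles, so the grade distribution is exact per cohort.

**Multi-cohort studies.** `biology_seed` separates feature-level
randomness (intercepts, loadings, MAFs) from sample-level randomness, so
discovery, replication and tissue cohorts can share one "biology" while
drawing independent subjects. Without this, per-cohort baselines differ
and a combined-sample analysis has artificial batch structure.

**Planted scenario.** `promoter_methylation_scenario()` encodes the causal
chain the pipeline is designed to detect: age → promoter CpG
(+0.08 logit/yr), six unlinked SNPs → CpG (0.6–0.9 logit per allele), and
CpG → gene (−3 per beta unit for the demonstration; −0.6 in the MR
recovery study, a magnitude in the range typically reported for
methylation–expression effects). There is deliberately no direct age → gene
or SNP → gene edge, so the whole age signal in the gene is mediated.
Magnitudes were chosen from the generative algebra to give high power at
n ≈ 260: with the defaults, corr(age, logit m) ≈ 0.6 and the induced
age–expression correlation ≈ −0.4, comfortably detectable after FDR over
the simulated transcriptome.

### What the generator does not emulate

No read-level sequencing or bisulfite noise (the pipeline starts at a TPM
matrix); no population demography, relatedness or long-range LD; no
cell-type composition shifts with age; no nonlinear age trajectories; no
confounding between methylation and expression beyond the modeled paths.
Passing tests therefore demonstrate that the estimators are correct and
calibrated under the stated model — not that real kidney data satisfy that
model. In particular the MR unbiasedness result leans on the absence of
unmodeled mediator–outcome confounding, which real one-sample designs
cannot guarantee.

## Normalization

* log2(TPM + 1): pseudo-count 1 by convention.
* Quantile normalization across samples by rank means; tied values receive
  the average of their would-be rank means (via interpolation at average
  ranks). Afterward all samples share one empirical distribution.
* RBINT per feature with Blom offset c = 3/8: Φ⁻¹((r − c)/(n − 2c + 1)),
  ties sharing average ranks. A constant feature maps to zeros with a
  warning and should be excluded downstream.
* M-values: M = log2(m/(1 − m)) with betas clamped to [ε, 1 − ε],
  ε = 10⁻⁶.
* Hidden factors: regress out known covariates per feature, standardize
  residual rows, SVD, return the top-k right singular vectors. This is a
  PCA-style stand-in with the same interface as variational residual-factor
  methods (k factors used as covariates); it recovers a planted factor with
  |r| > 0.95 at n = 200, 1000 genes. The appropriate k is data-dependent;
  the pipeline exposes it per scenario precisely so sensitivity analyses
  can vary it.
* Genotype PCs: per-variant centered, unit-variance scaled dosages
  (mean-imputed where missing), SVD, top 3 score vectors by default.

## Association engine

OLS per feature with design [1, predictor, covariates]; Wald t with
Student-t reference at df = n − p (not the normal: correct finite-sample
size, and the two coincide at these n anyway). Features with complete data
share one vectorized solve; features or predictors with missing entries
fall back to pairwise-complete fits, skipped below 90 % observed (the
threshold is configurable). Zero-variance responses/predictors and
rank-deficient designs yield status records, not exceptions. Ordinal
histology grades enter as linear 0–3 scores. The age-adjustment flag of
the trait scan implements the sensitivity analysis asking how much of a
trait association is carried by age.

## Meta-analysis, FDR, replication

Fixed-effect inverse variance (the minimal reading of "inverse-variance
method"); Cochran's Q and I² are reported, never used for gating.
BH step-up is delegated to statsmodels; Storey's π₀ is estimated as
#{p > λ}/(m(1 − λ)) on λ = 0.05…0.95 (step 0.05), smoothed by a
least-squares cubic in λ and read off at λ = 0.95, clamped to [1/m, 1]
(a deterministic cubic smoother; spline smoothing would add a tuning
parameter without changing the estimate materially on a 19-point grid).
Replication treats each replication resource (e.g. cortex and medulla) as
its own multiple-testing family and takes the union of family-level
successes; a success needs q below threshold *and* a concordant sign.
Features absent from a replication family are "unavailable" and excluded
from that denominator.

## cis-QTL mapping

Windows are half-open: a variant at position pos is cis to [start, end)
iff start − window ≤ pos < end + window. Signed distance is 0 inside the
span, pos − start (negative) upstream, pos − (end − 1) (positive)
downstream. MAF filter 0.05 by default. The nominal engine residualizes
phenotype and (mean-imputed) dosages against the covariates once and fits
the simple regressions vectorized — by Frisch–Waugh–Lovell this equals the
full multiple regression coefficient, SE and t at df = n − 2 − n_cov.

Permutations use the residualize-then-permute scheme (standard and
efficient; permuting raw phenotypes against fixed covariates would break
exchangeability). The per-feature statistic is the best cis association
(max r², equivalently min p at fixed df), giving per-feature empirical
p = (k + 1)/(B + 1) with floor 1/(B + 1) — never zero, and printing as
5.00E-04 at B = 2000. Ties at the observed statistic count as exceedances
(conservative). Best-variant ties break by smaller |distance|, then
lexicographic id.

## Mediation

Product of coefficients under the linear no-interaction model: a from
M ~ X + C, b and the direct effect from Y ~ X + M + C, total from
Y ~ X + C; ACME = a·b and total = ACME + ADE holds exactly for OLS point
estimates on a common sample. Uncertainty by nonparametric bootstrap
(resampling subjects, default 1999 resamples), percentile 95 % CI, and a
two-sided sign p-value 2·min(P(ACME* ≤ 0), P(ACME* ≥ 0)) floored at
2/(n_boot + 1) so it can never be exactly zero. Bootstrap systems are
solved with pseudo-inverses so a degenerate resample of a discrete
exposure (e.g. a rare genotype absent from one resample) cannot abort the
run. Measured coverage at n = 500 is ≈ 94 %, the usual mild anticonservatism
of percentile intervals.

## Mendelian randomization

One-sample summary statistics: per instrument, β̂ₓ from the exposure
(methylation) QTL regression and β̂ᵧ from the outcome (log2 expression)
regression with the same covariates. Instruments are exposure-QTL
significant variants (BH q < 0.05 within the cis window by default, or an
explicit p threshold), greedily pruned to pairwise dosage r² ≤ 0.1 keeping
the smaller p — near-independence is what licenses the uncorrelated-weights
formulas.

* IVW: first-order weights wⱼ = β²ₓⱼ/SE²ᵧⱼ on Wald ratios; one instrument
  reduces exactly to the ratio βᵧ/βₓ with SE = SEᵧ/|βₓ|.
* Weighted median: ratios ordered, cumulative weights evaluated at
  midpoints sⱼ = Σ₍ᵢ≤ⱼ₎wᵢ − wⱼ/2, linear interpolation where they cross
  0.5; SE by seeded parametric bootstrap (1000 draws of (β̂ₓ, β̂ᵧ) from
  their normal approximations) since no closed form exists. Consistent
  when valid instruments carry ≥ 50 % of weight.
* Egger: instruments oriented to βₓ > 0, WLS of βᵧ on βₓ with weights
  1/SE²ᵧ; the slope is the causal estimate and the intercept the average
  directional pleiotropy, tested by t with J − 2 df.

The triangulation outcome scale is log2(TPM + c) with c = 0 by default:
the generator's TPM values are strictly positive, and a pseudo-count of 1
at TPM ≈ 16 attenuates slopes by 10–25 %, which would masquerade as
estimator bias in the recovery studies. For sparse real matrices set
c = 1. CIs are θ̂ ± 1.96·SE throughout and always reported as
(lower, upper) sorted.

## Validation studies and problem sizes

The studies in `nephroage/validation.py` use: B = 2000 permutations for
the floor check; 2000 null genes at n = 160 for the type-I study; m = 2000
p-values × 200 replicates (80 % null) for BH FDP and m = 5000 for π₀;
100 random small designs for the OLS oracle; 200 cohorts of n = 500 with
six instruments for MR recovery; J = 50 instruments × 500/200 replicates
for Egger size/power; 500 replicates × 499 bootstrap resamples at n = 500
for mediation coverage; and a full pipeline run with discovery 160 + 100,
two replication families of 150, and B = 1000 for the end-to-end check.
These sizes give Monte-Carlo error comfortably inside each check's
tolerance while keeping a complete run in the low minutes on one CPU.

## Known limitations

* Fixed-effect meta-analysis only; no random-effects estimator.
* Hidden-factor estimation is linear PCA; nonlinear batch structure is out
  of scope.
* No beta-approximation extrapolation of the permutation null: empirical
  p-values are bounded below by 1/(B + 1), so genome-scale multiplicity at
  small B will saturate at the floor.
* MR assumes instruments act on the outcome only through the exposure;
  the weighted median and the Egger intercept probe, but cannot prove,
  this.
* Ordinal traits are modeled linearly; no proportional-odds model.
* The VCF layer handles GT (and dosage implicitly via hard calls) but not
  genotype-probability fields.
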