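# Methods

`adipomr` re-implements, as a tested library, a four-part analysis linking
obesity, adipose tissue biology and systemic insulin resistance: two-sample
Mendelian randomization (MR) of body fat percent on prediabetes and on the
Matsuda index; quantification of adipose mitochondrial (MT) gene expression
with bias-aware technical correction; deconvolution of bulk adipose RNA-seq
into cell-type proportions using a single-nucleus reference; and a
multivariable / elastic-net model of the Matsuda index. Because the cohorts
such analyses run on (biobank GWAS, population bulk RNA-seq, snRNA-seq
biopsies) are access-restricted, every stage is paired with a synthetic
generator that encodes the statistical structure the stage assumes, and the
test suite measures recovery of known truth rather than reproduction of
cohort-bound numbers.

## Mendelian randomization

Inputs are per-variant summary statistics from two non-overlapping GWAS
samples: `beta_exp`/`se_exp`/`p_exp` for the exposure and
`beta_out`/`se_out` for the outcome. Instruments are selected at genome-wide
significance (`p_exp < 5e-8`) and greedily LD-pruned in ascending p-value
order (ties broken by variant id) so every retained pair has `r² < 0.01`.
Variants associated with named confounders (blood pressure, triglycerides,
lifestyle factors) below a configurable threshold — default the same 5e-8,
since no other scale is canonical — can be excluded, with a report of what
was dropped.

Estimators, all weighted by `w = 1/se_out²`:

* **IVW** — regression of outcome betas on exposure betas through the
  origin; multiplicative random-effects SE inflation by `sqrt(Q/(n−1))`
  when Cochran's Q exceeds its degrees of freedom (robust default; a
  fixed-effects switch is provided).
* **MR-Egger** — free-intercept weighted regression after re-signing
  variants so exposure betas are positive; the intercept estimates mean
  directional pleiotropy and its t-test (n−2 df) is the pleiotropy test,
  with the overdispersion scale capped below at 1.
* **Cochran's Q** — heterogeneity around a given slope, chi-square with
  n−1 (IVW) or n−2 (Egger) df.
* **MR-PRESSO** — the observed weighted residual sum of squares, with each
  variant's expectation taken from the leave-one-out IVW fit, is compared
  to a parametric null built by redrawing outcome betas from the fitted
  model at their reported SEs (default 5000 draws; the leave-one-out slopes
  are recomputed inside every draw, fully vectorized). The global p-value
  is the exceedance fraction with a plus-one correction. Per-variant
  squared residuals get the same exceedance treatment, Bonferroni-corrected
  over the instruments at α = 0.05; the corrected estimate is IVW on the
  non-outliers, and equals plain IVW exactly when no outlier is flagged.
  The distortion test is intentionally omitted from the default report.

Causal-effect p-values are Bonferroni-adjusted over the three MR analyses
of the study design (`m = 3`). A direction without enough genome-wide
significant instruments is reported as "not assessable" rather than fitted.

The MR generator draws exposure betas N(0, 0.05²) — the spread of
genome-wide-significant effects in a several-hundred-thousand-sample
biobank on an inverse-normal scale — with reported SEs of 0.0025 (exposure)
and 0.01 (outcome), and builds outcome betas directly from the observed
exposure betas (`beta_out = θ·beta_exp + pleiotropy + noise`); the
instrument–exposure associations are treated as fixed, so the recovery
benchmarks are free of regression-dilution bias that a separate
exposure-noise layer would add. Directional pleiotropy is half-normal
(single-signed), balanced pleiotropy zero-mean.

## MT expression and technical correction

TPM is computed from counts and gene lengths; MT expression is the sum of
TPMs of the MT-encoded genes (37 in the standard human annotation,
overridable). Library metrics computed over all aligned reads (intergenic
%, exonic %, ...) are strongly coupled to the MT read fraction because the
MT genome contributes a large, structurally atypical read mass; correcting
MT expression for them would subtract genuine signal. The package therefore
recomputes read-category fractions after removing MT reads from both
numerator and denominator, keeps the biased versions for comparison, and
residualizes MT expression on the unbiased factors plus genotype PCs (11
technical covariates and 3 PCs by default; both are column-name lists, and
a post-mortem-interval column is just one more covariate rather than a
special case). The inverse normal transform uses the Blom offset (c = 3/8)
with average ranks on ties; log transforms are natural log with a +1
pseudocount. Group contrasts (e.g. diabetic vs non-diabetic expression) use
Welch's t-test.

## Deconvolution

Reference QC removes nuclei with fewer than 300 expressed genes, then genes
expressed in fewer than 3 nuclei, in that order. Signature genes are
one-vs-rest Wilcoxon markers on library-normalized log1p expression
(Benjamini–Hochberg q < 0.05, log2 fold-change > 1; thresholds
configurable), each gene attributed to its strongest cluster; clusters with
fewer than 3 nuclei are excluded with a warning. Pseudo-bulk sums each
subject's counts (aggregate-read semantics, matching how a bulk library
samples a tissue) and cell-type profiles are the across-subject mean and
variance of within-type relative expression, with the mean per-cell library
size as the type's RNA content.

Nuclear libraries over-represent unspliced transcripts, so some genes
(MALAT1-like) are orders of magnitude higher in pseudo-bulk than in bulk.
The concordance filter z-scores the per-gene difference in mean log1p
expression between bulk samples and pseudo-bulk subjects (SD with n−1
denominator) and keeps genes with z² ≤ 1; a zero-spread difference vector
keeps everything with a warning. Proportions are estimated by iteratively
re-weighted nonnegative least squares on relative expression: the
coefficient of type k estimates its RNA fraction p_k·S_k; per-gene weights
`1/(floor + residual² + Σ_k coef_k²·var_k,g)` down-weight genes with large
residuals or high cross-subject variance, capped at 100× the median weight
to bound leverage, iterated until the proportion vector moves < 1e-6 in the
max norm (cap 300 iterations — the fixed point contracts with ratio ≈ 0.7,
so the older convention of 100 iterations cannot reach that tolerance).
Dividing by S_k and renormalizing yields cell-count proportions.
Near-collinear references (condition number > 1e8 after column
normalization) are flagged non-identifiable rather than silently split.
Estimates are scale-invariant in the bulk library size. Leave-one-out
validation rebuilds everything (signatures, profiles, filter) from the
other subjects inside each fold. Per-type RNA-content multipliers default
to 1 (equal RNA per cell) because no canonical values exist; they are a
config knob.

The cell generator draws per-subject compositions from a Dirichlet centred
on an adipose-like mix (adipocytes 44% of nuclei, concentration 25), gamma
base rates shared across types with subject-level lognormal jitter
(sd 0.15), markers for 10% of genes upregulated 8-fold in one type (the
cleanly-separated regime real adipose clusters occupy), and 5% discordant
genes inflated 30-fold in nuclei only. The default per-cell library
(1200 reads on the 2000-gene panel) gives a median ≈ 500 expressed genes
per nucleus — the detection rate typical of adipose snRNA-seq — so the
300-gene QC removes a small minority. Bulk mixtures apply the discordant
inflation on the nuclear side only, add lognormal noise (CV 0.1) and sample
Poisson counts with length-weighted read probabilities.

What the generator does not emulate: ambient RNA, doublets, batch effects
across subjects, genuinely distinct global transcriptomes per cell type
(types differ only in markers), or empirical LD; conclusions about those
failure modes cannot be drawn from these tests.

## Insulin-sensitivity models

Cohort preparation removes diabetic individuals from every Matsuda
analysis, inverse-normal transforms the Matsuda index and MT expression,
and residualizes the transformed Matsuda on age and age². The
multivariable model regresses it on body fat percent, adjusted MT
expression and 7 cell-type proportions — one type (endothelial by default)
is excluded because the 8 proportions sum to 1; including all 8 raises an
explicit error naming the fix. Variance partitioning refits OLS per
predictor subset. The per-cell-type association scan fits each proportion
with age as covariate and Bonferroni-corrects over the 8 types.

The elastic net minimizes `(1/2n)||y − Xβ||² + λ(a||β||₁ + (1−a)/2||β||₂²)`
by cyclic coordinate descent on standardized predictors with an unpenalized
intercept, warm-started along a 100-point log-spaced λ path from λ_max down
four decades; λ is chosen at the minimum mean 10-fold CV error and
coefficients are returned on the original scale with the standardization
stored in the serialized JSON model. The single-λ-on-both-norms penalty is
the a = 0.5 case of this parameterization. Solutions satisfy the KKT
stationarity conditions to ≤ 1e-6 and match closed-form ridge (a = 0) and
OLS (λ = 0) limits. The 100-group out-of-fold evaluation re-selects λ
inside every training set; all inner-CV coordinate descents are solved in
one stacked batch over a shared λ path, which is what makes 20-seed
evaluation at n = 324 take seconds rather than hours. Two predictor presets
exist — `bmi` (default, the transferable model) and `bodyfat` — each with
MT expression, age and the 7 proportions. For twin cohorts,
`evaluate_unrelated_subset` correlates predictions on a seeded
one-per-pair subsample.

The phenotype generator builds a latent Matsuda index as a linear function
of body fat percent (β = −0.08 per point), MT expression (β = +0.40 per SD,
itself negatively correlated with adiposity), cell-type proportions
(macrophages and dendritic cells strongly negative; the endothelial
coefficient is fixed at 0 so the 7-proportion model identifies the
generator betas directly rather than a reparameterization) and age, with
noise calibrated analytically — variance matching against the realized
linear predictor — to a target total R² of 0.44. The observed index is a
monotone (exp) transform of the latent, so rank-INT recovers the latent up
to its SD; recovery tests therefore compare fitted coefficients to
generator betas divided by the realized latent SD. HbA1c is
`5.4 + 0.02·bodyfat% + N(0, 0.3)` truncated at 4.5, which yields a
realistic 10–15% prediabetes fraction in the 5.7–6.4 band; a 3.3% subset is
assigned diabetes with HbA1c above the band. BMI is `20 + 0.25·bodyfat% +
N(0, 0.4)` (tightly coupled, as the two obesity measures are in practice).
Technical factors are standard normal plus 0.8× the standardized MT read
fraction, reproducing the confounding the bias-aware metrics are built to
break.

## Numerical choices and problem sizes

* Exceedance p-values use (1 + #{≥}) / (n_sim + 1); MR-PRESSO defaults to
  5000 draws (2000 in the replicated calibration studies).
* The pruning tie-break, one-per-pair twin sampling, CV partitions and all
  generators are seeded; everything is bit-reproducible given (config,
  seed).
* Benchmark sizes: PRESSO calibration 500 null replicates (50 instruments,
  2000 draws); effect recovery 200 replicates × 3 effects; deconvolution
  6 subjects × 8 types × 2000 genes × ~15,000 nuclei; multivariable-model
  recovery 100 replicates at n = 2000; out-of-fold prediction 20 seeds at
  n = 324. These sizes put Monte-Carlo error well below the tolerances
  being checked while keeping the full suite in a few minutes on one core.

## Known limitations

Per-cell-type Pearson correlations over a single 6-subject design are
fragile: when a type's true proportions happen to vary little across the
six subjects, its r is noise-dominated even when the absolute errors are
small (RMSE ≈ 0.015), so per-type correlation summaries are more stable
when pooled over replicate 6-subject experiments. The MR module treats
outcome betas as scale-agnostic (linear-probability betas from a
linear-model GWAS pass through unchanged). Clustering is an input, not a
step: the package never re-derives cell-type labels. The elastic net
standardizes predictors and does not penalize the intercept; tools that do
otherwise will give slightly different coefficients at the same λ.
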