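# adipomr

Causal inference and adipose-transcriptomics modelling of insulin
resistance. The package is for quantitative geneticists and computational
biologists who want to run — or stress-test on fully synthetic data — a
four-stage analysis linking obesity to prediabetes and insulin sensitivity:

1. **Two-sample Mendelian randomization (`adipomr.mr`).** Genetic variants
   associated with an exposure (body fat percent) in one GWAS sample
   instrument its causal effect on an outcome (prediabetes status, Matsuda
   index) in a second sample. Instruments are selected at `p < 5×10⁻⁸` and
   LD-pruned to `r² < 0.01`; the causal slope is estimated by
   inverse-variance-weighted regression through the origin
   (`β̂ = Σwβ̂ₓβ̂ᵧ / Σwβ̂ₓ²`, `w = 1/se²ᵧ`), cross-examined by MR-Egger
   (free intercept = directional-pleiotropy test) and Cochran's Q, and
   protected against outlying pleiotropic variants by an MR-PRESSO
   resampling test with leave-one-out expected values. Causal p-values are
   Bonferroni-adjusted over the three analyses of the design.
2. **MT expression (`adipomr.expression`).** Mitochondrial expression is
   the sum of TPMs over the 37 MT-encoded genes, corrected for technical
   factors that are themselves recomputed after excluding MT reads — the
   naive versions are dominated by the MT read fraction and would absorb
   real signal — plus genotype PCs, then inverse-normal transformed
   (Blom offset).
3. **Deconvolution (`adipomr.deconvolution`).** A single-nucleus reference
   (QC: ≥300 genes/nucleus, ≥3 nuclei/gene; one-vs-rest Wilcoxon signature
   genes) drives a MuSiC-style iteratively re-weighted nonnegative
   least-squares estimate of cell-type proportions in bulk RNA-seq, after a
   chi-square concordance filter (keep `z² ≤ 1` on the bulk-vs-pseudo-bulk
   mean log-expression difference) removes nucleus-retained, MALAT1-like
   genes. Validation is leave-one-subject-out with the reference rebuilt
   inside every fold.
4. **Insulin-sensitivity models (`adipomr.insulin_model`).** The
   multivariable model `Matsuda ~ β_b·bodyfat% + Σβ_c·CTᵢ + β_M·MT`
   (one cell type excluded; proportions sum to 1), variance partitioning by
   predictor subset, and an elastic net
   `argmin_β (1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` fit by coordinate
   descent, λ chosen by cross-validation, evaluated by 100-group
   out-of-fold prediction with λ re-selected inside every training set.

`adipomr.synthetic` generates every input — GWAS summary statistics with
tunable pleiotropy, multi-subject single-nucleus references with
marker and nucleus-retained gene structure, bulk mixtures, and phenotype
cohorts whose latent Matsuda index has a calibrated total R² — together
with ground-truth records, so every stage is testable without access to
restricted cohort data.

## Worked example

Run the all-synthetic demo pipeline and render its report:

```bash
adipomr run --seed 1 --out runs
adipomr report runs/<run_dir>
```

or equivalently in Python:

```python
from adipomr import pipeline
run_dir = pipeline.run_pipeline(pipeline.default_config(seed=1), out_root="runs")
print(pipeline.make_report(run_dir).read_text())
```

With seed 1 this prints (abridged):

```
## Mendelian randomization
| method | estimate | se | p (adjusted) | pleiotropy p |
| PRESSO-corrected | -0.6566 | 0.0273 | 2.68e-127 | global 0.0975 |
| Egger | -0.5643 | 0.0704 | 3.94e-08 | intercept 0.167 |

## Deconvolution (leave-one-out)
- overall Pearson r: 0.987
- overall RMSE: 0.0212

## Insulin-sensitivity model
- Model 1 R^2: 0.4719 (n = 313)
- out-of-fold Pearson r: 0.642 (p = 1.05e-37)
```

Reading the numbers: the demo generator plants a causal effect of −0.67
with 5% directional pleiotropy; the MR-PRESSO-corrected slope recovers it
(−0.657 ± 0.027) while the global pleiotropy test (p = 0.098) and Egger
intercept (p = 0.167) correctly find no residual directional bias after
outlier removal. The leave-one-out deconvolution reproduces the true
nucleus label frequencies to ~2 percentage points RMSE. The multivariable
model explains 47% of the variance in the transformed Matsuda index in
this 313-person cohort (generator target 0.44), and the out-of-fold
elastic-net prediction correlates 0.64 with the observed index.

Individual stages are also exposed as subcommands (`adipomr simulate ...`,
`adipomr mr ...`, `adipomr expr ...`, `adipomr decon ...`,
`adipomr model ...`); every command takes explicit seeds and writes plain
TSV/JSON.

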