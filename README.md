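# gtaccc

Genomic taxometric analysis of continuous and case-control traits.

`gtaccc` tests whether the genetic architecture of a continuous trait is
continuous or differentiated across its severity spectrum. It binarizes the
trait at multiple severity cut points, runs per-variant association scans of
every binarization (plus external case-control traits), estimates the full
genetic covariance/correlation matrix and its joint block-jackknife sampling
covariance with LD score regression, and then models the genetic
correlations as a function of severity with generalized least squares (GLS)
trend/decay regressions and severity-factor structural equation models fit
by diagonally weighted least squares. A bundled simulator with a planted
severity-gradient architecture makes every stage testable without external
data.

## Layout

| module | contents |
| --- | --- |
| `gtaccc.simulate` | genotype panels with block LD, item-level cohorts mixing two correlated genetic factors, ascertained disorder traits, and direct draws of summary statistics under the LDSC model |
| `gtaccc.gwas` | vectorized OLS association scans (single and batched) |
| `gtaccc.sumstats` | summary-statistics text format, validation, allele alignment |
| `gtaccc.severity` | multi-cut binarization, latent-normal severity scores, balanced downsampling, effective sample size |
| `gtaccc.ldsc` | LD scores, univariate/bivariate/multivariate LD score regression, joint delete-one-block jackknife V, liability-scale conversion, standardization (delta method or direct jackknife), PSD smoothing |
| `gtaccc.gls` | GLS severity-trend and correlation-decay models weighted by the full sampling covariance |
| `gtaccc.sem` | one/two/three severity-factor models with anchored loading patterns, DWLS fitting, sandwich SEs, chi-square/CFI/SRMR/AIC |
| `gtaccc.pipeline` | config-driven orchestration with manifests and stage skipping |
| `gtaccc.experiments` | reference desk-scale experiment recipes (gradient detection, model selection) |

## CLI

```sh
gtaccc pipeline --config configs/demo.yaml --out demo_run
```

runs simulate -> binarize -> GWAS -> multivariate LDSC -> GLS trend/decay ->
1- and 2-factor SEM, writing every artifact plus a manifest into `demo_run/`.
With the demo config the planted severity gradient yields a rising pattern
of genetic correlations with the disorder trait and (in the typical run) a
significantly positive GLS trend slope.

Individual stages are exposed as verbs operating on the serialized
artifacts:

```sh
gtaccc simulate --config configs/demo.yaml --out cohort_dir
gtaccc binarize --cohort cohort_dir --out severity.tsv
gtaccc gwas     --cohort cohort_dir --out sumstats_dir
gtaccc ldscores --cohort cohort_dir --out ld.tsv
gtaccc ldsc     --sumstats sumstats_dir/cut1.sumstats ... --ld ld.tsv --out struct_dir
gtaccc gls      --struct struct_dir --severity severity.tsv --external disorder --out gls.json
gtaccc gls      --struct struct_dir --severity severity.tsv --decay --out decay.json
gtaccc sem      --struct struct_dir --factors 2 --external disorder --out sem.json
```

Summary statistics use a tab-separated `SNP CHR BP A1 A2 FRQ N Z P` table
with a JSON metadata sidecar (binary flag, sample/population prevalence).
The genetic covariance structure is a directory of TSVs (`S`, `R`,
`intercepts`, `V_S`, `V_R`) with a manifest documenting the vech order
(row-major lower triangle, diagonal included).

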