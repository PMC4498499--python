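# irongc

Toolkit for genetic evaluation of iron-biomarker / atherosclerosis
relationships on SNP dosage data:

- **`irongc.simulate`** — synthetic genotypes (HWE, optional sibling pairs
  built from parental gametes), multi-trait phenotypes with known genetic and
  residual covariance, covariate effects, liability-threshold binary traits,
  and an outcome-trait subsample, mirroring a cohort with ~1 800 biomarker
  samples and a ~550-sample atherosclerosis-measurement subset.
- **`irongc.genio` / `irongc.preprocess`** — PLINK bed/bim/fam and GCTA
  binary-GRM IO, genotype-probability → dosage transform, effect-allele
  flipping, MAF/HWE SNP QC, and sex-stratified trait residualization with
  log transform, ±4 SD outlier exclusion or winsorizing, and standardization.
- **`irongc.mr`** — single-SNP and 8-SNP risk-score association models
  (OLS + IRLS logistic, Wald 95 % CIs), score quartile contrasts vs Q1,
  sex strata, lipid adjustment, cross-trait SNP × biomarker scans, and a
  direction-consistency evaluation against the hypothesized risk signs.
- **`irongc.grm`** — sliding-window LD pruning (100/5/r² 0.98 defaults),
  GCTA-formula GRM, greedy cryptic-relatedness filtering (cutoff 0.025), and
  eigendecomposition.
- **`irongc.greml`** — univariate and bivariate AI-REML variance components
  in the GRM eigenbasis (dense path for partial trait overlap), genomic
  correlations with delta-method SEs, boundary-status reporting, and a
  small-sample behaviour report.
- **`irongc.bayes`** — Gibbs-sampled multivariate genomic model on scaled GRM
  eigenvectors with latent genetic/residual factors, bounded-uniform variance
  priors, data augmentation for missing traits, DIC-based selection of the
  number of latent factors, and the four-model trait-roster suite with a
  merged 7 × 4 genomic-correlation report.

## CLI

```bash
irongc simulate --n-samples 1819 --n-snps 5000 --seed 1 --out scratch/cohort
irongc prep     --bed scratch/cohort --pheno scratch/cohort.pheno.tsv \
                --mode winsorize --out scratch/resid.tsv
irongc mr       --geno scratch/cohort --pheno scratch/cohort.pheno.tsv \
                --snps snps.yaml --out scratch/mr.tsv
irongc greml    --grm scratch/kin --pheno scratch/resid.tsv \
                --pair hepcidin,ABI_rest --out scratch/rg.tsv
irongc bayes    --grm scratch/kin --pheno scratch/resid.tsv \
                --sweeps 30000 --seed 7 --out scratch/bayz
```

`snps.yaml` is a list of records with `snp_id`, `effect_allele`,
`hypothesized_direction` (`+`/`-`/`unknown`) and optional published `betas`.
GRM files use the GCTA binary format (`.grm.bin`/`.grm.N.bin`/`.grm.id`);
write one with `irongc.genio.write_grm_gcta`.

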