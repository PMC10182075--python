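# polyfactor

Latent genetic factor analysis of multi-trait GWAS summary statistics.

Many clinically distinct diseases — for example immune-mediated disorders
such as Crohn's disease, lupus and asthma — share genetic risk. Given only
per-variant summary statistics from k case/control GWAS, `polyfactor`

1. estimates the k×k **genetic covariance matrix** S (heritabilities on the
   diagonal, genetic covariances off it) and its sampling covariance V by
   **multivariate LD-score regression** with block-jackknife errors,
   E[z_a z_b] = √(N_a N_b)·cov_g·ℓ_j/M + intercept;
2. fits **confirmatory factor models** (traits = Λ·factors + residual) to
   (S, V) by weighted least squares, judged by CFI > 0.95 and SRMR < 0.10;
3. runs a **factor-level GWAS**: each variant's effect on every latent
   factor, plus the **Q_SNP heterogeneity χ²** testing whether the variant
   acts through the factors or directly on individual traits;
4. defines associated **genomic regions** (seed p < 1e-6, 250 kb gap rule,
   significant if p < 5e-8; HLA excluded) and merges them across factors;
5. decomposes each region into **conditionally independent signals**
   (COJO-style stepwise selection from summary data + reference LD,
   "all-but-one" conditional datasets, stopping rule p > 1e-4);
6. groups signals across factors by **Bayesian colocalization**
   (Wakefield approximate Bayes factors, five-hypothesis posterior,
   PP4 ≥ 0.9) and colocalizes them with expression/protein **QTLs**;
7. estimates direction of effect by **Wald-ratio Mendelian randomization**
   (β_outcome/β_exposure, delta-method SE), labelling genes predisposing or
   protective.

A synthetic-data generator with block-AR(1) LD and a known
trait×factor architecture provides ground truth for every stage; the
bundled nine-trait, three-factor study exercises the whole pipeline in
about two minutes on one CPU.

## Worked example

```python
from polyfactor import demo_config, run_pipeline

cfg = demo_config(seed=1, outdir="demo_out")
res = run_pipeline(cfg)

print(res.selection.report[["model", "cfi", "srmr", "passes_fit"]])
print("regions:", len(res.merged_regions),
      "signals:", sum(len(s.valid_datasets()) for s in res.signal_sets))
print("accuracy vs planted truth:", res.evaluation["accuracy"])
```

prints (seed 1):

```
      model       cfi      srmr  passes_fit
0  1-factor  0.527082  0.159135       False
1  2-factor  0.683983  0.144732       False
2  3-factor  1.000000  0.045640        True
3  4-factor  0.999873  0.173654       False
regions: 111 signals: 141
accuracy vs planted truth: 1.0
```

Only the three-factor model (gut / autoimmune / allergic) adequately
describes the genetic correlation structure. The 111 significant merged
regions decompose into 141 conditionally independent signals; comparing the
pipeline's specific-vs-shared locus calls, QTL colocalizations and MR
directions against the generator's truth table gives perfect accuracy on
this study. Outputs (munged tables, S/V matrices, model selection report,
factor GWAS, regions, colocalization and MR tables, run manifest) land in
`demo_out/`.

The same stages are exposed as a CLI:

```bash
polyfactor run --outdir demo_out --seed 1
polyfactor munge sumstats.CD.tsv reference.tsv munged.CD.tsv
polyfactor mr --exposure-beta 0.5 --exposure-se 0.05 \
              --outcome-beta 0.25 --outcome-se 0.05
```

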