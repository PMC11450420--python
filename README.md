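# careclust

Data-driven phenotyping of **clinical complexity** in youth primary
mental-health services, built for episode-of-care (EOC) records of the kind
collected by service minimum data sets: per-visit symptom scales, clinician
staging, diagnoses, presenting issues and psychosocial flags, alongside
demographics and service-use counts.

Routine clinical cohorts of this kind are confidential, so the package
ships a first-class synthetic cohort generator that plants a known latent
group structure; every analysis stage is validated against that ground
truth before it is pointed at real data.

## What it computes

1. **Indicator mapping.** Raw visit fields are mapped to 13 binary
   complexity indicators (very high distress K10 > 30, low functioning
   SOFAS ≤ 60, low quality of life, later illness stage, severe/complex
   disorder, self-harm presentation, AOD treatment issue, trauma history,
   housing issues, NEET, education/employment engagement issue, government
   benefits, co-occurring difficulties) with any-visit OR aggregation and
   an explicit missingness mask. Episodes missing *all* indicators are
   excluded, with full accounting.
2. **Multiple imputation.** Missing items are completed *m* times by
   chained equations (ridge-stabilised logistic conditionals on the other
   indicators), giving an imputation set for every downstream estimator.
3. **Consensus clustering over imputations.** For each completed dataset
   and each of *R* replicates, a random subsample is clustered by k-means;
   pairwise co-clustering counts normalised by co-sampling counts form the
   consensus matrix
   `M(i,j) = #co-clustered(i,j) / #co-sampled(i,j)`.
   Final labels come from an average-linkage cut of `1 − M`, ordered by
   mean indicator burden (cluster 1 = lowest complexity). The proportion of
   ambiguous clustering, `PAC = P(0.1 < M(i,j) < 0.9)`, guides — but does
   not dictate — the choice of k.
4. **Tetrachoric correlation network.** For each indicator pair, the
   latent bivariate-normal correlation ρ solves
   `Φ₂(τ₁, τ₂; ρ) = p₀₀` with thresholds from the margins; estimates are
   pooled across imputations on the Fisher-z scale and embedded in 2-d by
   classical multidimensional scaling for network plots.
5. **Multinomial regression.** Cluster membership is regressed on
   demographic risk factors via a baseline-category logit
   `log P(y=c)/P(y=1) = x'β_c`; coefficients are pooled by Rubin's rules
   (total variance `W + (1 + 1/m)·B`, Barnard–Rubin degrees of freedom) and
   reported as relative risk ratios (RRR) with 95% CIs.

## Worked example

```python
import json
import careclust as cc
from careclust.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    outdir="demo",
    generator=cc.GeneratorConfig(n_episodes=3000, seed=7),
    m=5, consensus_R=50, k=4, seed=7,
)
manifest = run_pipeline(config)
acc = json.load(open("demo/cohort_accounting.json"))
print("stages:", ", ".join(manifest["stages"]))
print("accounting:", json.dumps(acc))
```

prints

```
stages: simulate, map, filter, impute, cluster, network, model, report
accounting: {"n_total": 3000, "n_excluded": 408, "n_retained": 2592,
 "pct_excluded": 13.6, "clusters": {"1": {"n": 993, "pct": 38.3},
 "2": {"n": 682, "pct": 26.3}, "3": {"n": 505, "pct": 19.5},
 "4": {"n": 412, "pct": 15.9}}}
```

13.6% of episodes were excluded for missing every indicator (the
generator's default all-missing stratum is 14.1%), and the consensus
4-cluster solution splits the retained 2,592 episodes into a large
low-complexity group (38.3%) and three smaller groups — close to the
planted shares of 39.8 / 19.9 / 21.8 / 18.5%, with the residual gap coming
from consensus-label noise on deliberately overlapping default profiles.
The pooled model output reports, for example,

```
gender-diverse RRR (high vs low): 1.92 CI 1.08 - 3.41
```

i.e. at this small n the planted gender-diverse → high-complexity effect
(RRR 3.41) is recovered attenuated through noisy cluster labels; fitting
against the hidden labels at larger n recovers 3.41 itself (see the
acceptance checks).

The same pipeline is available from the shell:

```bash
careclust run-all --out demo --n 3000 --seed 7
careclust simulate --n 5000 --seed 1 --out cohort/
careclust map --cohort cohort/ --out mapped/
careclust cluster --imputations imps/ --k 4 --diagnose-k --out clustered/
```

Every artefact is plain delimited text or JSON: episode/visit tables,
indicator matrix with paired `__observed` columns, one CSV per completed
imputation, consensus matrix, labels, edge lists, layout coordinates,
RRR tables and a run manifest with seeds and settings.

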