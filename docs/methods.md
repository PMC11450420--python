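# Methods

This note documents the statistical machinery in `careclust`: the models
and algorithms, the parameters that matter (with defaults and the reasons
for them), what the synthetic cohort generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## 1. Analysis unit and indicator layer

The analysis unit is the **episode of care (EOC)** — a continuous period
of service engagement for one young person; people can contribute several
episodes. Thirteen binary complexity indicators are derived from per-visit
fields with a fixed **any-visit OR**: an indicator is 1 if its predicate
fires at any visit of the episode, 0 if its source was measured at least
once and never fired, and *missing* if the source was never measured.

Scale cut-points: K10 strictly greater than 30 (very high psychological
distress; K10 totals range 10–50), SOFAS of 60 or below (moderate-to-severe
functional impairment; 0–100), MyLifeTracker below 40 (low quality of
life; 0–100, higher is better). The MLT instrument has no canonical
clinical cut, so 40 is a package default exposed as `mlt_cut`, not a
constant. "Later stage of illness" is clinician staging at or beyond
stage 2 on the 1a/1b/2/3/4 ordinal (configurable via `stage_cut`); the
severe/complex-disorder set defaults to psychotic, bipolar, personality and
neurodevelopmental diagnoses and is likewise a configurable category list
rather than a hard-coded diagnostic coding. The indicator set as a whole is
a reconstruction from the available threshold definitions, not a verbatim
data dictionary.

Missing-versus-absent follows form-driven data collection: check-box style
flags are 0 whenever the visit form exists with the box unticked, while
scale-based indicators are missing when the scale was never administered.

Episodes with **all 13 indicators missing** are excluded before analysis;
the exclusion report always satisfies `n_total = n_excluded + n_retained`
and the filter is idempotent.

## 2. Multiple imputation

Missing indicator cells are completed by chained equations on the binary
indicator layer (the continuous raw measures are never imputed — the
analysis operates on indicators):

- conditional model: main-effects logistic regression of each incomplete
  item on the other 12 (plus optional complete covariates), with ridge
  penalty `1e-4` for stability on sparse items; a non-converging fit is
  retried at strong ridge with a logged warning;
- initialisation by observed-prevalence draws; **10 sweeps** in ascending
  missingness order; these are standard chained-equation practice;
- each conditional model is fitted on a **bootstrap resample** of the
  observed rows, so parameter uncertainty propagates into
  between-imputation variance (the "boot" flavour of approximately proper
  imputation). Without this the pooled intervals below would be
  anticonservative;
- **m = 20** completed datasets by default;
- one master seed with per-imputation substreams recorded in the output,
  so imputation is a pure function of (input, settings, seed);
- observed cells are never modified (asserted by tests).

**Rubin's rules.** For per-imputation estimates `q_i` with variances
`u_i`: pooled estimate `q̄ = mean(q_i)`, within-variance `W = mean(u_i)`,
between-variance `B = var(q_i)`, total `T = W + (1 + 1/m) B`. Confidence
intervals use a t reference with `df = (m−1)/λ²` where
`λ = (1+1/m)B/T`, or the Barnard–Rubin small-sample adjustment
`df = [df_old⁻¹ + df_obs⁻¹]⁻¹` when a complete-data df is supplied.
`B = 0` degenerates cleanly to a normal reference.

## 3. Consensus k-means over imputations

Single-run k-means on large binary data is unstable; the package
integrates consensus clustering with the imputation set:

- for each of the m completed datasets and each of **R = 100** replicates,
  subsample `⌈p·n⌉` episodes without replacement (**p = 0.8**) and run
  k-means (k-means++ initialisation, one start per replicate, indicators
  as 0/1 numerics, Euclidean metric);
- consensus `M(i,j)` = co-clustered count / co-sampled count. Pairs never
  co-sampled (vanishingly rare at these settings) receive the global mean
  consensus as an unbiased neutral fill, logged when it happens;
- final labels: average-linkage hierarchical clustering on `1 − M`, cut at
  k — the full ensemble decides the partition, not any single k-means run;
- clusters are then relabelled 1..k by increasing mean indicator burden
  (averaged over imputations), so label 1 is always "lowest complexity";
- an empty cluster in a base run triggers exactly one re-seed, after which
  a reduced effective k is accepted for that replicate — bounded retries
  keep runs deterministic given the seed;
- binary columns are not rescaled before k-means (all items already share
  the {0,1} scale); a switch exists for covariate-style use.

R = 100 and p = 0.8 follow the standard consensus-clustering recipe; they
are defaults, echoed into every run manifest, not tuned constants.

**Choosing k.** Per k, the proportion of ambiguous clustering
`PAC = share of off-diagonal consensus entries in (0.1, 0.9)` and the
consensus CDF are computed; the PAC-minimising k is *recommended* but the
pipeline records a separately *chosen* k, because model-driven criteria are
known to be weak guides at large n and the substantively informative
segmentation may differ from the PAC optimum. When even the best PAC stays
above 0.3 the diagnostics flag "no structure".

## 4. Tetrachoric correlation network

For each indicator pair the 2×2 table is modelled as a dichotomised
bivariate normal: thresholds from the margins via the inverse normal, and
ρ the value at which the bivariate rectangle probability matches the
observed joint cell — equivalently the maximum-likelihood ρ for fixed
margins, found by Brent root-finding to `1e-10`. Rectangle probabilities
are evaluated through Owen's T function, accurate to near machine
precision. Zero cells are corrected by adding 0.5 to every cell; estimates
are clamped to ±0.999; a margin that is degenerate even before correction
yields an explicit missing value. The test suite cross-checks the
estimator against an independent brute-force likelihood grid (step 1e-4)
whose rectangle probabilities are built by integrating the bivariate
density over ρ.

Per-imputation matrices are pooled on the **Fisher-z scale** (variance
stabilisation; standard for correlation pooling); a pair undefined in more
than half the imputations is flagged missing. The network layout is
**classical (Torgerson) MDS** on `d = √(2(1−ρ))` after a
nearest-positive-semidefinite eigenvalue-clipping repair (a repair that
moves any entry by more than 0.1 is logged); classical scaling is used
because the target visualisation is an explicit multidimensional-scaling
plot, not a spring embedding. The layout is centred and its reflection
fixed (item 1 non-negative). Note that a 13-item all-positive correlation
matrix genuinely spreads over more than two dimensions, so the 2-d layout
is a visual summary: its stress-0 on the default cohort is ≈ 0.5, and the
package exports the full ρ matrix alongside the coordinates, leaving any
display thresholding to plotting code.

## 5. Multinomial model of cluster membership

Cluster membership (reference: cluster 1, lowest complexity) is regressed
on categorical risk factors — gender (reference female), age group,
Indigenous status, CALD background, and socio-economic tertile by
remoteness entered as a **full interaction** (the two are considered
jointly; a config switch drops the interaction). Dummy encoding with
declared reference levels, no standardisation.

Estimation is full Newton maximisation of the baseline-category-logit
likelihood with step-halving (the log-likelihood never decreases), to a
gradient infinity-norm below `1e-8` plus one polishing step; covariance is
the inverse observed information. Suspected quasi-separation (a
coefficient beyond ±15) triggers a ridge `1e-6` retry with a warning.
Exponentiated coefficients are relative risk ratios; a ratio r is rendered
as a `(r−1)·100%` change.

Cluster labels enter the regression **fixed** from the consensus solution
(one reported partition), and the demographic covariates are complete, so
the default specification needs a single fit, reported as a degenerate
pool; when imputed indicator columns are added to the design the model is
fitted per completed dataset and pooled coordinate-wise by Rubin's rules
on the log-RRR scale.

## 6. The synthetic cohort generator

The generator emulates a youth mental-health minimum data set with planted
structure; its defaults are the package's study conditions:

- four latent complexity groups with shares **(0.398, 0.199, 0.218,
  0.185)** and mean visits per episode **(4.0, 4.0, 2.9, 7.1)**; visit
  counts are 1 + negative binomial with dispersion 1.5, matching a
  right-skewed distribution with mean ≈ 4 and median ≈ 2;
- within-cluster indicator prevalences are **stylised profiles**
  reconstructed from the qualitative cluster descriptions (within-cluster
  percentages were never published): the low group sparse everywhere, the
  distress group high on distress/QoL/functioning, the psychosocial group
  additionally high on housing/NEET/education-employment/benefits, the
  high group adding later stage, severe disorder, trauma and co-occurring
  difficulties;
- a Gaussian copula adds within-cluster residual dependence
  (distress–low-QoL ρ = 0.45; the four psychosocial-stressor items
  ρ = 0.30) while preserving the profile marginals exactly — without it,
  conditional independence within clusters would make the severity block
  dominate the correlation network, which contradicts how strongly
  distress and quality of life co-vary in practice;
- demographic effects are multinomial-logit tilts of cluster membership
  (per level, a length-K log-relative-risk vector with cluster 1 as
  reference); the headline planted effect is gender-diverse →
  high-complexity at log 3.41. Intercepts are re-calibrated by fixed point
  so that the *marginal* cluster shares still equal the configured
  proportions — calibration shifts only the constant, so the planted
  log-RRRs remain exactly recoverable by the regression stage;
- continuous measures use **inverse-threshold sampling**: the episode's
  binary state is drawn first, then K10/SOFAS/MLT values are sampled
  uniformly from the matching side of the cut-point at every visit, and
  flag/categorical indicators force at least one firing visit when the
  state is 1 — so the indicator mapping reproduces the planted states
  exactly, by construction;
- services: 113 centres whose cluster mixes are Dirichlet draws with
  concentration `centre_mixing × shares` (default 10, giving wide
  across-centre prevalence ranges); a `centre_mixing → ∞` limit makes all
  centres identical;
- missingness: a **14.1%** all-missing stratum (the excluded fraction) and
  independent item-level missingness at 10% by default, MCAR, with a MAR
  option that multiplies the missingness odds for one observed covariate
  level;
- the generator is a pure function of its config including the seed;
  cohorts round-trip through CSV + YAML.

A `well_separated_profiles(k)` helper supplies profile matrices whose
pairwise mean absolute probability gap is ≥ 0.5 (binary codewords with
Hamming distance 8 over the first 12 indicators); recovery and k-selection
experiments use these so that the planted partition is unambiguous.

**What the generator does not emulate:** real geographic structure
(IRSAD/remoteness are sampled labels, not postcode lookups), DSM code
lists and free text, informative visit-level missingness, temporal change
within episodes, and person-level correlation beyond shared identifiers
for repeat episodes. Passing tests therefore demonstrate that the
machinery recovers known structure under these idealised conditions — not
that any particular real cohort has four clusters.

## 7. Problem sizes and numerical conventions

Tests and the acceptance script run deliberately scaled-down experiments
chosen to exercise every code path with tight Monte-Carlo bounds: cluster
recovery at n = 4,000 (m = 5, R = 50), k-selection at n = 900 over five
replicates per planted k, pooled-CI coverage over 200 replicates at
n = 400, planted-RRR coverage over 100 replicates at n = 10,000,
tetrachoric error over a ρ × margin grid at n = 2,000. Percentages in all
report tables are recomputed from integer counts and rendered to one
decimal, half-up. All randomness flows from explicit seeds through
`numpy` seed sequences; identical configs reproduce byte-identical
artefacts.

## 8. Known limitations

- Chained-equation imputation with bootstrap refitting is approximately,
  not exactly, proper; with very high missingness the pooled intervals can
  still be slightly narrow.
- The consensus matrix is dense (n × n); beyond ~30k episodes memory
  becomes the binding constraint and a chunked/sparse accumulation would
  be needed.
- PAC is a heuristic: on overlapping profiles it can prefer a coarser k
  than the generative truth, which is precisely why the chosen k is
  recorded separately from the recommendation.
- The multinomial model treats consensus labels as fixed; classification
  noise in the labels attenuates covariate effects (visible in the README
  example), as it would in the real analysis.
- Standard errors ignore centre-level clustering by design (plain
  multinomial models are reported).
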