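# Methods

## Model and rationale

`poolmark` evaluates the prognostic association of an expression marker
across heterogeneous cohorts without ever comparing expression values
between cohorts. For each cohort the marker is dichotomized on that
cohort's own distribution; the resulting high/low labels — not the
values — are pooled, and the pooled two-group cohort is analysed with
standard survival machinery. The design assumption is that a marker's
*rank* within a cohort is comparable across platforms even when its
measured value is not. The monotone-invariance property (identical
labels, hence bit-identical downstream statistics, under any strictly
increasing per-cohort transform) is the formal version of this
assumption and is tested end to end.

The pooled model is deliberately simple: one two-group Cox model (and
log-rank test) over the concatenated records, unstratified by default.
This treats all cohorts as sharing a baseline hazard; a per-cohort
baseline (`stratify_by_dataset=True`) is available when that worries
you. Covariates are used to *filter* cohorts (e.g. restrict to
lymph-node-negative, ER-positive patients), never as regression
adjustments — the question answered is always "does the high group fare
worse in this patient stratum", not a multivariable attribution.

## Dichotomization conventions

- Rules: `median` (high iff value > within-cohort median),
  `upper_quartile` (high iff > 75th percentile; top quarter vs rest),
  `lower_quartile` (low iff < 25th percentile; bottom quarter vs rest).
- Quantiles are linear-interpolation quantiles of the non-missing
  values (numpy's default estimator); this choice is covered by a
  brute-force quantile oracle test.
- Ties at the cut-off go to the majority side: strictly "greater than"
  defines the high group (so a constant vector is all-low), and
  symmetrically for the lower-quartile rule.
- Missing expression excludes a sample from both the cut-off computation
  and the pooled cohort. Fewer than two non-missing values is an error.
- With a clinical filter, cut-offs are computed within the filtered
  sub-cohort by default (`cutoff_scope="filtered"`); computing them on
  the full cohort first (`"full"`) is provided as an option because the
  order of filtering vs dichotomization is a genuinely open design
  choice, and the two differ.
- Multi-marker combination (`all_high` / `all_low`) requires unanimity
  across markers; any per-marker exclusion excludes the sample. A cohort
  contributes only if it measures *all* queried markers, so the combined
  group means the same thing in every contributing cohort.

## Survival statistics

- Kaplan-Meier: the product-limit estimator per group, with subjects
  censored at an event time counted at risk at that time.
- Log-rank: at each distinct event time, observed minus hypergeometric-
  expected events in the high group and the hypergeometric variance;
  χ² = (Σ O−E)² / Σ V, p from χ²₁. This log-rank p is the headline
  p-value of every query.
- Cox: a single binary covariate (high vs low), Efron correction for
  tied event times, maximized by one-dimensional Newton iteration to a
  step tolerance of 1e-12 (a handful of iterations; the step is clipped
  at ±2 for safety, and |β| > 15 is treated as monotone likelihood).
  The group is coded ±1/2, which makes the swapped-label partial
  likelihood the exact floating-point mirror of the original: swapping
  high and low returns exactly the reciprocal hazard ratio, and
  rescaling all times — which the partial likelihood sees only through
  ordering and ties — leaves β̂ bit-identical. Wald 95% CI and p
  accompany the estimate. Complete separation (all events in one group)
  yields a flagged result with an infinite-bound CI, not an exception.
  The implementation is cross-checked against an independent general
  Cox implementation (lifelines) in the test suite.
- Times are months and are never rescaled internally. No multiple-testing
  correction is applied within a single-marker analysis; a
  Benjamini-Hochberg utility (`adjust_pvalues`) is available for sweeps
  and is off by default.
- Degenerate inputs: an empty group, zero events, or a single-group
  cohort after exclusions raise descriptive errors rather than returning
  numbers.

## Subtype classification

Nearest-centroid, single-sample: restrict to genes measured in both the
sample and the centroid table, correlate the sample vector with each
subtype centroid, assign the argmax. Spearman correlation is the default
(calls are then invariant to monotone transforms of the sample, matching
the package's rank-based philosophy); Pearson is available per model.
Guards: fewer than `min_genes = 10` shared genes, or a best correlation
≤ 0, yields `unclassified` — a conservative rule, documented rather than
matched to any particular published implementation's internal scaling.
Correlation ties break deterministically by the model's subtype column
order. Centroid tables are data, not code: the published ssp2003 /
ssp2006 / PAM50 tables load from the documented TSV schema (first column
`gene_id`, one column per subtype); the repository ships only synthetic
fixture models with three distinct geometries for testing.

Subtype labels are sample-intrinsic, so a stratified query classifies on
the full cohort first and filters afterwards.

## Consensus sweeps

A sweep evaluates genes × endpoints × cut-offs under each supplied
classifier within a chosen subtype. A cell is consensus-significant when
the log-rank p is **strictly** below α in at least `min_classifiers` of
the attempted classifiers (defaults 0.05 and 2, i.e. two-of-three).
Cells that fail (endpoint absent in every cohort, single-group basal
subset, ...) are recorded as explicit NA cells, so the consensus counts
attempted classifiers only.

## miRNA host-gene proxies

Intragenic miRNAs are queried through their host gene's expression. The
miRNA→host map is user-supplied data pinned to a miRBase/Ensembl release
(TSV: `mirna_id`, `gene_id`); no live lookup. Multi-host miRNAs produce
one result per measured host rather than an averaged proxy, since
averaging across hosts has no defensible interpretation. Every result
carries `host_gene_proxy=True`: the inference assumes miRNA/host
co-expression, which holds for many but not all intragenic miRNAs.

## Data model and file formats

Expression: TSV, first column `probe_id`/`gene_id`, header row sample
ids, missing token `NA`, log-scale normalized values. Probe-level
matrices are gene-centered by dropping probes that map to more than one
gene and averaging multiple probes per gene arithmetically on the stored
log scale (per sample, over non-missing values) — averaging on the log
scale matches the scale on which the inputs arrive. Clinical: TSV with
`sample_id` plus any of `age, size_cm, ln_status, er_status, pr_status,
her2_status, grade, chemo, hormone` and `{dfs,ddfs,os}_{time,event}`.
Enumeration synonyms are folded (`positive/1/+ → pos`, etc.); unknown
tokens, out-of-range grades, and endpoint half-pairs become missing with
a logged warning, never an error. A YAML/JSON manifest lists cohorts.
Cohort inclusion policy (`validate_dataset`): at least 48 samples and at
least one survival endpoint — a curation threshold exposed as a
parameter, not mathematics.

## The simulator

`simulate_collection` emulates the structure that matters to the
pipeline, not array chemistry:

- **Cohort heterogeneity**: per-cohort affine (optionally monotone
  nonlinear, arcsinh-based) distortions of a common latent Gaussian
  expression scale, so raw values are incomparable across cohorts —
  precisely the situation the rank-based design is built for.
- **Survival**: exponential event times at baseline hazard 0.01
  events/month (median event time ≈ 69 months, the follow-up scale of
  typical breast-cancer cohorts). For each designated prognostic gene,
  samples above their cohort's median draw times at hazard h·HR; the
  designed HR is therefore exactly the estimand of the dichotomized
  analysis. A secondary log-linear continuous-effect mode exists for
  realism checks. Censoring is administrative-uniform on [0, τ], τ
  solved so the expected censored share at baseline hazard matches the
  requested fraction (default 0.30).
- **Defaults**: five cohorts of 48–204 samples (sizes spanning the
  inclusion boundary), 100 genes, one prognostic gene at HR 2.0,
  endpoint availability varying across cohorts (all have DFS; OS/DDFS
  in subsets), clinical covariates at breast-cancer-typical prevalences
  (ER+ 70%, PR+ 60%, HER2+ 15%, LN+ 45%, grades 20/45/35%) with 10%
  missingness per field.
- **Subtype design**: optional centroid model + mixing proportions +
  noise sd (default 0.5); centroid fixture genes live in their own
  namespace (`cg****`) so the subtype block never overwrites a
  designated prognostic gene.
- Everything is reproducible from the config seed; `write_fixture`
  emits the exact on-disk formats with full-precision round-trip.

What the simulator does **not** model: probe-level noise structure,
correlated gene-gene expression beyond the subtype block, non-constant
hazards, informative censoring, or clinical covariates correlated with
outcome. Passing tests therefore demonstrate the pipeline's statistical
correctness under its stated assumptions, not robustness to violations
of proportional hazards or to expression/covariate confounding in real
cohorts.

## Problem sizes in the test and acceptance runs

Oracle comparisons use 1,000 random cohorts of n ≤ 12 with forced ties.
Hazard-ratio recovery uses 200 replicates of the designed study (5
cohorts × 400 samples, pooled n = 2000, 30% censoring) with 5 simulated
genes per replicate; the type-I-error run uses 500 seeds of a 5 × 60
study with 3 genes — gene counts are kept small because only the queried
gene enters the statistics. Subtype recovery uses 300 samples per
geometry at noise sd 0.5 (and 60 at zero noise).

## Known limitations

- Dichotomization discards within-group expression information; the
  package deliberately offers no continuous-effect or optimal-cut-point
  analysis.
- The unstratified pooled model assumes a shared baseline hazard;
  cohorts with very different follow-up intensity can distort the pooled
  estimate (use the stratified option).
- Numerical equivalence with any specific published subtype classifier
  implementation is not claimed; equivalence is demonstrated on fixture
  models only.
- The miRNA layer inherits every caveat of host-gene proxying.
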