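# Methods

This note documents the statistical models implemented in `epidrift`, the
synthetic-data generator that the test suite runs them against, and the
design choices made where conventions genuinely diverge.

## Age-DMP model

For each probe the DNAm beta value is regressed on age by ordinary least
squares, `beta_ij = a_j + b_j age_i + c_j' x_i + e_ij`, with covariates
`x_i` taken from the sample annotations (categoricals are expanded to
indicator contrasts dropping one level). The age coefficient's t-statistic
is referred to a Student-t null with the residual degrees of freedom;
p-values are two-sided, since both age-hypermethylation and
age-hypomethylation are real and common. Betas are modelled untransformed —
the convention in the EWAS literature this package serves — and slopes are
therefore in beta units per year; the widely used effect-size threshold
0.002/yr corresponds to a 2% DNAm change per decade. Probes with zero
residual variance keep their fitted slope but are flagged degenerate with
p = 1, and degenerate probes are never selected as aDMPs; they do remain in
the multiple-testing denominator, so Bonferroni levels match per-dataset
probe counts.

Multiple-testing adjustment fills `bonf_p = min(1, p·n)` and Storey
q-values: π0(λ) = #{p > λ}/(n(1−λ)) on the grid λ = 0.05…0.95 (step 0.05)
is extrapolated to λ→1 by a cubic least-squares smoother evaluated at
max(λ) and clipped to [0, 1]; then q(i) = min_{j≥i} π0·n·p(j)/j over the
p-ordered probes. `1 − π0` is reported as the genome-wide drifting
fraction. All significance thresholds are strict (`q < α`, `p_bonf < α`,
`|b| > τ`), mirroring the "< 0.05" convention.

On the null (a drift-free simulation with 10,000 probes and 200 samples)
the per-probe type-I error sits at the nominal 5% and π0 estimates fall
above 0.95; with 30% of probes drifting at realistic effect sizes and
n = 500, `1 − π0` recovers the simulated fraction within ±0.05. These are
measured by the acceptance tests, not assumed.

## Overlap, concordance and the shared-drift fraction

Overlap significance is the upper-tail hypergeometric probability
P(X ≥ |A∩B|) with X ~ Hypergeom(universe, |B| successes, |A| draws); the
universe defaults to the intersection of the datasets' probe universes. For
three sets the seven exclusive Venn regions are reported with pairwise
hypergeometric p-values, and the triple overlap gets a *nested* test that
conditions on the observed pairwise intersection: X ~ Hypergeom(universe,
|C| successes, |A∩B| draws), evaluated at |A∩B∩C|. The nested construction
is this package's interpretation — the triple-overlap test is not uniquely
defined by its name — and is isolated in a single function so an
alternative can be swapped in; the pairwise tests are unambiguous.

Directional concordance restricts to discovery aDMPs present in both probe
universes, keeps those reaching a validation p threshold (default 0.05),
cross-tabulates the signs of the two t-statistics, and applies a one-tailed
Fisher exact test for enrichment of sign agreement. Probes with t exactly 0
are excluded from the sign table (a deterministic rule for a measure-zero
case); discovery aDMPs failing validation are counted separately rather
than entering the 2×2.

The shared-drift fraction estimator inverts the generator's sharing model:
if an age-affected probe is shared by all C cell types with probability s
and otherwise specific to one of the C uniformly, the fraction v of
discovery aDMPs that validate in a second cell type satisfies
v = s/(s + (1−s)/C), hence s = v/(C − (C−1)v). At high power, with a
confident (Bonferroni) discovery set, FDR-based validation and a
sign-agreement requirement, the estimator recovers a simulated s = 0.70
within ±0.03; the residual bias is downward (finite validation power) and
shrinks with sample size.

## Empirical subsampling power analysis

A gold-standard aDMP set is defined on the full dataset (fit → adjust →
select). For each subsample size and Monte-Carlo run, a simple random
sample of individuals is drawn without replacement, the identical model is
refitted, significance is re-adjusted *within* the subsample (the q-value
procedure is applied to the subsample's p-values; the Bonferroni
denominator is the probe count, which subsampling does not change), and
sensitivity |detected ∩ gold|/|gold| is recorded. Per-(size, run) seeds
derive from the base seed by a fixed counter scheme, so curves are
bit-reproducible and runs parallelise deterministically. Subsampling is
unstratified, with stratification available only through covariates in the
refitted model. The characteristic contrasts — steeply rising
Bonferroni/FDR curves versus an almost flat effect-size-only curve, and the
conjunction criterion bounded by Bonferroni pointwise — are asserted by the
acceptance tests at 10,000 probes, n = 600, sizes 50–500 and 5 runs per
size, a scale chosen to exercise the full machinery on a desk machine.

## Reference construction and deconvolution

Markers are derived from sorted (purified) profiles by a moderated
two-group t-test: per-probe pooled variances are shrunk toward a prior via
empirical Bayes, with the prior degrees of freedom estimated by method of
moments from the across-probe dispersion of the pooled variances (under the
scaled-F marginal, CV²(s²) = 2(d + d0 − 2)/(d(d0 − 4)), solved for d0) and
the posterior variance (d0·s0² + d·s²)/(d0 + d) referred to d + d0 degrees
of freedom. A plain Welch t-test is available as a fallback switch. Probes
pass if the Bonferroni-adjusted p is below 0.05 *and* the raw group-mean
difference is at least 0.70 in absolute value — the Δβ filter is inclusive
("at least a 70% difference") and is applied to raw means, not shrunken
ones. Reference entries are group means at the markers.

Cell fractions are estimated per sample by non-negative least squares of
observed marker betas on the reference profiles, renormalised to sum to
one. This constrained projection is deliberately simple and deterministic:
it is intended to produce covariates for age models, and is a stand-in for
— not a re-implementation of — robust-partial-correlation deconvolution
methods. On simulated Dirichlet mixtures (200 markers, 3 cell types, Beta
noise precision 100) it recovers fractions with RMSE well under 0.05.

## Cell-type heterogeneity and when adjustment helps

With genome-wide baseline divergence between cell types, fluctuations in
sample composition inject variance into every probe of a bulk profile.
When composition varies widely but correlates only weakly with age,
including (estimated or true) cell fractions as covariates removes that
variance and raises sensitivity at fixed FDR — the regime the property
tests assert. When composition is *strongly* confounded with age, the
unadjusted model instead floods the FDR list with composition-driven false
positives; because the q-value threshold is adaptive, this can inflate the
unadjusted model's apparent sensitivity while destroying its false-positive
control, and adjustment then trades apparent sensitivity for validity.
Both regimes are reproducible with the generator's `mixture_age_trend` and
`baseline_divergence_sd` parameters.

## The synthetic-data generator

The generator emulates the data regimes this kind of analysis meets:

- **Baselines.** Per-probe means come from a three-component mixture (40%
  unmethylated ~ Beta(2,40), 20% intermediate ~ Beta(10,10), 40% methylated
  ~ Beta(40,2)), matching the bimodal 450k/EPIC landscape. Cell types share
  these baselines up to a mild logit-scale divergence (SD 0.30 by default)
  plus a configurable fraction (5%) of marker probes with large Δβ
  (low 0.03–0.08 vs high 0.88–0.96), which is what makes reference
  construction and composition confounding possible.
- **Age effects** are applied on the logit scale and mapped back:
  logit(m) = logit(μ) + b·(age − midpoint) + batch + sex effects. Logit
  slopes default to 0.005–0.02 per year with balanced signs, i.e. roughly
  1–5% DNAm per decade at intermediate methylation — the typical magnitude
  of epigenetic drift — and effects compress toward zero near the bounds,
  which is exactly what produces the effect-size selection bias the
  pipeline diagnoses. Centring age at the range midpoint decouples slope
  from intercept. A probe is age-affected in all cell types with
  probability `share_probability`, otherwise in exactly one.
- **Mixtures and noise.** Samples are Dirichlet mixtures of the cell types
  (purified datasets use one-hot weights); observed betas add Beta noise
  with fixed precision (variance x(1−x)/(1+ν)), so dispersion shrinks near
  0/1 without clipping artefacts — heteroscedasticity by construction, not
  truncation. Ages are uniform on the configured range (default 22–84,
  the span of the purified-blood cohorts this emulates); sex, batch and an
  optional age trend in the mixture weights provide confounders; matched
  multi-tissue designs reuse the same individuals across tissues.
- **Reproducibility.** Every draw comes from a named substream of one
  global seed (seed + hashed stream label via `numpy` SeedSequence), so
  output is byte-identical across runs and independent of iteration order.

What the generator does **not** emulate: probe-level genomic structure
(neighbouring-CpG correlation, islands/shores), SNP-affected probes, array
batch chemistry (type-1/type-2 probe bias), detection-p physics beyond a
uniform failure mask, non-uniform age distributions, and genuinely
nonlinear age trajectories. Passing tests therefore demonstrate that the
statistical machinery is correct and calibrated under a faithful
heteroscedastic bounded-signal model — not that any particular real-data
estimate is right; the headline fractions from real cohorts additionally
depend on normalisation, confounder completeness and array coverage.

## QC and imputation

Coverage QC follows the probe-then-sample order: probe coverage (fraction
of samples with detection p < 0.05) is computed first and probes below 0.99
are removed; sample coverage is then recomputed over surviving probes and
samples below 0.95 removed. Comparisons are strict, so items exactly at a
threshold are kept. The pipeline fixes the order QC → imputation. Missing
values are imputed from the k = 5 nearest probes by Euclidean distance over
pairwise-complete samples, each hole filled with the mean of the
neighbours' observed values in that sample; observed values are never
altered, and probes missing more than half their values (or everything) are
rejected rather than imputed.

## Panel sharing

For a fixed CpG panel, each dataset contributes sign(t)·(−log10 p) and an
aDMP flag taken from its *genome-wide* q-values at FDR < 0.05 — the
per-dataset analyses being summarised are genome-wide, so the FDR is not
re-run within the panel. CpGs absent from a dataset's array are recorded as
not assessed, distinct from not significant (a strict mode counts them as
not significant instead). Sharing counts (datasets flagged) and the
cumulative proportion of the panel shared in ≥ k datasets follow;
"cell-type specific" is operationalised as a sharing count of exactly 1.

## Numerical and engineering choices

- Baseline means are clipped to [1e-4, 1−1e-4] before the logit; mixture
  means to [1e-6, 1−1e-6] before Beta noise.
- Degenerate-probe detection uses a residual-variance tolerance of 1e-12.
- q-value ties are handled by a stable mergesort; kNN neighbour ties break
  by probe order (stable sort), which the brute-force test oracle mirrors.
- The pipeline validates its entire YAML config (a hand-written pre-flight
  checker) before executing any stage, persists the config verbatim beside
  the outputs, and derives all stage randomness from the single top-level
  seed; re-running an identical config reproduces every analysis output
  byte for byte (the manifest's wall-clock durations excepted).
- Problem sizes in the test and acceptance suites (10,000-probe genomes,
  cohorts of 200–600, 5-run power curves) are the package's desk-scale
  defaults: large enough for calibration and recovery claims to be
  meaningful, small enough to run anywhere. Array-scale inputs (480k
  probes, thousands of samples) use the same code paths.

## Known limitations

- The nested triple-overlap test and the concordance 2×2 margins are
  declared interpretations of under-specified conventions (see above).
- The moderated t-test uses a method-of-moments prior rather than the
  marginal-likelihood fit of dedicated differential-methylation packages;
  for the large-Δβ markers it serves, the decisions coincide.
- The shared-fraction estimator assumes the generator's sharing model
  (all-or-one); graded sharing across subsets of cell types would need a
  richer model.
- π0 estimation inherits the known sensitivities of FDR machinery to
  unmodelled confounding; the package mitigates by making covariate and
  cell-fraction adjustment first-class, not by changing the estimator.
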