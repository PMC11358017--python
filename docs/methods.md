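# Methods

## Scope and data model

The package analyses k independent responder/non-responder comparisons
drawn from heterogeneous transcriptomic cohorts that share a mapped gene
universe. Each cohort is a genes × samples matrix of log2 expression with a
binary response label; cohorts with more than two response strata
contribute each responsive-vs-nonresponsive-type pairwise comparison as a
separate `ComparisonResult`. Cross-species ortholog mapping is out of
scope: real inputs are expected to arrive on a shared namespace (a
user-supplied two-column mapping table can produce one), and the simulator
emits a single namespace directly.

## Per-cohort differential expression

Fold change is `mean(log2 expr | nonresponder) − mean(log2 expr |
responder)`, so positive values mean "up in non-responders" — the
direction of interest throughout.

The default statistic is the empirical-Bayes moderated t. Gene-wise pooled
variances `s_g²` (residual df `d_g = n1 + n2 − 2`) are shrunk toward a
prior: `s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g)`, and `t = log2FC /
(s̃_g·sqrt(1/n1 + 1/n2))` is referred to Student t with `d0 + d_g` df
(standard normal when `d0 = ∞`). The prior `(d0, s0²)` is estimated by
matching the first two moments of `log s_g²` against a scaled-F model:
with `e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`, the excess of `var(e)` over
`mean(ψ'(d_g/2))` determines `d0` by trigamma inversion (Newton), and the
mean determines `s0²`. When the observed dispersion does not exceed the
trigamma floor, `d0 = ∞` is reported; when all variances are exactly
equal, `s0²` is that common value. At `d0 = 0` the statistic reduces
exactly to the classical pooled two-sample t, which the tests verify
against an independent implementation.

Degenerate zero-variance genes are floored at the 1st percentile of
positive gene variances and flagged, keeping them in the rank universe
with a finite statistic. A Welch t with Satterthwaite df is provided as an
assumption-free alternative; its null p-values are verified uniform by
simulation. One-tailed p-values (`p_one_up`, upper tail) feed the Fisher
combination.

Labels are taken as given: deriving response groups from e.g. growth
curves is a study-design step, not a statistical one.

## Rank-product meta-analysis

Each comparison is ranked by descending log2 fold change (rank 1 = most
upregulated in non-responders; ties get average ranks). The primary
statistic is the geometric mean of relative ranks, `rho_g = (Π r_{g,i} /
n_i)^{1/k_g}`, which combines cohorts with unequal gene counts coherently;
the raw integer product `Π r_{g,i}` is reported alongside and is the
statistic of the exact null. Genes absent from some comparisons are kept
if present in at least `min_studies` (default: all), with a
`k_g`-specific null.

### Null p-values

Three routes, certified against each other:

* **Exact** (`rp_pvalue_exact`): `P(Π R_i ≤ q)` for independent uniform
  integer ranks, by dynamic programming on distinct partial products with
  pruning above the threshold. Guarded by an enumeration budget (default
  10⁷ tuples); the reference for everything else. Defined on integer
  ranks, so tied (average) ranks route to the other methods.
* **Gamma approximation** (`rp_pvalue_gamma`, production default): under
  the null `−log(r_i/n_i)` is approximately Exponential(1), so the sum is
  approximately Gamma(k, 1). The discrete tail count is approximated by
  the volume of the half-unit-shifted rank box `Π [1/2, n_i + 1/2]` below
  the cutoff `q + 1/2`, evaluated as 2^k Gamma(k, 1) tails by
  inclusion–exclusion over box corners — the half-unit shift is the
  discreteness correction. When the smallest comparison has `n_i ≤ 256`,
  the sum over that comparison's integer ranks is taken exactly and only
  the remaining k−1 dimensions are approximated; this semi-discrete form
  is exact for k ≤ 2 and accurate to ~0.013 absolute over all rank tuples
  at `n_i = 8, k = 3` (exhaustively certified in the tests, alongside a
  Monte-Carlo cross-check at larger n). A plain half-offset gamma tail on
  `−Σ log((r_i − 1/2)/n_i)` was considered first but cannot track the
  discrete tail at small n (its k = 1 error is 1/(2n) by construction),
  so the corner-volume form replaced it; at large n the two agree.
* **Permutation** (`rp_pvalue_permutation`): seeded Monte-Carlo with the
  add-one estimator `(1 + #{rho* ≤ rho})/(B + 1)` and its binomial SE;
  in the pipeline, one null sample is shared by all genes with the same
  comparison pattern.

### Multiplicity and the parallel Fisher route

BH step-up adjustment is implemented directly (cross-checked against
statsmodels in the tests); Storey q-values with a single-λ π₀ estimate are
available behind a flag. Separately, per-cohort one-tailed p-values are
combined with Fisher's method (`X = −2 Σ ln p_i ~ χ²(2k)`); zero p-values
are floored at 1e−300 and flagged rather than erroring. Both routes are
reported side by side — they answer slightly different questions (rank
consistency vs evidence pooling) — and the headline ordering follows
`rho`. The metabolic GMT filter is applied after inference by default
(p-values are not recomputed on the subset; a flag moves the filter before
BH), and the final meta-rank is a total order: ascending `rho`, ties
broken by p and then gene id.

## Synthetic cohorts

The generator emulates the shape of a four-cohort ICB-response screen:
Gaussian log2 expression (the statistics consume log values and ranks, so
count-level simulation adds nothing the rank product can see), a per-gene
baseline `N(6, 2)` shared across cohorts, a per-study per-gene batch
offset `N(0, 0.5)` mimicking platform/species differences (it shifts both
arms equally, so cross-study rank agreement is driven only by true
effects), unit residual noise per measurement, and optional
detection-floor dropout (default off). Spiked genes are shifted up in
non-responders by a per-study log2 effect δ; the `TruthTable` records
exactly the spiked genes and the metabolic flag. The packaged default
configuration has 4 cohorts of 10 vs 10 samples over a 10,000-gene
universe with a 1,321-gene metabolic subset; the per-arm size of 10 is a
realistic small-cohort choice (the original mouse cohorts' arm sizes are
not published). The generator is seeded and bit-reproducible.

What passing tests on this generator do *not* show: robustness to
count-level mean-variance relationships, sample-level outliers or
confounded batch/response designs — none of which the rank product is
designed to repair.

The dose-response generator draws `baseline + Emax·c^h/(EC50^h + c^h) +
N(0, sd)` at a half-log concentration ladder (default 8 steps, 1 nM–10 µM,
the conventional span for a purinergic agonist assay), with sd 0.05 and 3
replicates as defaults matching plate-reader practice.

## Immune-context statistics

Signature scores are per-sample means of gene-wise z-scores over the
signature genes present (constant genes contribute 0; missing genes are
counted and reported). The scoring is invariant to gene-wise affine
rescaling, which is the property that matters when mixing platforms.
Dichotomization uses cohort medians with strict inequalities: stratum 1 is
A-score > median(A) and B-score < median(B), stratum 2 the converse, all
other samples excluded — with independent scores roughly half the cohort
drops out, which is why published strata of this kind have unequal sizes.
The packaged macrophage/CD8 signatures are synthetic placeholders
(marker-style symbols) for wiring and tests, not curated lists; real
analyses must supply their own GMTs. Between-stratum comparison is an
unpaired two-tailed pooled-variance t-test. Cross-dataset correlation
treats datasets as observations (pairwise-complete, ≥ 3 required) with
Pearson or Spearman options. Dot-plot summaries min–max scale group means
to [0, 1] per gene (single group ⇒ 1 by convention; optional 0/1
thresholding at 0.5) and report the fraction of samples with expression
above a configurable threshold (default 0).

## Dose-response quantification and Hill fitting

A calcium trace is reduced to `(max post-stimulus ratio − mean
pre-stimulus ratio) / ionomycin amplitude` (≥ 5 pre-stimulus samples
required; non-positive ionomycin amplitude is an error). Hill fits
optimize EC50 on the log10 scale with a 7-point log-spaced multi-start
spanning the observed concentrations (trf least squares, bounds:
log10 EC50 within ±3 of the data range, h ∈ [0.3, 4], Emax ∈ [0, 1.5]);
the best candidate by residual sum of squares is returned with a
convergence flag. The baseline is fixed at 0 by default because responses
are already baseline-subtracted; the Hill coefficient is free by default
(a `fix_h` option exists — with only 8 concentrations a free slope is at
the edge of identifiability, which is why the non-identifiability flag
`SE(EC50)/EC50 > 1` and the extrapolation flag (EC50 more than one log
unit outside the data) are part of the result). Standard errors are
asymptotic (Jacobian-based, delta method for the linear-scale EC50).
Potency ratios are compared on the log scale with errors combined in
quadrature. Fits use all replicate points by default (an option fits
per-concentration means). Noiseless data are recovered to ~1e−6 relative;
at assay-like noise (sd 0.05, 24 points) the median recovered EC50 over
200 seeded repeats stays within a few percent of truth and the EC50 bias
is below 10%.

## Problem sizes used in validation

The validation suite runs the full pipeline at the study-shaped scale
(4 cohorts × 1,321 genes × 10 vs 10 samples; 50 seeded repeats for power
and significance checks), null calibration at 10,000 genes × 4 cohorts,
exhaustive small-n certification of the gamma approximation (all rank
tuples at n ≤ 8, k ≤ 3), permutation cross-checks at B = 10⁵, and 200
seeded dose-response recoveries per agonist. These sizes were chosen so
the whole suite completes in about half a minute on one CPU while keeping
every Monte-Carlo tolerance at 3 standard errors or better.

## Known limitations

* The exact null assumes untied integer ranks; heavy tying (discrete
  expression values) pushes all inference to the gamma/permutation routes.
* The gamma route's semi-discrete refinement is certified for the small-n
  regime down to n_i = 8; cohorts smaller than that (n_i ≤ ~5) should use
  exact enumeration, which is cheap there.
* Signature scoring is mean z-score only; rank-based (ssGSEA-style)
  scoring is deliberately out of scope.
* No count-model differential expression (negative binomial GLMs),
  covariate adjustment or paired designs; no random-effects effect-size
  meta-analysis.
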