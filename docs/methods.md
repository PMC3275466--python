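# Methods

## Classification model

A sample is an expression signature x ∈ R^G (log-scale relative expression,
one value per gene). Each subtype k has a centroid c_k on the same genes.
The classifier computes Spearman's ρ — the Pearson correlation of
average-rank-transformed vectors — between the sample and every centroid
and assigns the argmax. ρ is a *similarity* (occasionally loosely called a
distance in assay descriptions), so we maximize it. Rank transformation
makes the call invariant under any strictly monotone transform of the
sample's values, which is why centroid assays tolerate scale and offset
differences between laboratories.

Ties in values get average (fractional) ranks — the standard definition
with ties. Exact ties in ρ across centroids are broken by the centroid
set's declared subtype order and flagged (`is_tie`); determinism here is
required for reproducible simulation tallies. Genes are matched by exact,
case-sensitive id between sample and centroid set; the shared set is taken
in sorted order so results are invariant to input row order. Unmatched
genes are dropped and counted, with a warning above 50% loss. Input values
are treated as already preprocessed (housekeeper normalization and any
other upstream steps are out of scope).

## Error characterization (archetype mode)

The intrinsic measurement error of each gene is estimated from replicate
measurements (default design: twelve) of one archetypal sample per
subtype. Per gene and archetype we fit a Gaussian with μ = replicate mean
and σ = replicate standard deviation with the n−1 denominator (unbiased
convention; at n = 12 the choice matters little but should be stated).

Twelve points cannot identify a distribution's shape, so for diagnostics
the replicates are median-centered per gene *within* each archetype and
pooled across archetypes. Centering removes the subtype-specific
expression level, leaving pure measurement error; pooling multiplies the
per-gene point count by the number of archetypes. `normality_summary`
reports skewness, excess kurtosis and a Shapiro–Wilk p per gene. These are
descriptive only and never gate the pipeline: the Gaussian error family is
an explicit modelling assumption, accepted by inspection, not a tested
hypothesis.

## The sigma surface (cohort mode)

Error magnitude is not constant: weakly expressed genes are harder to
quantify, and subtypes differ in which genes they express weakly. To
perturb arbitrary cohort samples we therefore model σ as a smooth function
of expression level, per subtype. Training points are one
(mean expression, replicate SD) pair per gene per archetype. Each
subtype's cloud is smoothed by locally weighted linear regression via
statsmodels' `lowess`: span 0.75, degree 1, three Tukey-bisquare robust
reweighting iterations (the "symmetric" family of classical loess).
Queries beyond the training range are extrapolated linearly with the slope
of the boundary segment of the fitted curve — the behaviour of a degree-1
local fit evaluated directly off-grid.

The 95% confidence band around each fitted curve comes from a seeded
nonparametric bootstrap: B = 500 resamples of the points, a loess refit
per resample, percentile bands on a 100-point grid, linear interpolation
between grid points. (The band construction used in classical plotting
routines is not specified anywhere recoverable; a bootstrap is
method-agnostic and reproducible.) Bands are reordered pointwise so
lower ≤ fit ≤ upper always holds. The three bands define the simulation
scenarios: **best** (lower band, smallest error), **average** (the fit),
**worst** (upper band). All predicted σ are clipped below at a hard floor
(default 1e−6 expression units) because direct linear extrapolation can go
negative, and a Gaussian needs σ ≥ 0.

Which curve a test sample uses is decided by its *original*
classification. A subtype with no fitted curve (no archetype was measured
for it — typically the Normal-like class) causes its parents to be skipped
with a warning and a manifest record; an optional pooled-across-subtypes
fallback curve (`pooled_fallback=True`) can serve them instead.

## Monte Carlo simulation

A simulated sample draws every gene independently from
N(parent value, σ_gene). Centering each Gaussian on the parent's own value
preserves the sample's co-regulation structure — only the *measurement
error* is assumed independent across genes, not expression itself.
Correlated error, tumor heterogeneity and sampling variation are explicitly
out of scope. Simulated values are not clipped to any expression range.

Each parent × scenario gets its own counter-based RNG substream derived
from (master seed, hash of parent id, scenario), so per-parent results are
bit-identical regardless of batch composition, processing order or
parallel execution. Tallies conserve exactly: counts over subtypes (plus,
in lenient mode, an `unclassifiable` bucket for degenerate draws) sum to
`n_sims`. The headline statistic per parent is `prop_identical`, the
fraction of simulations assigned the parent's original subtype.

The default `n_sims = 100,000` follows from the normal-approximation
half-width W = z√(θ(1−θ)/n): at z = 1.96 and an expected misclassification
proportion θ = 0.02, W = ± 0.00087 — Monte Carlo noise far below any
reportable difference. The test suite and acceptance script run at
10,000 simulations per archetype and 2,000 per cohort sample, sizes at
which W (± 0.0027 and ± 0.0061 at θ = 0.02) is still an order of magnitude
below the effects the assertions check.

## Reporting

* **Confusion table**: per scenario, cell(original, assigned) =
  100 × Σ counts / Σ n_sims over parents of that original subtype; rows sum
  to 100 by construction. Rendered at 2 decimals.
* **Change histogram**: per parent, 100 × (1 − prop_identical), bucketed
  into left-closed buckets of default width 5% (the first bucket therefore
  holds the "never or almost never changes" samples); 100% lands in the
  last bucket.
* **Never-change summary**: a parent "never changes" iff its entire tally
  sits on its own subtype.
* **Scorecard**: per-sample assignment probabilities, 100 × counts/n_sims,
  sorted descending, rendered at 1 decimal as JSON or Markdown. This is the
  artifact intended for clinical reporting: a probability vector instead of
  a bare label.

## Synthetic fixtures

The `synthetic` module generates what the method needs to be exercised
without proprietary data, on an expression range of [0, 10] matching the
magnitude of log-scale qPCR-type relative expression:

* **Centroids**: the first is a uniform draw over the range; each
  subsequent centroid is a random *involutive* gene swap of the previous
  one, rejection-sampled until all pairwise |ρ| ≤ 0.3. The involution makes
  adjacent centroids exchangeable, so the value-space midpoint between them
  correlates exactly equally with both — gray-area samples built from
  adjacent pairs are maximally ambiguous by construction, not by luck of
  the seed. (With independently drawn centroids, the λ = 0.5 midpoint can
  sit a Spearman gap of 0.1–0.2 from the tie and be perfectly stable,
  which would defeat the purpose of a borderline fixture.)
* **Archetypes**: centroid plus Gaussian jitter of SD 0.1 (1% of the
  dynamic range) — close enough to classify to their own subtype with
  ρ ≈ 1.
* **Borderline samples**: value-wise convex mixtures λ·c1 + (1−λ)·c2 plus
  jitter, default λ = 0.5.
* **Repeated measures**: replicates drawn N(value, σ(value)) with
  per-subtype affine σ functions whose intercepts and slopes differ (the
  HER2-like subtype gets the largest error at low expression, the Luminal
  A-like the smallest), emulating the expression- and subtype-dependence
  the sigma surface is built to capture. Default 12 replicates.
* **Cohorts**: labeled mixtures of archetypal and borderline samples with
  a truth manifest (kind, source subtypes, λ, seed salt) for
  parameter-recovery tests.

What passing on these fixtures shows: the statistics, the error
propagation machinery, the determinism contract, and the qualitative
archetype-stable / gray-area-fragile dichotomy. What it does not show:
fidelity to any real assay's centroids, gene panel, error magnitudes, or
cohort composition — real centroid sets and repeated measures must be
supplied to make claims about a real assay.

## Numerical choices and edge cases

* Spearman ρ is clipped into [−1, 1] against floating-point overshoot and
  is undefined (error) when either vector is constant in ranks.
* Sample/gene tables reject missing values, non-numeric cells (reported
  with gene and column), duplicate ids, and non-finite values. Parsed
  floats use correctly-rounded conversion so write→read round-trips are
  bit-exact.
* Argmax ties: first maximum in declared centroid order, flagged.
* Simulation chunking (default 50,000 columns) bounds peak memory without
  affecting results (the RNG stream is consumed identically).
* A parent whose original classification is itself tied is simulated under
  its deterministically assigned subtype and logged.

## Known limitations

* The Gaussian, gene-independent error model ignores correlated technical
  effects (plate, run, batch) and biological heterogeneity.
* Loess behaviour at the extreme edges of the training range is
  extrapolation and inherits its usual fragility; the σ floor only guards
  against invalid (negative) values, not against over- or under-estimated
  ones.
* The bootstrap CI band quantifies sampling uncertainty of the σ fit, not
  systematic error in the replicate design (e.g. replicates measured in a
  single run underestimate between-run variability).
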