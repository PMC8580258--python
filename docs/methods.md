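# Methods

## Generative model

Each trial carries a category `C ~ Bernoulli(p_C1)`. Under `C = 0` all `N`
points are uniform on the disc of radius `R` (density `1/(πR²)` per point).
Under `C = 1` a source location `μ ~ N(0, σ_s² I)` is drawn, each point is
affiliated with probability `p_aff` independently, affiliated points follow
`N(μ, σ² I)` and the rest are uniform on the disc. If *any* generated point
falls outside the disc, the entire stimulus — category, source, affiliation
vector and all points — is redrawn; at the defaults (`σ_s = σ = 2`,
`R = 10`) this affects well under 5% of draws, and the observer models
ignore the truncation entirely (affiliated points are treated as exactly
Gaussian). Defaults equal the experimental design: `p_aff = 0.5`, `R = 10`,
`σ_s = σ = 2`, `p_C1 = 0.5`, `N ∈ {6, 9, 12, 15}`.

Set-size allocation per trial is uniform over the design's four values; the
design does not prescribe an allocation, and the symmetric choice treats
the four conditions identically. All coordinates are continuous Cartesian
"park units" with the origin at the disc centre; display scaling is
presentation-only.

## Exact inference

For a fixed affiliation pattern `z` with `N1` affiliated points (sums
`x_sum`, `sq_sum` over those points), the marginal over `μ` collapses in
closed form, because a product of isotropic Gaussians times the Gaussian
prior is one unnormalised Gaussian in `μ`:

    L(z)  = (πR²)^(−N0) · w̃(x, z)
    w̃     = [1 + (σ_s²/σ²) N1]^(−1) (2πσ²)^(−N1)
            · exp(−[sq_sum − ‖x_sum‖²/(N1 + σ²/σ_s²)] / (2σ²))

with `w̃ = 1` when `N1 = 0`, so the all-zeros pattern reproduces the
background evidence exactly. The evidence `L1 = Σ_z p(z) L(z)` is a
log-sum-exp over all `2^N` patterns, enumerated as a vectorised bit matrix
with incremental sufficient statistics; the enumeration is capped at
`N = 20` (2²⁰ terms) with an explicit capacity error pointing to the
quadrature route. That route integrates the per-point mixture form

    L(μ) = Π_i [(1 − p_aff)/(πR²) + p_aff N(x_i; μ, σ² I)]

against the `μ` prior on a tensor trapezoid grid (default 201 × 201 nodes
over ±5σ_s; posterior mass beyond 5σ_s is negligible at experiment scale,
and doubling the resolution moves a reference evidence by < 1e−6). The two
marginalisation orders agree to ~1e−5 in log units on random stimuli, which
the test suite and acceptance script verify; everything runs in natural-log
space with log-sum-exp, and remains finite for `N = 15` with points pushed
to the rim.

The posterior over `μ` is the mixture of `2^N` isotropic Gaussians with
component means `m(z) = x_sum/(N1 + σ²/σ_s²)`, variances
`v(z) = 1/(1/σ_s² + N1/σ²)` and log-weights
`log p(z) − N0 log(πR²) + log w̃`. The `(πR²)` factor in the mixture weight
carries a *negative* exponent `−N0`: that is the form consistent with the
joint likelihood and the only one under which the mixture density equals
`p(μ) L(μ)/L1` pointwise (verified to 1e−8 relative in tests); some
renditions of the weight print the exponent with the opposite sign, which
is a typo. The posterior-mean point estimate is the weight-averaged `m(z)`,
accumulated in log space.

`v(z)` is implemented as a scalar isotropic variance (times `I`), which is
what the Gaussian algebra produces for isotropic `σ`, `σ_s`.

## Observer zoo

Every observer emits a decision variable `d`, compared to a criterion by
the response stage.

* **A (marginalise both)** — `d = log L1 − log L0` exactly. Variants differ
  only in fitted response/belief parameters: A1 one criterion, A2 one per
  set size, A3 additionally frees the internal `σ`, `σ_s`.
* **B (commit to μ̂, sum over z)** — evidence
  `L̃1 = Π_i [p_aff N(x_i; μ̂, σ²I) + (1 − p_aff)/(πR²)]` with `μ̂` the
  centroid (B4), the peak of a Gaussian-kernel density map (B5), or the
  posterior mean (B6). The B5/H11 kernel width equals the internal `σ`
  (2 park units): the display-unit width quoted for the kernel (1.4 cm on a
  7 cm arena) is exactly `σ` after unit conversion, and the kernel is
  described as matching the dispersal of points around the source. Density
  maps use a 141 × 141 grid spanning the disc, kernels summed (a single
  point peaks at `1/(2πσ_k²)`), argmax ties broken by lowest linear index.
* **C (commit to ẑ, marginalise μ)** — `L̃1 = L(ẑ)` with `ẑ` the argmax of
  `L(z)` (maximum marginal likelihood), of `L(z) p(z)` (maximum marginal
  posterior, whose evidence keeps the `p(ẑ)` factor exactly as the strategy
  maximised it), or the agglomerative search below (prior omitted by
  default, matching the family's evidence integral; a flag includes it).
* **D (commit to both)** — joint-posterior maximiser (inner `μ`-argmax is
  the closed-form `m(x, z)`; evidence keeps the `p(μ̂)` factor),
  joint-likelihood maximiser (inner argmax at the cluster mean), the
  agglomerative partition with the cluster-mean `μ̂`, or a committed `μ̂`
  (centroid/density peak) with the maximum-likelihood radial affiliation
  rule `ẑ_i = 1 ⇔ ‖x_i − μ̂‖ < r*`, `r* = sqrt(2σ² log(R²/2σ²))` — the
  distance at which the Gaussian density crosses the uniform background
  (≈ 4.495 at defaults; 0 with a warning when `R² ≤ 2σ²`).
* **H (no generative variables)** — scalar statistics: negative mean
  pairwise distance (H10), max kernel density (H11), negative minimum
  pairwise distance (H12), negative mean nearest-neighbour distance (H13),
  and the fraction of points with nearest-neighbour distance below a
  threshold (H14). H14's threshold is unspecified in the original
  description (whose printed text duplicates H13's — an apparent
  copy-paste slip; we implement the statistic its title names) and defaults
  to `r*`, exposed as an argument.

Because the committed-value evidences for the MMP/MJP strategies include
prior factors, their `d` is not a calibrated log posterior ratio; the
fitted criterion absorbs the shift. Argmax ties across partitions are
broken by smallest `N1`, then lexicographic `z`, for deterministic tests.

Canonical IDs (`A1`…`H14`) come with two alias tables, because the source
literature numbers the C/D models differently in different sections
(`C7`/`C8`/`D9`… vs `C(8)`/`C(9)`/`D(10)`…); both map onto the canonical
set without guessing which numbering is authoritative.

## Agglomerative cluster search

For each point as seed (an exhaustive, deterministic sweep): start with the
singleton cluster, score `LLR(z) = log L(z) − log L0`, repeatedly add the
nearest non-member to the *current cluster centroid* (recomputed after each
addition; nearest-to-seed and nearest-to-any-member variants are available
behind an option for sensitivity analysis) and re-score. Growth stops at
the first strict decrease of the LLR — ties continue — and the seed's best
is the running maximum over its trajectory (identical to "the value before
the drop" whenever growth is unimodal). The result is the best partition
across seeds, its LLR, and the total number of LLR evaluations (at most `N`
per seed, so ≤ N² overall), which doubles as a reaction-time proxy. Every
evaluation, including each seed's initial singleton, counts.

A property worth knowing: on stimuli where *all* points are affiliated
(`p_aff = 1` generation), the committed partition is the all-ones vector in
only ~60% of `N = 6` trials at the default dispersions — not because the
greedy search fails (it matches the global argmax of `L(z)` on essentially
all such trials) but because the marginal likelihood genuinely prefers to
drop points ≳2.2σ from the cluster mean, where the Gaussian predictive
density falls below the uniform background; at least one such point occurs
in ~39% of those trials. An observer matched to that degenerate condition
(internal `p_aff = 1` with the partition prior included in the score) can
only commit to the full cluster and recovers it always. Both rates are
reported by the acceptance script.

## Response model and fitting

`p(report present | d) = λ/2 + (1 − λ) Φ((d − k_N)/σ_d)`. Reading the
noisy-threshold rule as "the probability that `d` plus zero-mean Gaussian
noise exceeds `k`" is numerically identical to a normal CDF at `d` with
mean `k`. Heuristic observers use per-set-size criteria and omit the lapse
term, as their printed response rule does; a flag adds it for fairness
comparisons (default off). Lapses are included for all A–D variants.

Fitting maximises the Bernoulli likelihood of the binary choices.
Free-parameter sets: {k, σ_d, λ} for single-criterion models; {k_N × 4,
σ_d, λ} for flexible-criterion variants (all B/C/D models carry N-dependent
criteria by default, as does A2); "P" variants add one internal `p_aff` per
set size; A3 adds internal `σ`, `σ_s`; H models use {k_N × 4, σ_d}.
Decision variables depend only on the stimulus and the internal beliefs, so
they are computed once per trial and cached; belief-flexible fits recompute
them inside the objective. The optimiser is multi-start Nelder-Mead
(objective tolerance 1e−6, parameter tolerance 1e−4) from Latin-hypercube
starts over criterion ∈ [−5, 10], `σ_d` log-scale in [0.1, 5], lapse
logit-scale in [0.005, 0.3] (plus belief ranges), with λ optimised on the
logit and σ's on the log scale. Every flexible-criterion fit adds one extra
start lifted from its tied-criterion nested fit, which guarantees the
nested-model likelihood ordering up to optimiser tolerance. Response
probabilities are clipped to [1e−12, 1 − 1e−12] before the log. AIC =
2k − 2LL; BIC = k log n − 2LL; fitting is per synthetic subject, with no
hierarchical pooling.

Recovery harnesses: `parameter_recovery` simulates replicate datasets from
one observer and refits it; `model_recovery` simulates subjects from one
observer and fits several candidates to each. The recovery study conditions
used by the tests and the acceptance script: the Bayesian generator uses
`k = 0.5, σ_d = 1, λ = 0.05` (2000 trials per replicate); the clustering
generator uses `k = 2.0` with the same noise and lapse, because its
decision variable is nonnegative and right-shifted, so a mid-distribution
criterion is the realistic choice; model recovery uses 10 subjects × 1000
trials. Recovery simulations restrict the design to `N ∈ {6, 9}`, which
keeps the exact-inference stage light while exercising both a small and a
medium set size; the qualitative-signature simulations use the full
`{6, 9, 12, 15}` design at 2000 background-only trials per set size.

## Summaries

Quantile binning is rank-based with stable-order tie-breaking (bins differ
in size by at most one); binomial standard errors `sqrt(p(1−p)/n)`.
Decision-variable histograms default to 35 equal bins on [−10, 25]. The
false-alarm slope is the OLS slope of `P(respond present | C = 0)` against
`N`. The affiliation curves condition on ground-truth `z`, so they apply to
synthetic data only.

## What the synthetic data can and cannot show

The generator *is* the task: every distributional statement above is
implemented exactly, so tests against it verify the inference algebra, the
observer taxonomy's qualitative signatures (e.g. the Bayesian observer's
false alarms *fall* with set size on background-only stimuli while the
greedy-clustering decision variable *rises*), and the identifiability of
the response-stage parameters. It does not emulate human sensory noise,
sequential effects, learning, or motor errors beyond the lapse term, so a
model winning on synthetic data says nothing about which model fits people
— that requires behavioural data, which this package does not ship.
Confidence ratings and reaction times are out of scope (the clustering
iteration count is exposed as an RT *proxy* only).

## Numerical choices and limitations

* Exact enumeration: `N ≤ 20` hard cap; beyond it, use the quadrature
  evidence (O(N · grid)).
* Quadrature: trapezoid weights in log space; accuracy ~1e−5 in log
  evidence at the default grid, driven by tail truncation at ±5σ_s.
* Tie-breaks: partition argmax by (N1, lexicographic z); density-grid
  argmax by lowest linear index; quantile-bin ties by input order.
* The disc truncation of affiliated points is ignored by all observers
  (and is rare under the defaults); likelihoods are therefore very slightly
  miscalibrated near the rim.
* Nelder-Mead is derivative-free by design — the cached-d objective is
  cheap but only piecewise-smooth in belief-flexible fits; with ≥ 10
  restarts the recovery errors are well inside the tolerances the tests
  assert, but global optimality is not guaranteed for the 8–10-parameter
  "P" variants.

## Trial-table formats

CSV (wide): one row per trial, columns `trial_id, N, C, mu_x, mu_y, z,
x1_x, x1_y, …, xM_x, xM_y` with `M` the largest `N` in the table; unused
point columns and `mu`/`z` on `C = 0` or unlabelled trials are empty; `z`
is a bitstring such as `010011`. JSON-lines: one object per line with the
same field names plus a `points` key holding an `[[x, y], …]` list.
Behavioural tables append `response` (and optionally `d_model`) columns.
YAML/JSON configs carry the TaskParams fields plus an optional `seed`.
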