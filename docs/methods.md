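# Methods

## Model and hypotheses

Let `X = (X_1, ..., X_J)` be binary item scores.  The monotone homogeneity
(MH) model assumes a single latent variable `Theta`, conditional
independence of the items given `Theta`, and nondecreasing response
functions `P(X_i = 1 | Theta)`.  MH implies conditional association (CA):
for every item pair `(i, j)` and every function `h` of the remaining items
`X_{-ij}`, `Cov(X_i, X_j | h(X_{-ij})) >= 0`.  A significantly negative
conditional covariance therefore refutes *every* MH representation at
once, without any parametric assumption.

Multidimensional monotone factor models (independent traits, simple
structure) satisfy the weaker observable conditions commonly tested —
nonnegative covariances, manifest monotonicity, total positivity — so those
conditions cannot separate one trait from several.  They do not, in
general, satisfy CA with respect to *rest-score-like* conditioning
functions, which is the leverage the package exploits.

## The CARP statistic

For focal pair `(i, j)`:

1. **Split.**  `L = round(ell * N)` training subjects (rounding ties
   downward), the rest test subjects, drawn uniformly at random with a
   caller-supplied seed.  Defaults: `ell = .5` for `N <= 500`, `.3`
   otherwise; the power-optimal training fraction is near `.5` for small
   samples and `.2–.3` for large ones (see `ell_sweep` / `optimal_ell`,
   which fit a quadratic in `ell` and report its vertex, refusing convex
   fits or vertices outside `(0, 1)`).
2. **Regression.**  OLS of `X_i` on all items except `X_i, X_j` (intercept
   included), and likewise for `X_j`, on the training sample only.  The
   focal coefficients are structural zeros — this is what makes the
   conditioning variable a function of `X_{-ij}` and the error-rate
   argument go through.  Numerically we center the design, zero out
   exactly-constant predictor columns (the intercept absorbs them), and
   use minimum-norm least squares, so collinear training samples still
   yield a unique, documented solution.  Centering is a reparameterization
   only; predictions and layers are unchanged.
3. **Quantile layers.**  Type-1 empirical quantiles (left-continuous
   inverse EDF) of the conditioning score `X^_ij + X^_ji` at probabilities
   `s/m`, `s = 1..m-1`, computed on the training sample; `m = 10` by
   default.  Duplicate separators are collapsed and a separator equal to
   the training maximum is dropped, so the effective number of layers can
   shrink (never below 2; all-constant scores are a flagged no-decision).
   Test-sample scores are assigned to right-closed intervals: a score
   exactly equal to a separator falls in the lower layer.
4. **Test.**  One-sided Mantel–Haenszel on the layered 2x2 tables:
   `Z = (n_11+ - e+ + 0.5) / sqrt(v+)`, `p = Phi(Z)` (lower tail).  The
   numerator is the layer-size-weighted sum of the per-layer sample
   covariances plus the continuity correction, so rejection (small `p`)
   indicates negative conditional covariance.  Layers with `n_++s <= 1`
   or a zero row/column margin contribute `0/0` or exactly zero to every
   sum; they are excluded, and `layers_used` records the remainder.
   Keeping zero-margin layers with `n_++s >= 2` would not change `Z`.
   If *all* layers are degenerate the result is a flagged no-decision;
   rejection-rate studies count no-decisions as non-rejections, which is
   conservative.

The CRS comparator applies the same Mantel–Haenszel machinery with layers
equal to the raw values of the unweighted rest score (`J - 1` possible
layers), on the full sample with no split — the classical pairwise CA test
this method generalizes.

## Screening and aggregation

Testing all `J(J-1)/2` pairs with a blanket correction wastes level on
pairs whose conditional covariance is positive.  `carp_scan` makes one
train/test split; on the training half it computes, for every pair, the
CARP-layered Mantel–Haenszel numerator `n_11+ - e+` (no continuity
correction) with weights and separators estimated on that same training
half, and collects the pairs with a negative numerator into the screened
set `S`.  Screened pairs are then tested on the independent test half and
rejected iff `p <= alpha / |S|`.  Since `S` is a function of the training
sample alone and each test-half p-value is (asymptotically)
supra-uniform under the null, the family-wise error rate is at most
`alpha`.  No inner split inside the training half is needed: the argument
requires independence from the *test* sample only, and reusing the full
training half maximizes screening power.

## Simulator

`simulate_responses` draws from the compensatory multidimensional logistic
model `P(X_i = 1 | Theta) = logistic(sum_d alpha_id Theta_d + beta_i)` with
independent standard-normal trait components, at most three dimensions,
and nonnegative loadings.  Latent draws are consumed before item draws in
subject-major order, so identical `(bank, n, seed)` give bit-identical
matrices across platforms with the same generator (NumPy PCG64).

Study designs follow the conventions of the Monte-Carlo literature for
this problem:

* **standard simple-structure banks** (`standard_case_bank`): unit
  loadings, zero intercepts, one to three item blocks;
* **random parameter sets** (`sample_parameter_set`): intercepts
  `beta ~ U(-1.5, 1.5)`, structurally nonzero loadings `~ U(0.5, 2.5)`,
  for zero-dimensional (all loadings zero — mutually independent items,
  the least favorable null, since every conditional covariance is exactly
  zero rather than positive), unidimensional, and two-block designs.

What the generator does *not* emulate: correlated traits (higher-order
factor structure), non-logistic response functions, polytomous items,
local dependence, and real-data artifacts such as missingness or
speededness.  Passing tests therefore certify the procedure's behavior
under conditionally independent logistic populations, not robustness to
those complications.

## Population oracle

`pattern_distribution` enumerates all `2^J` response patterns (J <= 20;
item 1 is the least-significant bit of the pattern index) and integrates
the conditional pattern probabilities over the trait distribution by
tensor-product Gauss–Hermite quadrature with probabilists' weighting.
Only loading columns with a nonzero entry consume quadrature dimensions.
The default of 64 nodes per dimension was chosen so that doubling the
node count moves no pattern probability by more than 1e-8 even at the
steepest supported loadings (2.5); at 40 nodes such banks still show ~2e-8
shifts.  Node blocks are chunked to bound the `(2^J x nodes^D)`
intermediate at ~4M entries.

Population regression weights solve the normal equations built from the
exact second-moment matrix of the pattern distribution (minimum-norm on
singular moments, mirroring the sample fit).  Conditional correlations in
quantile groups of any pattern-level score are computed exactly from the
pmf.

**Quantile groups of a discrete score** need a tie rule, and extreme-group
correlations are sensitive to it.  The rule used: cluster score values
that differ by less than 1e-9 (relative) to absorb floating-point noise in
the weights; sort distinct values; place boundaries at cumulative
probability `s/m`; a value whose mass straddles a boundary is assigned
wholly to the straddled group *nearer the center* of the distribution
(ties to the lower group).  Consequently the outermost groups contain
exactly the values whose entire tail mass fits within `1/m` — a
conservative convention for "most extreme group" conditioning.  Under
this rule the exact cross-block correlation in the union of the two
extreme vigintile groups of the predicted-score *difference*, for two
independent five-item Rasch blocks with zero intercepts, is −.2043; an
alternative rule that assigns straddling values outward dilutes the
extreme groups and weakens the correlation to about −.13.

## Study harness and problem sizes

`type1_study`, `randomized_type1_study` and `power_study` derive all
replicate seeds from one root generator up front (each below 2^31), so
results are reproducible and independent of execution order.  Reported
tables carry binomial standard errors `sqrt(r(1-r)/R)` and no-decision
counts.

The shipped study scales are scaled-down presets chosen to give
Monte-Carlo standard errors small enough for the qualitative and
quantitative checks they support:

* type-I grid: `J in {10, 30, 50}`, 20 zero-dimensional parameter sets per
  `J`, 500 replicates each at `N = 500`, `ell = .3` (SE of each
  per-configuration rate about .009; SE of the grand mean far smaller);
* randomized-design type-I study: 30 configurations with
  `ell ~ U(.2, .5)`, `N ~ U{500..1000}`, `J ~ U{10..50}`, 500 replicates
  each;
* power table: the three-block designs (2,2,8), (3,3,6), (2,2,20),
  (4,4,16) at `N = 5000`, `ell = .2`, 1000 replicates (SE at most .016);
* qualitative comparisons (CARP vs CRS ordering, convergence of the
  power ratio in the balanced case across `N in {500, 5000}`) use 300–400
  replicates.

## Known limitations

* The test is for a *single* focal pair; the scan controls family-wise
  error but compounding the pair statistics into one overall test (the
  variance of a sum of correlated Z's) is deliberately out of scope.
* One random split is used; averaging over repeated splits would reduce
  outcome variability but its aggregation theory is unsettled.
* Pattern enumeration is exponential in `J`; the oracle is for desk-scale
  banks (`J <= 20`), not operational item pools.
* With very small samples or extreme intercepts, many layers degenerate
  and the test returns flagged no-decisions rather than forcing a
  p-value; callers should inspect `layers_used` and the failure flag.
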