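# Methods

This note documents the models, numerical choices, and the reasoning behind
the open design decisions in `phylomilk`.

## Data model and transforms

Macronutrient concentrations are proportions of milk mass. All modeling is
done on the logit scale, `ln(p / (1 - p))`, which maps (0, 1) onto the real
line so Gaussian trait-evolution models respect the boundaries; g/100 g
values are divided by 100 first. The logit is undefined at 0, and a reported
zero concentration in practice means "below the detection limit", so loaders
convert exact zeros to missing values with a warning rather than clamping.

Quality control regresses dry matter on the sum of fat + protein (+ sugar):
the relationship is almost affine in clean data, so large outliers indicate
transcription or assay errors. The outlier rule is |externally studentized
residual| > 3 by default (a config knob; the flag list is advisory — nothing
is deleted automatically). When the regression is numerically exact the
studentized residuals are 0/0 noise and are defined as zero.

Trees are used at unit height (largest root-to-tip distance = 1, optional but
default in the pipeline). This makes `Sigma_P` a per-tree-height rate, the
selection strength alpha dimensionless, and heritability scale-free.
Continuous life-history covariates are log10-transformed and mean-centered;
aquatic adaptation is coded ordinally 0–3 (terrestrial, partly, mostly,
completely aquatic); diet enters with herbivore as the reference level.

## Phylogenetic mixed model

The trivariate model places two covariance components on the stacked trait
vector: `Sigma_P (x) A` (phylogenetic, with `A[i, j]` the shared path length
from the root) and `Sigma_R (x) I` (residual). Missing cells are handled by
row selection of the stacked Gaussian — the exact marginal likelihood — never
by imputation.

The primary backend is maximum likelihood: both covariance matrices are
parameterized by log-Cholesky factors (positive-definite by construction,
h2 in [0, 1] automatically), the fixed effects are profiled out by GLS at
every objective evaluation, and L-BFGS-B optimizes the 12 remaining
parameters, with a second perturbed start if the first does not converge.
A jitter of `1e-8 * mean(diag)` stabilizes Cholesky factorizations (callers
can lower it when verifying exact algebraic identities). Wald intervals and
normal-theory two-sided p-values cover the fixed effects; covariance-derived
quantities (h2, correlations) get percentile intervals from an optional
parametric bootstrap (`n_boot`; each replicate resimulates from the fitted
model, reapplies the observed missingness pattern, and refits).

The MCMC backend (emcee ensemble sampler) exists to mirror the Bayesian
framing of this model family: weakly informative Gaussian priors on the
fixed effects (sd 5 on the logit scale, generous for concentrations) and on
the log-Cholesky parameters (sd 2), walkers initialized near the ML optimum.
p-values are the MCMC-style two-sided tail fractions
`2 min(Pr(b > 0), Pr(b < 0))`, floored at 1/draws. Reported `Sigma` matrices
are posterior means (means of PSD draws are PSD); scalar summaries are
posterior medians, which their own percentile intervals always contain. No
attempt is made to match any particular Gibbs sampler numerically; agreement
is expected at the level of signs, magnitudes, and interval overlap.

## KSI clade distinctiveness

The statistic is `sqrt(n1 n2 / (n1 + n2)) * sup |F1 - F2|` between trait
values inside and outside a clade. For one trait the supremum is evaluated
at all pooled data points (ties handled exactly). For two or three traits
the exact Peacock statistic maximizes over all 2^d axis-orientation
quadrants and the full grid of pooled coordinates; it is computed by
histogramming the signed difference of the two empirical measures on the
pooled-coordinate grid and taking one inclusive cumulative sum, from which
every orientation follows by inclusion–exclusion (the signed histogram has
total mass zero). This is exact and O(g^d) per clade; an O(8^d n^2)
enumeration oracle verifies it in the tests. Exactness is preferred at the
~124-species scale; an approximate variant is unnecessary below a few
hundred species.

The search scores every internal non-root node with at least `min_clade`
(default 4) remaining tips on both sides, reports the argmax, removes the
winning clade's tips, and iterates (default 5 ranks), which produces the
declining-distinctiveness series. The nodeset of a winner is every testable
node on its ancestor/descendant chain scoring at least `nodeset_frac`
(default 0.95) of the winning statistic — the reported ambiguity about which
neighboring node is the true MRCA of the distinctive group. Species missing
any trait of the tested set are excluded listwise for that set only.

A structural caveat documented here because it shapes the power tests: the
sample-size scale factor is maximized at clades holding half the species, so
on strongly autocorrelated (Brownian) backgrounds the argmax can
legitimately land on a neighbor of a displaced clade — an ancestor carrying a
few extra extreme tips, or a large clade on the complement side whose
"outside" contains the displaced group. The multivariate statistic saturates
near its maximum for many clades at these sample sizes, amplifying this.
The power tests therefore plant the displaced clade as exactly half the
tips, attached below the root (`simulate_planted_clade_tree`): in that
configuration every competing node has a strictly smaller scale factor and a
discrepancy of at most 1, so the planted node is the unique argmax whenever
it is fully separated — which a 10-SD displacement guarantees. This is a
designed identifiable configuration, not a typical one; on real data the
nodeset, not the single argmax, is the meaningful unit of inference.

## Scalar-OU shift detection

All traits follow an Ornstein–Uhlenbeck process with a single selection
strength alpha and Brownian rate matrix R; optima are piecewise constant on
the tree, jumping on internal edges ("shifts"), with the root state equal to
the root optimum. An optimum jump `delta` on an edge starting at depth `t`
moves the expectation of each tip below it by
`delta (1 - exp(-alpha (d_tip - t)))`, and tip covariance is
`R * exp(-alpha (d_i + d_j - 2 t_ij)) (1 - exp(-2 alpha t_ij)) / (2 alpha)`;
at alpha = 0 both reduce exactly to Brownian motion with step-change means.
Simulation uses the exact per-branch OU transition (mean decay
`exp(-alpha b)`), never Euler steps.

Because the mean is linear in (root, jumps) and the covariance separates as
`kron(R, C(alpha))`, the ML fit for a fixed shift configuration is
closed-form matrix GLS. Fitting therefore profiles alpha on a log-spaced
grid (default 0 plus seven points in [1e-3, 50] per unit tree height — half
lives from ~0.014 to ~700 tree heights) and, per alpha, selects shift edges
by greedy forward search over all internal edges, warm-started from the
best single edges with seeded random restarts. Precomputing the Gram matrix
of all candidate mean columns against `C(alpha)^{-1}` makes each candidate
evaluation O(K^3), so the full search is a few seconds at 124 tips.
Configurations that would leave a regime with zero tips are rejected
(parsimonious allocation). Shifts are restricted to internal edges.

Missing cells are handled by an EM-style loop: impute conditional means
under the current fit, re-solve the GLS, iterate to convergence. The M-step
omits the conditional-covariance correction to the rate matrix, a slight
underestimate that is negligible at the ~4% missingness this data regime
has; the reported final log-likelihood is always the exact marginal Gaussian
likelihood of the observed cells. Imputed values are flagged separately in
all outputs.

K is selected by penalized likelihood over K = 0..K_max:
`-2 logL + p(K) log(n_obs) + 2 log C(E, K)`, where `p(K)` counts free
parameters ((K+1) optima rows, the rate matrix, alpha), `n_obs` is the
number of observed cells, and the last term is a Birgé–Massart-style
complexity charge for choosing K of the E candidate edges. Plain BIC was
evaluated first and discarded: on pure Brownian data the tree-structured
means let every added shift gain just more than its BIC price, so plain BIC
over-segments null data (K-hat of 5 on 124-tip Brownian simulations); the
configuration term restores null calibration (K-hat = 0) while leaving
strong planted shifts easily detected. The full criterion curve is kept on
the fit so near-ties between adjacent K are visible.

Equivalent shift allocations (degeneracy) are enumerated as all edge sets
producing the identical tip-to-regime partition: exhaustively when the
configuration count is small, otherwise by closure over single-edge
substitutions. On ultrametric trees equal partitions imply equal fitted
likelihoods; the reported configuration is the lexicographically smallest.
The phylogenetic half-life is `ln 2 / (alpha * height)`; at a fitted alpha
of 0.07 on a unit-height tree this is ~9.9 tree heights, i.e. the process
is empirically close to Brownian motion with jumps.

## Ancestral states and figures

Ancestral reconstructions are GLS/ML under Brownian motion: with `P` the
node-tip shared-path matrix, states are `mu + P A^{-1} (y - mu)` with `mu`
the GLS root, computed per trait; tip rows equal the observations exactly.
Reconstruction is done on the logit scale and back-transformed for display.
The phylomorphospace plot draws one segment per non-root node between parent
and child positions; aquatic species get triangle markers. The mixture plot
renormalizes fat/protein/sugar to sum to 100 and draws sugar isoclines
(`fat + protein = 100 - s`) every 25 percentage points. Figures are styled
minimally and rendered deterministically (fixed SVG hash salt, no embedded
dates).

## Synthetic data: what it does and does not emulate

The default preset matches the statistical regime of a ~124-species milk
dataset: unit-height birth–death tree (pendant branches extended past the
stopping event so no two tips coincide); logit-scale phylogenetic variances
(1.7, 0.45, 2.5) for (fat, protein, sugar), sized to the observed
interspecific ranges (fat ~1–60 g/100 g, sugar ~0.1–8 g/100 g);
heritabilities (0.976, 0.997, 0.872); phylogenetic correlations (0.675,
-0.750, -0.473); weak residual correlations (0.156, 0.380, 0.251); the 9
ecological fixed effects at their estimated logit-scale values; and 15/124
sugar values missing completely at random. Discrete covariates are
thresholded Brownian liabilities so predictors are clade-confounded the way
real mammalian ecology is. Shift presets use `Sigma_R = 0` because the
scalar-OU model has no independent residual term, and planted optimum jumps
are calibrated in units of realized tip displacement (a raw optimum jump
under weak selection barely moves the tips and would be undetectable by any
method).

Not emulated: the literature-compilation measurement process (per-species
sample sizes, assay differences), phylogenetic uncertainty (a single tree is
an input; the consensus-tree computation is out of scope), missingness that
depends on trait values (sugar is missing at random here, whereas real
below-detection values are missing not at random), and taxon-name
reconciliation. Passing recovery tests therefore demonstrates correctness of
the estimators under the model's own assumptions, not robustness to these
real-data complications.

## Known limitations

* The shift-location search is greedy per alpha; it can in principle miss
  jointly-optimal but individually-weak shift pairs. Restarts mitigate this.
* The K-selection penalty is a calibrated approximation, not a clone of any
  particular segmentation criterion; with real data near-ties between
  adjacent K (e.g. 6 vs 7 regimes) should be read off the criterion curve
  rather than from the single selected K.
* The EM imputation omits the rate-matrix correction term (see above).
* The MCMC backend's defaults are sized for interval sanity checks, not
  publication-grade posterior summaries; long chains are the caller's
  responsibility.
* `pmm_loglik` builds the full stacked covariance (3n x 3n); fine to a few
  hundred species, not intended for thousands.
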