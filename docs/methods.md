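# Methods

## Model

A continuous trait `x` evolves along a rooted, time-calibrated phylogeny by
Brownian motion whose instantaneous variance differs among branches. Rates
are attached to *nodes*: every tip and internal node `i` (including the
root) carries a log-rate `s_i = log(sigma2_i)`. Under the model the
log-rates themselves evolve by Brownian motion down the tree, so
neighboring branches tend to have similar rates and the prior covariance of
the non-root log-rates is proportional to `C_ext`, the matrix of MRCA
heights over tips and non-root internal nodes.

The trait covariance among tips is the matrix `T`: entry (i, j) sums, over
the edges from the root to MRCA(i, j), edge length times the edge's average
rate. Because rates live at nodes, the average rate of an edge is the time
integral of `exp(s(t))` with `s(t)` linear between the endpoint log-rates —
the logarithmic mean `(sigma2_p − sigma2_c) / (s_p − s_c)`. When the
endpoint log-rates differ by less than 1e-8 the midpoint limit
`exp((s_p + s_c)/2)` is used to avoid 0/0 cancellation; the logarithmic
mean is symmetric and always lies between the endpoint rates.

Estimating one rate per node from one observation per tip is
over-parameterized, and the joint likelihood of data and rates diverges as
the rate-of-rates `sigma2_BM → 0` (the unobserved log-rates' density
becomes a spike; `joint_loglik` exposes this pathology for inspection). The
model is therefore fitted by penalized likelihood: the objective is the
Gaussian log-likelihood of the data under `T` minus `lambda` times the
negative log-density of the log-rates under BM on the tree, constants
included (the reported objective matches the printed form of the penalty,
log-determinant and 2*pi terms and all; they do not affect the argmax at
fixed `lambda`). `lambda` is set by the user; it cannot be estimated for
the same reason `sigma2_BM` cannot.

## Parameters that matter

- `lambda` (dimensionless, user-set): penalty weight. `lambda → ∞`
  collapses all rates onto the single-rate ML estimate (verified to 1%
  at `lambda = 1e6`); `lambda → 0` is accepted but ill-conditioned and
  warns. Typical exploratory ladder: 0.01, 0.1, 1, 10.
- Branch lengths: any positive time unit; rates are trait-variance per that
  unit. Zero-length edges are rejected because `C_ext` must be positive
  definite (every non-root node strictly above the root).
- `FitOptions.tol` (1e-8 relative objective change) and `gtol` (1e-5
  projected-gradient norm): L-BFGS-B stopping rules. `bound = 20` boxes the
  log-rates to avoid overflow of `exp`.

## Fitting

The optimization variable is the full vector of node log-rates (dimension
`n + m`, root included). The root trait state `x0` is profiled out in
closed form (GLS) at every objective evaluation — that profile is exact.
The root log-rate `s0` is *not* profiled: the GLS expression
`(1' C_ext^-1 1)^-1 1' C_ext^-1 s` minimizes only the penalty quadratic,
while `s0` also enters the data likelihood through the root's child edges,
so `s0` is optimized jointly with the other log-rates and the GLS form
(`profile_s0`) serves as initialization and summary. After a fit, a 1-D
search over either `x0` or `s0` cannot improve the objective (tested to
1e-6).

Optimization is quasi-Newton (L-BFGS-B) with 2-point finite-difference
gradients, step 1e-7 — the objective's noise floor is ~1e-12, and a 1e-8
step intermittently stalls the line search; if the first attempt fails the
fit retries once, deterministically, with a 10x step. Initialization sets
every log-rate to the log of the single-rate MLE (the large-lambda
solution). All positive-definite solves go through Cholesky
factorizations; a non-positive-definite `T` during the search returns an
objective of −inf (step rejected) rather than raising. Fits are
bit-reproducible given identical inputs and options.

`fit_lambda_ladder` fits a set of lambdas warm-started from the largest
(best-conditioned) value downward and returns results in the order given;
the dispersion of fitted log-rates should be non-increasing in lambda, and
a violation (possible with local optima) is logged, not raised.

## Choosing lambda by cross-validation

For each candidate lambda the model is fitted to the full data; each tip
(or a random subset) is then dropped, the model refitted on the pruned
tree, and the score accumulates squared differences between pruned-fit and
full-fit log-rates over shared nodes. Nodes are matched between the trees
by the set of tip labels they subtend, which is invariant to re-indexing;
the dropped tip and any node suppressed by its removal are excluded. The
preferred lambda minimizes the total. The procedure is O(grid x tips) full
fits — expensive on large trees; `n_drop` subsamples folds.

## Simulators

All fixture trees are pure-birth (Yule): lineages split at unit rate until
the requested tip count, one further exponential waiting time is appended,
and heights are rescaled to unit depth. The generating scenarios are:

- **gbm** — log-rates diffuse down the tree at `sigma2_BM` (default 1 per
  unit depth, which spreads rates over roughly 2–3 orders of magnitude on
  a 50-tip tree); traits then diffuse with per-edge variance = length x
  logarithmic-mean rate.
- **uncorrelated** — a gbm draw whose non-root log-rates are uniformly
  permuted among nodes: identical rate multiset, no phylogenetic signal in
  the rates.
- **mk** — an ordered low/medium/high Markov chain (regime rates 0.1, 1,
  10; adjacent transitions only, both directions at rate `q`) paints
  regimes from a middle-state root. Whole paintings with two or more
  transitions on any edge are rejected and redrawn; surviving transitions
  are relocated to their edge midpoint, so a shift edge diffuses at the
  arithmetic mean of its two regime rates (exact for a midpoint shift) and
  every node has a well-defined state. `q` is calibrated per tree so the
  expected number of shifts is ~6 (1.5`q` as the typical exit rate times
  total edge length); rejection trims the upper tail, so realized paintings
  average somewhat fewer.
- **constant** — a single rate (default 1) everywhere.

Every generator is bit-reproducible from a seed; `simulate_scenario`
derives independent tree/rate/trait sub-seeds from one master seed via
`SeedSequence`.

What the simulations do not emulate: measurement error, within-edge rate
paths (rates are node-valued with deterministic edge averaging, matching
the estimator's assumption), fossil (non-ultrametric) sampling, and
multivariate traits. Passing recovery tests therefore demonstrates correct
behavior *under the model's own data-generating assumptions*, not
robustness to empirical misspecification.

## Problem sizes and stochastic checks

The validation experiments use 50-tip trees (10 replicates for the
constant-rate recovery at `lambda = 10`, 5 for the discrete-regime recovery
at `lambda = 0.1`) and 30-tip trees for the 10 matched gbm-vs-permuted
pairs at `lambda = 1`; these sizes give stable medians while keeping a full
run in minutes. Monte-Carlo moment checks in the test suite use 1e3–1e4
replicates with 4-standard-error bands.

Known behavior worth noting: when a regime is painted on only a few
terminal nodes, a single trait realization cannot reveal its rate and the
penalty shrinks those estimates toward the background, so per-regime means
are noisy for rare regimes; and at `lambda <= 0.1` the arithmetic mean of
edge rates on constant-rate data sits ~25–30% below the single-rate MLE
even at full convergence (the near-unpenalized rates scatter over several
log units) — the mean-rate agreement is tight only from `lambda = 1`
upward.

## Conventions

Tips are numbered 1..n in Newick encounter order and internal nodes
n+1..n+m in preorder (root = n+1); `C_ext` rows are tips then non-root
internals in id order, heights are measured from the root (root = 0), and
all output files follow this indexing. Polytomies are supported; rates are
reported as `sigma2` (variance per unit branch-length time), and the
single-rate reference estimate is ML (divide by n), not REML.
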