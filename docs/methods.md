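# Methods

This note documents the model, the estimation choices, and the numerical
decisions behind `cncb`, in the package's own terms. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Generative model

A trial presents one of a small set of stimulus strengths `mu_i`
(e.g. ±0.67 in the standard two-stimulus design). Sensory evidence is
`s = mu + eps_s` with `eps_s ~ N(0, sigma_s²)`, and the binary decision is
`D = sign(s − theta_s)`; the measure-zero tie `s = theta_s` is resolved to
+1 for reproducibility. Confidence evidence is

    w = (mu + (1 − alpha)·eps_s − theta_s)/sigma_s + eps_c,
    eps_c ~ N(0, sigma_c²).

The same sensory-noise sample appears in both equations; normalising by
`sigma_s` puts confidence evidence in internal-noise units so that it is
comparable across sensory dimensions. A discrete rating on m levels cuts
the signed evidence `D·w` at m−1 increasing boundaries `b_1 < … < b_{m−1}`,
with the lowest category spanning `D·w ∈ (−inf, b_1]` — confidence evidence
may contradict the decision, and such trials land in the lowest category.

Parameters and defaults:

| parameter | meaning | units | default |
|---|---|---|---|
| `mu` | stimulus strengths | stimulus units | ±0.67 (→ 75% correct) |
| `sigma_s` | sensory noise SD | stimulus units | 1.0 |
| `theta_s` | sensory criterion | stimulus units | 0.0 |
| `sigma_c` | confidence noise SD | internal-noise units | 0.5 |
| `alpha` | confidence boost | dimensionless, [0, 1] | 0.2 |
| `b_k` | rating boundaries | internal-noise units | calibrated |
| `delta` | top/bottom rating-use ratio | dimensionless | 1 (uniform) |

Two parameters of the fuller family — a mis-scaling of sensory noise in
the confidence normalisation, and a confidence criterion offset — are
deliberately not implemented; the scope here is the noise + boost model.

## Exact probabilities

(s, w) are jointly Gaussian with `E[w] = (mu − theta_s)/sigma_s`,
`Var[w] = (1 − alpha)² + sigma_c²`, `Cov[s, w] = (1 − alpha)·sigma_s`.
Every decision × rating cell is a bivariate-normal rectangle probability.
The bivariate CDF is evaluated through Owen's T function, which is exact
(machine precision) at every correlation; this matters because the
model's correlation `(1 − alpha)/sqrt((1 − alpha)² + sigma_c²)` approaches
1 whenever the fitted confidence noise collapses. Degenerate geometries
are routed to one-dimensional reductions: correlation above `1 − 1e-9`
treats w as an affine function of s, and `Var[w] = 0` (no noise, full
boost) treats w as a constant. Tiny negative cell masses from
inclusion–exclusion are clamped to zero and each stimulus row is
renormalised (the correction is at the 1e-15 level).

Boundary calibration solves `P(D·w ≤ b)` = cumulative target proportion
by Brent root-finding on the pooled CDF (tolerance 1e-11). Pooling uses
equal stimulus weights, which is exact for the equal-trials-per-stimulus
designs simulated here. Confidence bias is modelled by a triangular
profile `p_k ∝ 1 + (delta − 1)(k − 1)/(m − 1)`, so `delta` is exactly the
top/bottom usage ratio and `delta = 1` is uniform.

## Maximum-likelihood fitting

The multinomial log-likelihood `L = Σ n·log P(j,k|i)` is maximised over
`(sigma_s, theta_s, sigma_c, alpha, b_1…b_{m−1})` jointly — one sensory
model explains both the decisions and the ratings. The optimizer works on
an unconstrained transform (log scales, logit boost, first boundary plus
log-increments). Model probabilities are floored at 1e-12 inside the log
so calibration-edge cells cannot produce −inf; `sigma_c` is bounded below
at 1e-4 during fitting; `alpha` may cling to 0 or 1 (its logit is capped
at ±13). Starting values: a probit fit of the Type 1 margins initialises
`(sigma_s, theta_s)`; boundaries are initialised by calibrating to the
empirical pooled rating marginals; the Type 2 starts cross
`sigma_c ∈ {0.5, 2.0}` with `alpha ∈ {0.25, 0.75}` (no-boost variant: the
two noise starts). Each start runs an adaptive Nelder–Mead stage; the best
is refined by L-BFGS-B (likelihood tolerance ~1e-8). All starts reached
the same optimum in every development check, so only the best is polished.
Non-convergence is reported in the result, not raised.

Goodness of fit is the deviance `G² = −2(L − Ls)` against the saturated
model `Ls = Σ n (log n − log N_i)`. The no-boost (`alpha = 0`) and
with-boost variants are compared by a likelihood-ratio test with 1 df;
the selection threshold is p < 0.05 (the recovery studies are reported at
that level). Because `alpha = 0` lies on the boundary of its domain, the
test is conservative under the no-boost truth, and the retention rate of
the simpler model exceeds 95%.

A `fix_sensory` option fits only the Type 2 parameters with
`(sigma_s, theta_s)` held at supplied values, for designs where the
Type 1 model is estimated separately.

## Equivalent noise and efficiency

At `alpha = 1` the confidence evidence is independent of the sensory
sample, so the model factorises into the Type 1 term times a 1-D interval
probability. The equivalent confidence noise tau of an arbitrary model
table is defined by projecting it onto this boost-1 family. The general
path minimises the KL divergence over (tau, boundaries) with equal
stimulus weights; with two rating levels on a symmetric unbiased design
this reduces to solving the two Type 2 hit/false-alarm equations for
(tau, boundary), and the two paths agree to better than 1e-6 (tested).
The KL projection is this package's choice of how to collapse
multi-level, multi-strength Type 2 behaviour to a single tau; the
two-level geometric construction is retained as the cross-validation
path. The search is bracketed in [1e-3, 1e3]; a tau at the bracket means
the target is below chance or beyond the boost-1 frontier and raises an
out-of-range error.

The ideal confidence observer has `sigma_c = 0`, `alpha = 0` and
boundaries calibrated so its pooled rating marginals equal the observer's
own (exact root-finding; marginal matching is interpreted as exact when
reachable). Efficiency is `eta = tau_ideal²/tau_human²`. For
continuous-rating fits, which have no boundaries, efficiency is summarised
on an equal-proportion 4-level discretisation of the fitted model.

Conditioning for Type 2 rates is either objective correctness
(`D = sign(mu)`) or self-consistency (`D = sign(mu − theta_s)`); the two
coincide for unbiased observers and the package exposes both.

## Meta-d′ / M-ratio

For comparison the package implements the standard equal-variance
meta-d′: d′ and criterion c from the Type 1 margins (half-count
correction for empty marginal cells), then meta-d′ and response-
conditional confidence criteria by ML on the Type 2 count distributions,
holding the relative criterion c′ = c/d′ fixed — the original
formulation; variants exist but are out of scope. When any Type 2 cell is
empty, 1/(2m) is added to every cell of the Type 2 table (recorded in the
result). The M-ratio is meta-d′/d′ and empirically satisfies
`eta ≈ M-ratio²`; the acceptance suite measures the log–log slope across
observers varying in confidence noise and boost at the default sensory
parameters, the regime in which both quantities are well estimated (with
strongly biased sensory criteria the M-ratio itself is biased, which is
one of the motivations for the efficiency measure).

## Continuous ratings

Continuous reports are modelled as `r = pi(g(D·w))`. The mapping
`g(x) = P(correct | D·w = x)` is computed by Bayes' rule from the mixture
of per-stimulus evidence distributions under a design prior (uniform by
default; exposed as an argument). This conditions on the signed evidence
only, pooling the two decisions; it is one defensible definition of the
objective probability scale, documented rather than asserted. Note that
`g(0) ≈ 0.55` for the default observer, not 0.5: the decision is based on
s, which carries information beyond w, so zero confidence evidence does
not imply chance accuracy (verified against trial simulations binned on
D·w). The distortion `pi` is linear in log-odds with slope `gamma` and
fixed point `p0`; `gamma = 1` is the identity for any `p0`, in which case
`p0` is unidentified and flagged as such (threshold |gamma − 1| < 0.05).

Rating densities follow by change of variables: the closed-form
distortion derivative times a numerical derivative of `g` on a cached
monotone grid. The grid spans all but 1e-6 of the signed-evidence mass at
each end; beyond it, ratios of underflowing densities are numerically
meaningless (and `g` can wiggle there), so evaluation points are clamped
to the grid. Non-monotone `g` on the grid raises a misconfiguration
error; during fitting such parameter points are treated as infeasible.
Fitting maximises the exact rating likelihood without binning over
`(sigma_s, theta_s, sigma_c, alpha, gamma, p0)`, with the discrete
multi-start crossed with `gamma ∈ {0.5, 2}`. Ratings are clipped to
[1e-4, 1 − 1e-4] on ingestion (log-odds is unbounded); 0–100 scales are
rescaled on read.

## Simulation studies and problem sizes

A simulated experiment has 10,000 trials split equally across stimuli
(remainder to the lowest-index stimuli), 4 rating levels, and boundaries
calibrated to the target rating proportions. Study parameter ranges:
accuracy (at the optimal criterion) uniform in [0.55, 0.95] mapped to
`sigma_s`; `theta_s` uniform in [−1.5, 1.5]; `sigma_c` log-uniform in
[0.25, 4]; `alpha` uniform in [0, 1]; `delta` log-uniform in [0.25, 4].
The model-recovery study uses six strengths {−1.43…1.43}; the
M-ratio grid uses ±0.67. All randomness flows through a single seeded
generator per run; identical seeds give identical outputs.

The acceptance script runs 300 replicate datasets per generating model
for the recovery rates, and the test suite runs 100 per model and 100
parameter draws for the slope check — sizes chosen so the full recompute
stays desk-feasible on one CPU while keeping binomial error a few points.

The simulator emulates i.i.d. trials from the stated model. It does not
emulate sequential dependencies, lapses, finite motor noise, response
times, or rating-scale anchoring effects present in real data; passing
tests therefore validate the estimation machinery on well-specified data,
not the model's adequacy for any particular empirical dataset.

## Known limitations

* The estimated boost tends to cling to 0 or 1 in single-dataset fits;
  noise and boost trade off strongly unless the design has >2 levels or
  >2 strengths, and even then ~2,000+ confidence judgments are needed for
  a stable boost estimate.
* With 2 levels × 2 strengths, (noise, boost) is structurally
  unidentified; only the efficiency is stable (this is reproduced as a
  test).
* The equal-quartile boundary calibration is analytic; values quoted
  from finite simulated calibration runs can differ from the exact ones by
  calibration sampling noise (about ±0.01 at 10,000 trials) — the exact
  lowest quartile boundary for the default observer is 0.283.
* Gaussian confidence noise only; two response categories only.
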