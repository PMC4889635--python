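# Methods

## Measurement model

Responses to each GHQ-30 item take one of K = 4 ordered categories
(scored 1–4, higher = more distress). The package works in Samejima's
graded response model (GRM), logistic metric: the probability of responding
in category k or above is a boundary curve

    P*_{ik}(θ) = logistic(αᵢθ − t_{ik}),   k = 1, …, K−1,

with P*_{i0} ≡ 1, P*_{iK} ≡ 0, and category probabilities
P_{ik} = P*_{i,k−1} − P*_{ik}. No extra 1.7 scaling constant appears here:
the packaged parameters are already in the logistic metric. The constant
lives only in `bank.loadings_to_irt`, which converts bifactor factor-model
estimates (normal-ogive metric) into this parametrization:

    α = 1.7·λ_g / √(1 − λ_g² − λ_m²),   t_k = 1.7·τ_k / √(1 − λ_g² − λ_m²).

Only the general-factor loading λ_g produces a discrimination; the wording
(method) factor loading λ_m enters through the communality in the
denominator. This reflects the measurement intent: the CAT scores general
distress, and variance specific to positive/negative item phrasing is
treated as nuisance.

The packaged bank carries two occasions. Items 16, 19 and 25 showed
differential functioning between baseline and a later follow-up wave, so
they have occasion-specific parameters; all other items are anchored
(identical across occasions), which is what keeps the two occasions' θ
scales comparable.

Item Fisher information is
I_i(θ) = Σ_k (P*'_{i,k−1} − P*'_{ik})²/P_{ik} with P*' = αP*(1−P*);
test information is the sum over administered items. The latent scale is
standardized (mean 0, variance 1), giving the precision mapping used for
stopping rules: marginal reliability r ⇔ SE cutoff √(1−r), so the grid
r = 0.96/0.94/0.91/0.88/0.84/0.80/0.75 corresponds to SE cutoffs
0.20/0.245/0.30/0.346/0.40/0.447/0.50. The exact cutoff convention behind
published grids of this kind is not always stated; r = 1 − SE² is the
natural one on a unit-variance scale and is adopted throughout.

## Estimators

All estimators clamp working θ values to [−4.5, 4.5] (`THETA_MAX`,
configurable); likelihoods for extreme response patterns are monotone in θ
and would otherwise diverge.

* **MLE** — coarse grid (step 0.1) to bracket the maximum, then bounded
  Brent refinement (tolerance 1e−6). SE = 1/√I(θ̂) over the answered items,
  evaluated at the estimate — this is the quantity that drives per-respondent
  termination. Boundary solutions are clamped and flagged.
* **BME** (Bayesian modal / MAP) — same optimization of log-likelihood +
  log prior. With a uniform prior on the working range it is formally
  identical to MLE (verified to 1e−6 in the tests). The reported SE includes
  the prior's Fisher information (1/sd² for a normal prior, 0 for uniform):
  without that term a normal-prior CAT could not terminate earlier than an
  MLE CAT, contradicting the characteristic prior-information effect (fewer
  items needed under an informative prior). The convention is isolated in
  one function so the alternative is a one-line change.
* **EAP** — posterior mean, with SE = posterior SD, by fixed-grid quadrature
  on 101 equally spaced nodes over the working range (node count
  configurable). The quadrature is deterministic and cheap; a 10×-finer grid
  moves estimates by ≲1e−4 on extreme patterns (bounded in the tests at
  1e−3). Note one consequence of the clamped range: with no responses the
  EAP "posterior" is the prior truncated at ±4.5, so its SD is ≈0.99993
  rather than exactly 1.

## Item selection

* **UW-FI** picks the unanswered item with maximal Fisher information at
  the current point estimate.
* **FP-KL** picks the item maximizing the pointwise Kullback–Leibler
  divergence between the response distributions at θ̂+δ and θ̂−δ. The
  half-width δ defaults to 0.1. As δ→0, KL → 2δ²I(θ̂), so the two rules
  agree in the limit (pinned by a rank-correlation test at δ = 1e−3); at any
  small δ the two produce near-identical workloads, which is why published
  comparisons find them equally effective.

Ties are broken deterministically by lowest item id, so traces are exactly
reproducible.

## The adaptive loop

One administration (`engine.run_cat`): estimate θ̂ (the start value, default
0, before any response), select, fetch the response, re-estimate, and stop
when SE ≤ cutoff (after at least `min_items` = 1 response) or when all 30
items have been used; `reached` records whether the precision target was
met. The first item is always selected at the population mean since nothing
is known about the respondent yet; under MLE the pre-response "estimate" is
defined as the start value for exactly this purpose. Re-estimation happens
before the termination check, including at the 30-item boundary. The engine
itself contains no randomness: given a response row and a configuration the
trace is byte-identical across runs.

`engine.score_full_bank` scores a complete 30-item response row with the
same estimator — the reference against which CAT scores and CAT change
scores are compared.

## Simulation design

The synthetic module replaces survey microdata. It emulates exactly the
structure the calibrated model assumes:

* θ ~ N(0,1) (the identification under which the bank was calibrated);
  longitudinal designs draw a bivariate normal (baseline, follow-up) pair
  with unit marginals and correlation ρ, default 0.5 — a conservative
  mid-value for a multi-year distress retest, exposed as a flag because no
  authoritative value exists.
* Responses are sampled from the GRM at the packaged parameters by inverse
  CDF. Full matrices are generated up front and the CAT replays rows, so
  every grid cell sees the same respondents and cell differences are purely
  policy effects.
* One experiment seed governs everything; each simulee's stream is derived
  from (seed, simulee_id), so any single trace can be regenerated in
  isolation.

What the generator does **not** emulate — and therefore what passing
simulations do not show about real data: the empirical distress
distribution of a real population (typically right-skewed, with many
low-distress respondents sitting exactly where the GHQ-30 is least
informative), wording-method covariance beyond the general factor
(responses here are conditionally independent given θ), and any model
misfit. All of these make real CAT administrations *less* efficient than
model-generated ones. Concretely: with N(0,1) simulees the workload grid
reproduces published full-bank results at the low-reliability end
(≈8–10 items at r = 0.80, two-thirds saved) and the longitudinal
change-score correlations almost exactly (0.92–0.93 at r = 0.80), but at
high reliability cutoffs (r ≥ 0.84) it needs visibly fewer items than
published grids computed on real survey respondents, because the synthetic
population lacks the heavy low-distress mass that forces near-exhaustion of
the bank. The package reports what the calibrated model itself implies;
discrepancies of that kind are a property of the population stand-in, not
of the engine (the engine-side conventions are pinned by oracle tests).

Default problem sizes — 1000 simulees per grid cell, 2000 per group for DIF
screens — keep every experiment deterministic and fast (seconds to a couple
of minutes per experiment on one CPU) while leaving Monte-Carlo error well
inside the comparison tolerances used in the tests.

## DIF screen

For each item, three nested proportional-odds models are fitted to pooled
two-group data: cumulative logit on θ; plus a group main effect; plus a
θ×group interaction. θ is the full-bank EAP score under the pooled bank — a
defined, reproducible matching variable. The statistic is the McFadden
pseudo-R² change between the θ-only and the full model (uniform and
non-uniform DIF combined), flagged at ≥ 0.02, the conventional large-sample
cutoff. McFadden is one of several pseudo-R² variants in use; it was chosen
as the most common default and the variant is swappable. An optional single
purification pass re-scores θ from the non-flagged anchor items and
re-screens once; the full iterative-hybrid machinery of dedicated DIF
packages is intentionally out of scope.

The fitter is a damped Newton scheme (analytic gradient,
finite-difference Hessian, step halving) on the cumulative-logit
likelihood; with no covariates the closed-form solution (marginal
cumulative logits) is returned directly. Its maximized log-likelihoods are
checked against statsmodels' ordered-logit implementation in the tests.
Degenerate items (a single observed category) are reported as untestable
rather than fitted. Note that a threshold shift of c on an item with
discrimination α moves its response curves by c/α on the θ scale, so
equal-sized injected shifts are "larger" DIF on less discriminating items;
and realistic occasion effects of moderate size can sit below the 0.02
pseudo-R² cutoff at n = 2000 per group — the screen is conservative by
construction.

## Numerical choices and edge cases

* Probabilities are floored at 1e−300 inside logs; category probabilities
  sum to 1 to 1e−12 across the working range.
* MLE/BME optimization cannot leave [−4.5, 4.5]; `at_bound` marks clamped
  solutions. Zero-response MLE is an API error; the engine never produces
  it.
* Zero-discrimination items are permitted (they carry no information and
  are never selected ahead of informative ones); the packaged bank has
  α > 0 throughout.
* `avg_items` is stored at full precision; the integer display value
  rounds half away from zero.
* Empty trait-profile bins are reported as missing (NaN), never zero.

## Known limitations

* The population stand-in issue described above: absolute workload numbers
  at high reliability cutoffs are optimistic relative to real survey
  populations.
* No item-exposure control or content balancing — selection is purely
  information/KL greedy, so the most discriminating items are used in
  almost every administration.
* The DIF screen tests total DIF with a single statistic; it does not
  separate uniform from non-uniform DIF, and its single purification pass
  is a simplification of iterative-hybrid purification.
* Estimation assumes the item parameters are known constants; calibration
  uncertainty is not propagated.
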