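# Methods

## The model family

All six parameterizations share one observation model: arm-level event
counts are binomial with a logit link.  Writing *j* for trials, *k* for
treatments (1 = network reference), *i* for arms, *s*[*i*] and *t*[*i*]
for the trial and treatment of arm *i*, and *b* for a trial's base
treatment (the lowest treatment index it contains):

- **Contrast-FE / Contrast-RE** parameterize each trial as a baseline
  `mu_j` (log odds on the trial's own base treatment) plus contrasts.  In
  the random-effects form the contrast effects of a trial with L contrasts
  are jointly normal with common variance `sigma^2` and all covariances
  `sigma^2/2`, the structure consistency imposes on multi-arm trials.  The
  joint density is evaluated through conditional univariate normals: the
  l-th contrast given its predecessors is normal with mean
  `d_bk_l + (1/l) * sum_{m<l} (delta_m - d_bk_m)` and variance
  `sigma^2 (l+1) / (2l)`.  A unit test pins this construction against a
  direct multivariate-normal density to 1e-10 on trials of 2–4 arms.
- **Arm-FE / Arm-RE / Arm-RE-Tx** parameterize each *arm*: `eta_i =
  mu_s[i] + d_t[i]` (fixed effects) or `eta_i = mu_s[i] + delta_i` with
  independent `delta_i ~ N(d_t[i], sigma^2/2)`.  Contrasting two arm
  effects within a trial yields variance `sigma^2/2 + sigma^2/2 = sigma^2`
  and, for two contrasts sharing the base arm, covariance `sigma^2/2` — the
  same distribution as the contrast-based form without any explicit
  multivariate normal.  Here `mu_s[i]` is the trial's predicted log odds on
  the *network reference*, so the spread of the fitted baselines across
  trials is a meaningful descriptive of reference-treatment-risk
  heterogeneity (exposed as `baseline_heterogeneity`, which refuses
  base-shift and contrast fits where baselines are not comparable).
- **Base-treatment shift** replaces `mu` by `mu' = mu + d_b` so the
  baseline refers to the trial's own base arm: `eta_i = mu'_s[i] + d_t[i] -
  d_b[i]`.  It is an exact reparameterization of Arm-FE.
- **Treatment-specific variances** (`arm_re_tx`) replace the common
  `sigma` by one scale per treatment, `delta_i ~ N(d_t[i],
  sigma_t[i]^2/2)` — the assumption being that outcome variability attaches
  to individual treatments rather than to treatment contrasts.  With all
  `sigma_t` equal it reduces exactly to Arm-RE (tested).

Identifiability: an arm-based fixed-effects fit of a two-trial chain
network (A–B, B–C) has four free parameters — two baselines and two basic
effects — against four data points, and the count `J + (K-1) + #delta +
#sigma` is exposed as `n_free_parameters` and tested.

## Priors and defaults

| parameter | prior | default hyperparameter |
|---|---|---|
| trial baselines `mu` (log odds) | N(0, sd²) | sd = 100 |
| basic effects `d_k`, k ≥ 2 (log OR) | N(0, sd²) | sd = 100 |
| random-effect SD(s) `sigma` | Uniform(0, U) | U = 5 |

These are deliberately vague on the logit scale; `d_1` is constrained to 0.
Zero-event arms need no continuity correction because the binomial
likelihood is used exactly.  The full likelihood keeps the binomial
coefficient so that the reported deviance (−2 log L) is the conventional
one; the coefficient cancels in all Metropolis ratios.

## Sampler

A bespoke componentwise adaptive random-walk Metropolis-within-Gibbs
engine.  Per sweep, every scalar gets a Gaussian random-walk update
(`sigma` on the log scale with the Jacobian term; proposals outside the
uniform support are rejected).  Step sizes adapt toward an acceptance rate
of 0.44 by Robbins–Monro scaling of the log step, in batches of 50 sweeps,
during burn-in only — retained draws therefore target the exact posterior.

Plain componentwise updates mix slowly along the posterior's strong
`mu`–`d`–`delta` ridges, so each sweep also proposes Metropolis updates of
fixed linear combinations (all symmetric, hence valid moves that leave the
invariant distribution untouched):

- `d_k` jointly with the arm effects (or contrast effects) tied to
  treatment *k*, leaving the random-effects density invariant;
- `mu_j` jointly with trial *j*'s random effects, leaving the likelihood
  (or all but the base arm's likelihood) invariant;
- for arm-based RE models, a *level* move (all `mu` up, all `delta` and
  free `d` down) gated only by the reference arms' random-effect terms, and
  a *reroute* move per treatment (`d_k`, its arm effects, and the
  containing trials' baselines and co-arm effects move together) that is
  likelihood-invariant and lets `d_k` move relative to the rest of the
  network — important when a treatment touches the reference only through
  indirect paths;
- for fixed-effects models, `d_k` jointly with the baselines of the trials
  containing treatment *k*.

Because these reparameterized moves are cheap (they touch no or few
likelihood terms), each sweep repeats them `mix_repeats` times (default 8);
the likelihood-coupled scalar updates run once per sweep.  With the default
kernel the basic effects reach effective sample sizes of roughly 20 000–35
000 out of 60 000 retained draws on the bundled fixture, which is what
makes the ±0.01 arm-vs-contrast agreement check resolvable.

Runs use 3 chains × (20 000 burn-in + 20 000 retained) sweeps by default,
no thinning.  Chain 1 starts at zero (σ at mid-support); further chains
offset `mu` and `d` by ±1, ±2, … with σ near the edges of its support;
random effects start at their means so every start has finite log
posterior.  Each chain draws from its own PCG64 stream spawned from the
master seed, so results are bit-reproducible and adding chains does not
reshuffle existing ones.

Numerical details: linear predictors and per-arm log-likelihood terms are
cached and updated incrementally; caches are rebuilt from scratch every 500
sweeps to bound floating-point drift, and at the end of each chain the
cached log posterior is checked against a from-scratch evaluation (a test
asserts agreement to 1e-7 for all six parameterizations).  Out-of-support
states evaluate to −inf, never NaN; a NaN deviance aborts the run.

## Summaries and diagnostics

Moments and percentile-interpolated quantiles (2.5/50/97.5) pool
post-burn-in draws across chains.  Convergence is the split-chain
Gelman–Rubin statistic (each chain halved; degenerate draws report exactly
1), verified against an independent implementation to 1e-8; Monte-Carlo
standard errors of posterior means come from batch means.  DIC uses
`Dbar − Dhat = pD` with `Dhat` evaluated at the posterior mean of each
arm's event probability — the direct parents of the data — which keeps DIC
comparable across parameterizations; the identity `DIC = Dhat + 2 pD` is
asserted on every summary.

## Synthetic data

The generator draws from the arm-based process: `mu_j ~ N(mu_mean,
mu_sd^2)`, arm effects fixed or normal with variance `sigma^2/2` (common or
per-treatment), binomial counts at `expit(mu + delta)`.  Defaults (`mu ~
N(-1, 0.5^2)`, 100–400 subjects per arm) put event rates in a realistic
15–50% band so the binomial information is neither degenerate nor
overwhelming.  Generating under the arm-based process is deliberate: the
contrast-based fit on such data doubles as a check that the two
parameterizations describe the same distribution, including the σ²/2
covariance induced in multi-arm trials (verified by Monte-Carlo on the
generator's latent truths).

Benchmark networks: a two-trial A–B/B–C chain (the minimal just-identified
network), a 24-trial four-treatment network shaped like the
smoking-cessation evidence base with exactly one 3-arm trial, and a
22-trial variant in which one treatment is connected to the reference only
indirectly.

What the generator does *not* emulate: inconsistency (effect modification
differing between direct and indirect evidence), non-binomial outcomes,
patient-level covariates, and unequal randomization beyond the per-arm
sizes.  Passing recovery tests therefore show calibration under the model's
own assumptions, not robustness to their violation.

## Problem sizes used in the tests

End-to-end checks fit the bundled 22-trial network at the full 3 × (20 000
+ 20 000) run length.  Parameter-recovery uses 8 replicates of a 16-trial,
4-treatment network with 200 subjects per arm and shorter chains (2 ×
(1 500 + 2 500)), asserting ≈95% credible-interval coverage with a
generous binomial bound (≥19 of 24 effect intervals).  The
covariance-identity check uses 4 000 simulated 3-arm trials and 3-standard-
error tolerances.

## Known limitations

- The sampler is tuned for aggregate binomial NMA of modest size (tens of
  trials); it is pure Python and not meant for thousands of arms.
- Only the logit/binomial observation model is implemented; contrast-level
  (log-OR + SE) likelihoods, meta-regression and node-splitting
  inconsistency checks are out of scope, though the long data format does
  not preclude them.
- DIC is reported with one plug-in convention (posterior-mean `p_i`);
  other conventions give slightly different pD and DIC, so cross-package
  DIC comparisons should mind the convention.
- The ±0.01 agreement between parameterizations is a Monte-Carlo statement
  at the default run lengths; much shorter runs will show larger gaps.
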