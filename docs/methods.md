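# Methods

## Model

The package models a two-arm randomised trial with `m` post-randomisation
visits in which the intervention is one-off, is received just after
baseline by everyone randomised to it, and may be taken up by controls at
any time during follow-up. Non-compliance is assumed unidirectional
(control-arm contamination only) and single-episode; repeat treatments and
more than two arms are out of scope.

Compliance type `C ∈ {0..m}` is the grouped potential departure time under
randomisation to control: `C = c` means treatment would be received in the
interval `(t_c, t_{c+1}]` of follow-up days (with `t_0 = 0`), and `C = m`
means never. Types are principal strata: they are fixed pre-randomisation
characteristics, observed in the control arm (where `C` equals the
recorded departure `D`) and latent in the intervention arm.

Conditional on `(R, C)`, outcomes are multivariate normal with
unstructured `m × m` covariance `Σ` and mean

* visits scale: `α(C, j)` plus `β(j)` (intervention), nothing
  (still-untreated control), or `β(j − C)` (control treated `j − C` visits
  ago);
* days scale: identical except that the effect at `u` elapsed days is the
  piecewise-linear interpolant through `(0, 0), (t_1, β(1)), …,
  (t_m, β(m))`, held at `β(m)` beyond `t_m`.

Key assumptions, all standard for this design: randomisation independent
of `(C, untreated outcomes)`; SUTVA; the exclusion restriction (untreated
mean `α(c, j)` shared across arms within type); effect curve `β(·)` equal
across arms; correctly specified normal likelihood; missing outcomes
missing at random (MAR).

Two modelling choices deserve comment. First, the days-scale effect curve
needs a value of the effect at elapsed times below `t_1`; the curve is
anchored at zero effect at zero elapsed time, which is the only choice
under which an untreated subject has no effect and the days model nests
the visits model when treatment lands on grid days. Second, the boundary
convention groups a departure recorded exactly on a visit day with the
*preceding* interval (`t_c < T ≤ t_{c+1}` maps to type `c`), consistent
with treatment occurring "just after" a visit.

## Estimation

**Gibbs sampler with data augmentation.** Per iteration: (1) impute each
intervention subject's type from its multinomial full conditional,
`p(c) ∝ γ(c) · N(y_obs; μ_c,obs, Σ_obs)`, computed in log space over the
subject's observed coordinates only; (2) impute missing outcome cells from
the conditional normal given observed cells; (3) draw all mean
coefficients `(α, β)` jointly from their Gaussian full conditional —
the mean structure is linear in the stacked coefficient vector on both
scales, so with independent `N(0, v)` priors this is an exact conjugate
draw; (4) draw `Σ` from the inverse Wishart with df `ν₀ + n` and scale
`Ω + residual cross-product`; (5) draw `γ` from the Dirichlet with the
prior concentrations plus type counts. Imputing types from the observed
coordinates *before* imputing outcomes avoids feedback between the two
imputations inside one sweep; the stationary distribution is the same
either way.

Priors (all configurable through `PriorSpec`): coefficient variance
`v = 10⁶` on the outcome scale (diffuse for outcomes measured in tens of
units); inverse Wishart `ν₀ = m + 2` (smallest integer df with a finite
mean) with identity scale — fits are insensitive to this scale on the
problems tested; symmetric Dirichlet(1) on `γ`, the natural flat choice
for a saturated categorical model. Default run length is 100 000
iterations with 10 000 burn-in on two chains started from deliberately
different coefficient constants, (α, β) = (20, −10) and (10, −5); the
package's own analyses use much shorter chains (below) after verifying
convergence. Convergence is monitored by the classic Gelman–Rubin
potential scale reduction factor per scalar parameter; identical constant
chains return 1, constant chains at distinct values return `inf`.

Numerical details: type probabilities are normalised in log space (never
NaN, even in far tails); the inverse-Wishart draw uses a Bartlett
decomposition driven by the chain's own `numpy.random.Generator`, making
runs bit-reproducible from seeds (one spawned `SeedSequence` child per
chain); a compliance type absent from the augmented data simply leaves its
`α(c, ·)` block at the proper prior (the conjugate update does this
automatically), with a warning logged. Degenerate inputs handled
explicitly: fully missing outcome rows are drawn unconditionally, `m = 1`
reduces every block to its scalar analogue, and `γ(0) = 1` makes the
moment recursion error out as unidentified.

**Recursive moment estimator.** `γ̂` = control-arm departure proportions;
the per-visit ITT difference satisfies
`ITT(j) = β(j) − Σ_{c<j} γ(c) β(j − c)`, inverted forward in `j`. This
closed form was derived from the mean model and is validated in the test
suite against a brute-force population-expectation oracle
(`population_itt`), as a guard against algebraic drift. Moments use
available-case means; the Bayesian fit remains the principled MAR
treatment. No standard errors are attached — inference comes from the
Bayesian or IV machinery.

**Comparators.** The ITT model is the two-arm multivariate-normal
arm-means model with unstructured covariance, fitted by EM over missing
coordinates (relative log-likelihood tolerance 1e-8, cap 10 000
iterations); interval SEs use the observed-coordinate GLS information at
the ML covariance. The IV comparator is pooled 2SLS on available-case
person-visit rows: elapsed-treatment indicators (treated exactly `k`
visits ago, `k = 1..m`) instrumented by arm×visit interactions with visit
fixed effects. Since person-visit rows within a subject are correlated,
SEs are cluster-robust by subject, and coverage for IV uses Wald
intervals on those SEs — design choices of this package, as is the
available-case row selection.

## Synthetic-data generator

`SimConfig` defaults define the evaluation design used throughout: trials
of n = 300 subjects, m = 5 visits at days (90, 180, 365, 550, 730), fair
randomisation, type probabilities (1/9, 1/9, 1/9, 1/9, 1/9, 4/9),
untreated trajectories `α(c, j) = 10` for types 0 and 5, `25 − j` for
types 1–2, `22 − 3|j − 3|` for types 3–4, transient effect
`β(j) = 2(6 − j)`, and iid `N(0, 8²)` errors with no missing data. This
mimics a childhood-hearing surgical trial: outcome-related crossover
(about 5/9 of controls eventually treated), a benefit of ~10 dB that fades
to ~2 dB over two years, and early departures looking like never-takers.
Generation uses the visits-scale mean; treatment timed to the visit grid
makes the days-scale mean identical, so nothing hinges on the choice. An
optional uniform per-cell MAR missingness rate (default 0, typical
real-trial rates are 13–18% per visit) exercises the imputation machinery.

What the generator does *not* emulate: baseline covariates, non-normal or
heteroscedastic errors, informative (non-MAR) dropout, treatment received
off the visit grid, repeat treatments, or intervention-arm non-receipt.
Passing tests therefore demonstrate correctness of the estimators under
the model's own assumptions — parameter recovery, efficiency ranking,
calibrated intervals — not robustness to violations of them.

## Replication study and problem sizes

The harness (`run_study`) fits any subset of {bayes, iv, moment} to each
replicate and reports per-visit bias, empirical SE, RMSE
(`RMSE² = bias² + SE²` by construction) and 95%-interval coverage, each
with Monte-Carlo standard errors; a self-test estimator that returns the
truth scores zero bias and full coverage.

The package's own headline numbers (tests and `scripts/acceptance.py`) use
100 replicates with 2 chains × 3000 iterations and 500 burn-in per fit —
chosen after checking that short and 4× longer chains give posterior means
agreeing to ~0.05 outcome units and R-hat ≤ 1.005, so the replication
noise, not chain length, dominates. At this scale the maximum |bias| of
the Bayesian `β̂(j)` is a few tenths of a unit (MC SE ≈ 0.13 per visit),
the Bayesian empirical SE runs 10–20% below the IV SE, and credible-
interval coverage sits within Monte-Carlo error of 95%. Consistency checks
use single trials of n = 100 000. Full-scale runs (1000 replicates, long
chains) are available by raising `SimConfig.n_replicates` and the chain
length.

## Known limitations

* The saturated `α(c, j)` grid grows as `(m+1) × m`; with many visits or
  rare types, cells lean on the prior (warned, not fatal).
* The moment estimator propagates no uncertainty and can be noisy at
  small n (it equals just-identified 2SLS on complete data).
* No covariate adjustment, multi-level treatments, continuous compliance,
  arm-specific effect modification, or non-MAR sensitivity analyses.
* EM for the ITT model assumes the pooled covariance is shared across
  arms, matching the model it fits; severely pathological missingness
  patterns (a visit never observed) degrade its information matrix to a
  pseudo-inverse.
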