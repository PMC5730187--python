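# Methods

## The task and what the package models

The paradigm is a dual-contingency probabilistic cueing task. On each trial
an auditory cue with two features (pitch, composition) precedes a visual
target with two features (location, latency). Cue pitch probabilistically
predicts target location and cue composition predicts target latency.
Participants alternate between location and latency discrimination in 20
blocks of ~48 trials (960 trials per session), so on every trial one
contingency dimension is task-relevant and the other is not.

Everything is coded in *contingency space*: the binary outcome `u_d = 1`
means the fixed, arbitrary cue–target association held on that trial (e.g.
right target after a high-pitch cue), so `P(u_d = 1)` equals the current cue
validity regardless of which cue was drawn. Responses `y_d` use the same
coding, which makes the observer and response models symmetric under a
global relabelling of the association.

### Schedule generation

Cue validity per dimension takes values {0.9, 0.7, 0.5, 0.3, 0.1} and is
piecewise constant. Run lengths are drawn uniformly on an integer window
centred on the active volatility mean (16, 32 or 48 trials) with half-width
8, then clipped to [8, 54]; consecutive validity levels never repeat. The
volatility mean advances after every 5 validity changes, cycling through
{16, 32, 48} in fresh random permutations that never repeat the mean active
at a cycle boundary. The uniform-window shape and its half-width are this
package's choice: only the three means and the global range are fixed by the
design, and the half-width 8 window is the minimal symmetric one that
reaches both global extremes (8 for the fast regime, 54 — via clipping — for
the slow regime). The clipping at the slow extreme biases the grand mean run
length from 32.0 to ≈ 31.9 trials, well inside sampling noise of any
per-session estimate.

The spatial and temporal series are generated from independent streams, and
a schedule *pair* is accepted only when the trial-wise Pearson correlation
of the two validity series satisfies |r| ≤ 1e-4, by rejection over
incremented sub-seeds (typically a few thousand attempts, ~2 s; bounded by
`max_attempts`). `default_schedule()` exposes one accepted pair under a
fixed fixture seed, mirroring the original design in which a single
precomputed pair was shared by all participants.

## Observer models

The binary hierarchical Gaussian filter (HGF) inverts a three-level
generative model: the outcome is Bernoulli with probability `s(x2)` (logistic
sigmoid of the latent logit-scale validity), `x2` performs a Gaussian random
walk with step variance `exp(kappa * x3 + omega)`, and the log-volatility
`x3` performs a random walk with variance `theta`. The closed-form
variational updates per trial `k` are, at level 2,

    mu1hat = s(mu2)                      # prediction before the outcome
    delta1 = u - mu1hat                  # outcome prediction error
    pi2hat = 1 / (sigma2 + exp(kappa*mu3 + omega))
    pi2    = pi2hat + mu1hat * (1 - mu1hat)
    mu2   <- mu2 + delta1 / pi2
    sigma2 = 1 / pi2

and at level 3 the standard volatility update driven by the level-2
volatility prediction error

    delta2 = (sigma2 + (mu2 - mu2_prev)^2) / (sigma2_prev + v2) - 1,

with `w2 = v2 / (sigma2_prev + v2)`, `r2 = (v2 - sigma2_prev) / (sigma2_prev
+ v2)`, `pi3 = 1/(sigma3_prev + theta) + (kappa^2 / 2) w2 (w2 + r2 delta2)`
and `mu3 <- mu3 + sigma3 (kappa/2) w2 delta2`. The 2-level variant fixes
`kappa = 0`, freezing the volatility level entirely.

**Context specificity.** Both dimensions are filtered on every trial; the
task only selects which step-size constant applies: `omega_rel` when the
filtered dimension matches the current task, `omega_irrel` otherwise. The
nonspecific variants share a single omega per dimension across contexts.

**Precision-weighted prediction error.** The level-2 PE regressor is
`eps2 = psi2 * delta1`. The generic precision ratio `psi2 = pi1hat / pi2` is
ambiguous for binary outcomes, where level 1 has no free variance; we fix
`pi1hat = 1`, making `eps2` equal to the belief update `delta1 / pi2`
(matching the standard binary-HGF convention). The alternative reading
`pi1hat = 1 / (mu1hat (1 - mu1hat))` rescales `eps2` by ≈ 4 near
`mu1hat = 0.5` without changing the trajectory; it is exposed via
`ObserverParams(unit_pi1hat=False)` because the choice affects regressor
magnitudes (not GLM inference, which is scale-invariant per regressor).

**Initial beliefs.** `mu2(0) = 0` (unbiased), `sigma2(0) = exp(log_sigma2_0)`
with `log_sigma2_0` a free parameter, `mu3(0) = 1`, `sigma3(0) = 1`. The
level-3 initials follow common practice for this model family and are
config-exposed; for the 2-level variant they are inert.

The Rescorla–Wagner baseline tracks `v(k+1) = v(k) + alpha (u(k) - v(k))`
with `v(0) = 0.5` and a fixed learning rate per dimension.

## Response models

Choice probabilities are a binary softmax of the pre-outcome predictions:

    p(y) = s( (zeta_rel (2 mu1hat_task - 1) + zeta_irrel (2 mu1hat_other - 1)) (2y - 1) )

`zeta` subscripts name the prediction dimension, so in a spatial-task trial
the relevant weight is `zeta_s_rel` and the irrelevant one `zeta_t_irrel`.
The task-specific variant fixes both irrelevant weights to zero. Note the
*positive* sign: the literal negative-sign form (available via
`literal_sign=True`) would make belief-congruent responses less likely,
contradicting the model's purpose, and is treated as a sign typo.

## Free parameters, transforms and priors

All parameters are estimated in a transformed space with independent
Gaussian priors:

| parameter | transform | prior mean | prior SD | units / meaning |
|---|---|---|---|---|
| `log_sigma2_0_{s,t}` | identity (already log) | 0.10 | 4 | log prior variance of the validity belief |
| `omega_*` | identity | −5 | 1 | log step-size variance (learning rate) |
| `log_zeta_*` | log | 1.38 | 1 | inverse decision noise |
| `log_kappa` | log | 0 | 1 | volatility coupling (3-level only) |
| `log_theta` | log | −6 | 1 | volatility walk variance (3-level only) |
| `logit_alpha_{s,t}` | logit | 0 | 2 | RW learning rate |

The first three rows reproduce the empirical prior specification of the
winning model; `log_kappa`, `log_theta` and `logit_alpha` priors are this
package's defaults (the source design reports only the winning 2-level
model's eight parameters). `kappa` and `theta` are shared across the two
contingency dimensions, matching the single symbols in the generative
equations; omegas and zetas are per-dimension, matching the winning model's
eight reported parameters (2 prior variances, 4 omegas, 2 log zetas).

## Fitting and evidence

MAP estimation maximizes response log-likelihood plus normalized log priors
with L-BFGS-B (finite-difference gradients, `ftol` 1e-10) from 4 starts: the
prior means plus jittered starts at 0.5 prior SD. Parameter vectors whose
filter trajectories become non-finite (or produce non-positive precisions)
score −inf and are thereby rejected; level-2/3 variances are floored at
1e-8. Log evidence is approximated at the MAP by the Laplace method, with
the Hessian from central finite differences
(`statsmodels.tools.numdiff.approx_hess3`); a non-positive-definite negative
Hessian is repaired by flooring its eigenvalues at 1e-6 and flagged on the
`FitResult`.

## Model space and random-effects comparison

The canonical space crosses {HGF3, HGF2} × {context-specific, nonspecific}
observers plus the RW baseline with {task-general, task-specific}
responders: 10 models. Group-level comparison uses variational
random-effects BMS: a Dirichlet posterior over population model frequencies
(uniform Dirichlet(1) prior), exceedance probabilities by Monte Carlo
sampling from that posterior (1e5 seeded draws by default), and the Bayesian
omnibus risk from the free-energy comparison of the estimated frequency
model against the fixed equal-frequency null,
`BOR = 1 / (1 + exp(F1 - F0))` with
`F0 = sum_n [logsumexp_k lme_nk - log K]`. Protected exceedance
probabilities are `PXP = (1 - BOR) * EP + BOR / K`.

## Behavioural analysis conventions

- **RT filter**: discard trials with RT strictly greater than
  median + 2 SD, computed per subject over responded trials using the
  *sample* SD (ddof = 1). With the population SD the worked toy example
  (RTs 0.4/0.5/0.6/3.0 s, all retained) would lose its slowest trial.
- **Stable second half**: within each constant-validity run of length L,
  keep the final floor(L/2) trials (1-based within-run index > ceil(L/2)),
  independently per dimension. A run of length 1 contributes nothing.
- **Predictability bins**: strong = {90%, 10%}, weak = {70%, 30%},
  unpredictable = {50%}; relevance = task–dimension match. Accuracy is the
  proportion of current-task responses equal to the target feature; empty
  cells report n = 0 with NaN accuracy, never 0.
- **Regressors**: |mu2hat| (pre-outcome validity belief, cue-locked) and
  |eps2| (post-outcome precision-weighted PE, target-locked), each split
  four ways by dimension × relevance with zeros off-support. Correlations
  between regressors are computed after mean-centring each regressor over
  its own supporting trials, as parametric modulators enter a convolution
  GLM. Without centring, the structurally disjoint relevant/irrelevant
  supports of a dimension force an artefactual anticorrelation of roughly
  −1/(1 + 2 CV²) ≈ −0.5; the uncentred matrix remains available with
  `center=False`. A signed-PE variant is provided for lateralization-style
  control analyses.
- The 3×2 repeated-measures ANOVA helper and the per-parameter
  Pearson-correlation report are conveniences for simulation demos; the
  stepwise-regression analysis of parameters on accuracy is deliberately
  replaced by the plain correlation report.

## What the synthetic cohort does and does not emulate

The generator reproduces the statistical structure of the paradigm: the
validity levels, run-length regimes and volatility cycling, the decorrelated
schedule pair, block alternation, and agents that respond through the
fitted observer/response models (with an optional log-normal RT stub for
exercising the RT filter). It does not emulate psychophysics outside the
model: stimulus rendering and timing, contrast stair-casing, lapses,
fatigue, response biases, or RT dynamics. Passing tests therefore establish
internal consistency (correct filtering, fitting, selection and regressor
arithmetic under the model's own assumptions), not that the model is the
true generative process of human behaviour.

Default study sizes — 17 agents, 960 trials, 10 models, 4 restarts per fit,
1,000 schedules for run-length statistics — are the package's canonical
experiment settings; the recovery experiment completes in about a minute on
one core.

## Known limitations

- **Near-equivalence of context-specific and nonspecific observers at the
  reference parameters.** The reference (posterior-mean) learning rates
  differ between contexts by only 0.04–0.11 log units. Agents simulated
  exactly at those values are therefore almost observationally equivalent to
  a nonspecific observer, and model recovery correctly concentrates
  posterior mass on the *nonspecific* nested reduction (the ~0.3 nat
  per-subject Occam penalty of two nearly-redundant omegas), rather than on
  the context-specific generating structure. Recovering context specificity
  requires generating cohorts with genuinely separated `omega_rel` /
  `omega_irrel` — e.g. `simulate_cohort(heterogeneous=True)`, which draws
  per-agent parameters with the reference between-agent spread.
- The Laplace evidence is a local Gaussian approximation; strongly skewed
  posteriors (e.g. `log_zeta_irrel` on data generated without irrelevant
  weighting) are summarized only to second order.
- Exceedance probabilities are Monte Carlo estimates; with 1e5 draws their
  standard error is ≈ 0.0015 near 0.5.
- The RW baseline reports `eps2 = alpha * delta1` (its update magnitude) for
  interface compatibility; it has no precision machinery, and regressor
  extraction is meaningful for HGF trajectories only.
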