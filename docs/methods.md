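# Methods

## Task model

The environment is a three-stimulus probabilistic reversal learning (PRL)
task. A session has 40 acquisition trials followed by 40 reversal trials
(`TaskConfig`, both configurable). During acquisition one stimulus yields
positive feedback with probability 0.75 ("rich"), one with 0.50 ("neutral")
and one with 0.25 ("lean"); at reversal the rich and lean probabilities swap
while the neutral contingency is unchanged. Roles are not fixed to physical
stimuli in advance: the first stimulus the agent ever chooses becomes the
rich one, the second distinct stimulus chosen becomes the lean one, and the
remaining stimulus is neutral by elimination. The first choice of a session
is always rewarded.

Two modelling choices here were genuinely open:

* **Feedback scheduling.** Feedback is sampled as an independent Bernoulli
  draw at choice time with the role's current probability. The alternative —
  pre-scheduled blocks with exact reward counts (e.g. exactly 30 rewards in
  40 rich-stimulus choices) — is not implemented; nothing in the task
  description requires it, and i.i.d. sampling is the simplest generator
  consistent with the stated contingencies. Long-run feedback rates converge
  to the configured probabilities either way, but short-session variance is
  slightly larger under i.i.d. sampling.
* **Role assignment timing.** Roles are assigned lazily at first selection.
  If a session ends with only one stimulus ever chosen, the remaining two
  are neutral by convention (`RoleAssignment.finalize`); this cannot affect
  any analysed quantity because unchosen stimuli generate no feedback.

Stimulus screen positions are not modelled; they enter no analysed quantity.

## Choice models

Three nested Rescorla–Wagner models describe trial-level choice among the
stimuli `i` with values `V_i`:

* value update (chosen stimulus only): `V <- V + α (R − V)` with outcome
  `R ∈ {0, 1}`;
* choice score: `Q_i = τ^reinf V_i + τ^stim s_i`, where `s_i = 1` iff `i`
  was chosen on the previous trial (all zero on trial 1);
* choice rule: `P(i) = softmax(Q)_i` over the three options, with no
  additional inverse temperature (β = 1), so `τ^reinf` is directly the
  weight on value and `τ^stim` the weight on pure choice repetition.

Model **M1** uses separate learning rates for reward (`α^rew`) and
punishment (`α^pun`) and no stickiness term; **M2** uses a single rate
`α^reinf` plus stickiness; **M3** is the full model (both rates plus
stickiness). M3 reduces exactly to M1 when `τ^stim = 0` and to M2 when
`α^rew = α^pun`; the test suite verifies these reductions by seed-matched
simulation equality.

All stimulus values start at `V₀ = 0.5`, the midpoint of the outcome range
and therefore unbiased between reward and punishment; it is exposed as
`initial_value` on `AgentParams`. With binary outcomes and rates in [0, 1],
values remain in [0, 1] for the whole session.

## Likelihood

The scorer replays a session in trial order: compute choice probabilities
from the current state, score the observed choice, then update with the
observed outcome. The scalar path shares its code with the generative agent,
so replaying a simulated session reproduces the simulator's internal values
and probabilities bit for bit. A batched numpy path evaluates many parameter
vectors on many sessions simultaneously (the computational core of the
hierarchical fit) and is tested against the scalar path to 1e-9.

Log-probabilities use a max-shifted log-sum-exp; no clipping is applied
because the softmax of finite scores is strictly positive.

**Phase-restricted fits** score only the selected 40-trial phase with state
re-initialised at the phase's first trial (`V₀ = 0.5`, no previous choice).
Carrying acquisition-end state into a reversal-only fit would leak
information from trials outside the fitted window; a caller who wants the
alternative can score an explicit trial subset directly. The reversal-phase
likelihood therefore treats the first reversal trial as a fresh start, which
is a deliberate simplification.

## Hierarchical model

The hierarchy has drug condition at the top and subject below. For each
model parameter `p`:

* each condition `c` has a group mean `μ_{p,c}` on the unconstrained scale
  (logit scale for learning rates, identity for `τ^reinf` and `τ^stim`),
  with the *same* prior in both conditions, so the prior is unbiased with
  respect to the drug contrast;
* each subject `s` has a single offset `δ_{p,s} ~ N(0, σ_p)` shared across
  both conditions, matching the within-subject design: the same person
  contributes the same idiosyncratic component to both sessions;
* a subject's natural-scale parameter in condition `c` is
  `link(μ_{p,c} + δ_{p,s})`.

`τ` parameters are modelled on the whole real line (no positivity
constraint): negative stickiness (switching) is meaningful, and nothing
bounds reinforcement sensitivity below.

The offsets are sampled **non-centrally**: the free coordinates are
standardised offsets `z_s ~ N(0, 1)` with `δ_{p,s} = σ_p z_s`.  The centred
form (sampling `δ` directly with a `N(0, σ)` prior) creates a prior funnel
between `σ` and the 19 offsets that general-purpose ensemble moves cannot
traverse — expanding `σ` requires moving all offsets jointly — and in
testing the centred chains collapsed into the small-`σ` neck and stayed
there (integrated autocorrelation times near 300 steps and offset scales
biased far below truth).  The non-centred form removes that prior coupling;
measured autocorrelation times halve and the offset-scale posteriors become
well behaved.  `PosteriorDraws.delta_draws` returns the implied `σ·z`
offsets, so downstream summaries are unaffected by the reparameterisation.

### Priors

Defaults (`PriorSpec`): `μ ~ N(0, 1)` for logit-scale learning-rate means —
roughly uniform on the rate itself — and `μ ~ N(0, 5)` for the sensitivity
and stickiness means, whose plausible magnitudes reach several units and for
which a unit-scale prior would be strongly informative rather than weakly
informative; `σ ~ half-normal(1)` for learning rates and `half-normal(2)`
for the `τ` parameters. Offset scales are sampled as `log σ` with the
Jacobian folded into the joint density.

### Sampling

Sampling uses ensemble MCMC (`emcee`): 80% differential-evolution moves and
20% snooker moves over a walker population of twice the dimension (88
unconstrained dimensions for M3 with 19 subjects, hence 176 walkers). The
posterior density is evaluated for the whole ensemble at once through the
batched likelihood, which is what makes the fit fast on one CPU.

A **chain** is one independent ensemble run with its own seed and
initialisation. Walkers start in a small Gaussian ball (sd 0.15) around a
crude centre: per-condition pooled maximum-likelihood estimates for the
condition means (Nelder–Mead on the 3–4 pooled parameters), zero
standardised offsets, and `log σ` at `log 0.3` (or the prior scale if
smaller). Defaults: 4 chains, 1500 warmup steps each — roughly ten measured
integrated autocorrelation times of the slowest coordinates — then enough
post-warmup steps (thinned by 16) to retain ≥ 2000 draws per chain, i.e.
≥ 8000 pooled draws.

Convergence is summarised by the split-chain Gelman–Rubin statistic computed
across chains for every group-level quantity (condition means, offset
scales, and natural-scale condition means); the guideline threshold is 1.2.
An unconverged fit is flagged (`converged_ = False`), never fatal. The
statistic is implemented from the textbook formula and cross-checked against
arviz's split-R-hat in the tests; for constant chains it is undefined and
reported as `nan`.

## Model comparison

Marginal likelihoods are estimated by iterative (Meng–Wong) bridge sampling
on the unconstrained scale: half of the pooled posterior draws fit a
moment-matched multivariate-normal proposal, the other half enter the
estimator together with an equal number of proposal draws; the fixed-point
iteration runs in log space until the relative change falls below 1e-10 or
1000 iterations. Proposal points with non-finite posterior density are
excluded with a warning. The estimator is validated against a closed-form
conjugate normal–normal marginal (to 0.05 nats) and checked for invariance
under affine reparameterisation. Posterior model probabilities are the
softmax of log marginal likelihood plus log prior probability, with equal
prior probabilities (1/3 each) by default.

A zero-parameter model integrates nothing: its marginal likelihood is the
fixed data likelihood, handled as an exact special case.

## Condition contrasts

Contrasts are computed per posterior draw on the **natural scale** (the
scale on which group means are reported): e.g. drug minus placebo reward
learning rate for each of the ≥ 8000 simulation runs, plus the
difference-of-differences score
`(α^rew_drug − α^rew_placebo) − (α^pun_drug − α^pun_placebo)`.
Each contrast is summarised by highest-posterior-density intervals at 90, 95,
99 and 99.9% mass — the thresholds conventionally quoted for such effects —
with no further multiplicity correction, relying on the hierarchical model's
partial pooling.

The HDI is the shortest contiguous interval containing `⌈mass·n⌉` sorted
samples; ties between equally short windows break toward the lowest start,
making the result deterministic. At least 100 samples are required.

## Raw behavioural measures

* **Win-stay / lose-stay**: stays after rewarded (punished) trials divided
  by rewarded (punished) trials that have a successor. With three options
  the chance stay rate is 1/3 (not 1/2 as in two-option tasks). A zero
  denominator yields `nan`, deliberately distinct from a stay rate of 0.
* **Perseverative errors**: choices of the previously rich stimulus during
  the reversal phase, excluding the first reversal trial, counted inside
  maximal runs of ≥ 2 consecutive such choices (every choice in a
  qualifying run counts). The phrase "two or more responses" is ambiguous
  between consecutive and cumulative counting; the run-based reading is the
  default and a `cumulative=True` switch implements the alternative (all
  such choices count provided at least two occurred in the phase).
* **Acquisition–perseveration coupling**: ordinary least-squares slope (with
  classical p-value) of perseverative errors on acquisition correct counts,
  per condition and on within-subject condition-difference scores.

## Synthetic cohorts and what recovery does (and does not) show

`simulate_cohort` emulates the study design: 19 subjects, two conditions
("drug"/"placebo"), one 80-trial session per condition, subject offsets
drawn once per subject on the unconstrained scale and reused in both
conditions. Default generating condition means are group-level estimates
representative of published hierarchical fits of the full model to this task
under an acute LSD challenge versus placebo (whole-task fits): reward
learning rate 0.87 vs 0.28, punishment learning rate 0.48 vs 0.39,
reinforcement sensitivity 4.70 vs 5.57, stickiness 0.23 vs 0.43. Default
intersubject standard deviations are modest — 0.5 logit units for learning
rates, 1.0 for reinforcement sensitivity, 0.25 for stickiness — chosen so
that individual parameters vary noticeably without leaving the plausible
range (e.g. a ±0.5 logit offset moves a mid-range rate by about ±0.12). The
exact generating values are written to a companion truth table so recovery
analyses never re-derive them.

Parameter recovery (simulate at known means → hierarchical fit → compare
posterior condition means with truth) is the package's acceptance surface.
With 19 subjects and 160 trials per subject the posterior for the group
means is honest but not narrow; recovery is judged against
`max(0.15·|truth|, half the 95% HDI width)`. Replicate cohorts at different
seeds show posterior group means scattering around the generating values
with occasional cohort-level deviations of the order of the HDI width —
exactly what a calibrated posterior at this sample size implies.

What passing recovery does **not** show about real data: the generator is
the fitted model itself, so recovery demonstrates internal consistency
(simulation, likelihood, sampler and summaries agree), not that the model
family is adequate for human behaviour; real datasets also contain
phase-dependent strategy shifts, lapses and reaction-time structure that the
generator deliberately omits.

## Problem sizes and numerical choices

The default fit (4 chains × 1500 warmup + ~200 sampling steps of 176
walkers) retains ≥ 8000 pooled draws and completes in a few minutes on one
CPU; the test suite uses 2-chain variants of the same configuration. The
pooled-ML initialisation intentionally ignores the hierarchy — it only needs
to land the ensemble in the right region; the warmup does the rest.
Degenerate inputs are handled explicitly: constant chains give `nan` R-hat,
zero stay denominators give `nan`, constant regression predictors and
missing subject × condition cells raise errors, and learning-rate generating
means outside (0, 1) are rejected.

## Known limitations

* The sampler is a general-purpose ensemble method, not gradient-based HMC;
  it needs the large walker population and warmup above, and its slowest
  coordinates (the offset scales) retain autocorrelation times of ~10² steps
  even in the non-centred form, so short custom runs should always be
  checked against the reported R̂ values.
* Marginal-likelihood estimates inherit the usual bridge-sampling
  sensitivity to how normal the pooled posterior is; the moment-matched
  proposal is adequate here because the unconstrained posteriors are
  unimodal and mildly skewed.
* Perseveration counting implements two defensible readings of "two or more
  responses"; results can differ between them for choppy choice sequences.
* The cohort generator draws i.i.d. Bernoulli feedback; it does not
  implement pre-randomised feedback schedules (see Task model above).
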