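# Methods

## The task

The probabilistic reward task (PRT) is a two-alternative discrimination
with asymmetric probabilistic reward. A session has 3 blocks of 100
trials; on each trial a face with a short (11.5 mm) or long (13 mm) mouth
appears for 100 ms and the subject reports the mouth length. Per block, 50
trials show each stimulus. Correct responses are rewarded ("you won 20
points") on a controlled schedule: 30 rewards per block are planned for
correct identifications of one stimulus (*rich*) and 10 for the other
(*lean*), so a subject who never errs is rewarded on 40% of trials at a
3:1 rich:lean ratio. Which mouth length is rich is randomised per subject
and never disclosed; the asymmetry induces a *response bias* toward the
rich-paired response.

### Reward-schedule mechanics

The published constants (40%, 3:1) do not determine delivery mechanics, so
the simulator implements the controlled schedule standard in the PRT
literature: planned rewards are attached to specific trials; a planned
reward on an error trial is carried forward to the next correct
same-stimulus trial of the block, and pending rewards are dropped at block
end. This reproduces both constants exactly for an error-free subject. A
`schedule="bernoulli"` switch replaces this with independent per-trial
reward probabilities (0.6 rich / 0.2 lean given correct), matching the
constants only in expectation, for sensitivity analyses.

## The five choice models

All models choose between the two responses with a softmax on action
values

    V(a) = Q-term(a) + gamma * 1[a is the correct response to s_t]
                     + Q0 * 1[a is the rich-paired response],
    P(a1) = 1 / (1 + exp(-(V(a1) - V(a2)))),

and learn with a delta rule `Q <- Q + alpha * PE` driven by a
sensitivity-scaled prediction error. The outcome signal is the binary
reward indicator; the 20-point magnitude is absorbed into the reward
sensitivity.

| model            | values        | prediction error                                   | free parameters |
|------------------|---------------|----------------------------------------------------|-----------------|
| action_only      | Q(a)          | b_r R - Q(a)                                       | alpha, b_r, Q0, gamma |
| stimulus_action  | Q(a, s)       | b_r R - Q(a, s)                                    | alpha, b_r, Q0, gamma |
| punishment       | Q(a, s)       | b_r R - b_p (1 - R) - Q(a, s)                      | + b_p |
| belief           | zeta-mixed Q  | b_r R - [zeta Q(a,s) + (1-zeta) Q(a,s')]           | + zeta |
| counterfactual   | Q(a, s)       | as stimulus_action, plus mirrored update -alpha*PE on (a', s') | alpha, b_r, Q0, gamma |

(b_r = beta_reward, b_p = beta_punishment; s' and a' are the unshown
stimulus and unchosen action.)

Design choices where the literature leaves the rule open, all isolated
behind the model registry so a variant can be swapped without interface
changes:

- **Punishment sign.** The punishment term is *aversive* by default
  (subtracted: omitted rewards act as punishers, and `log(b_p)` keeps the
  sensitivity positive). A `punishment_sign="literal"` switch adds the
  term instead, for comparison with formulations that write it with a
  plus sign.
- **Initial action bias.** Q0 enters as a constant additive bias on the
  rich-paired response in the softmax rather than as a decaying initial
  Q-value; this keeps it interpretable as a stationary response
  preference and separates it cleanly from the learning rate.
- **Belief model.** zeta is the probability weight on the shown stimulus;
  it scales both valuation (the softmax uses the zeta-mixed value) and
  credit assignment (the update is split zeta/(1-zeta) across the two
  stimulus entries). zeta = 1 reduces exactly to stimulus_action.
- **Counterfactual model.** The unchosen action / unshown stimulus pair
  receives the mirrored update `-alpha * PE` in addition to the factual
  update.
- **State.** Q-values start at zero (the bias lives in Q0), reset at
  session boundaries, and persist across blocks within a session.

Nesting identities (punishment at b_p=0 and belief at zeta=1 equal
stimulus_action exactly; gamma=0 removes the instruction term) are
asserted in the test suite at 1e-10.

Parameters are fitted on unconstrained scales: `log(alpha/(1-alpha))`,
`log(beta_reward)`, `log(beta_punishment)`, `log(Q0)`, `log(gamma)`,
`log(zeta/(1-zeta))`.

## Hierarchical fitting

Each subject-session is one hierarchical unit under an independent
Gaussian group prior on the transformed parameters (a pooled prior across
sessions by default; fit sessions separately to get per-session priors).
Empirical-Bayes EM alternates:

- **E-step**: per unit, MAP estimation by L-BFGS on the penalised
  log-likelihood with central-difference gradients (step `1e-5 (1+|t|)`),
  multi-start (prior mean, previous mode, prior draws; 10 restarts for
  standalone fits, 3 in the first EM iteration, warm starts thereafter),
  plus a Laplace covariance from a finite-difference Hessian projected to
  SPD (eigenvalue floor 1e-8).
- **M-step**: moment matching — prior mean = mean of modes, prior
  variance = mean posterior second moment minus squared mean, floored at
  1e-6.

The M-step is damped (`prior <- 0.5 prior + 0.5 estimate`) because on
ridged likelihoods an undamped update can flip unit modes between
near-equal optima and cycle; damping leaves the fixed point unchanged.
Iteration stops when the prior moves by less than 1e-3, when the
approximate marginal likelihood (the sum of Laplace evidences) is stable
within 0.02 over three iterations, or at 80 iterations. The approximate
marginal likelihood is logged per iteration; because it is a Laplace
approximation it may legitimately dip by small amounts, so decreases
beyond 0.5 log-units produce a warning by default and an error only under
`strict_monotone=True`.

The prior initialises at mean 0, variance 3 — diffuse on every
transformed scale.

Subject-level marginal likelihoods `p(data_i | prior)` are estimated by
Monte Carlo (2000 prior draws through a compiled likelihood kernel;
delta-method standard error reported), with the Laplace value retained as
a cross-check. Model comparison uses the integrated BIC

    iBIC = -2 * sum_i log p(data_i | prior) + k * log(N),

with k the number of group-level hyperparameters (a mean and a variance
per free parameter) and N the total trial count. Differences below 3 are
flagged "not discriminable" rather than ranked.

### Numerical details

- The session likelihood exists twice: per-trial operations composed in
  Python (the reference, also used by the simulator) and a numba-compiled
  kernel used by fitting; tests pin their agreement at 1e-10 and both
  against an independent hand-enumeration oracle on toy sessions.
- Softmax log-probabilities use a softplus with linear tail above 35 to
  avoid overflow; the objective returns a large finite penalty outside
  |theta| < 50 so the optimiser cannot reach exp() overflow.
- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give byte-identical trial tables and identical fits.

## Synthetic cohorts

Real participant data from the smoking-cessation study this pipeline is
designed for are not publicly deposited, so a generator produces
longitudinal cohorts in their place: n subjects x sessions (S0, ABS2,
ABS30), each session an independent 300-trial PRT run, with per-subject
transformed parameters drawn from independent Gaussians and optional
additive session effects (e.g. +0.5 on log punishment sensitivity at
ABS30, the phenomenon of interest at the study's n = 19).

Two documented regimes:

- **Cohort defaults** (`task.DEFAULT_PARAM_MEAN`, SD 0.7): logit(alpha) =
  -1.0, log(beta_reward) = 0.5, log(beta_punishment) = 0.0, log(Q0) =
  -1.5, log(gamma) = 0.5. Chosen for realistic PRT phenomenology: overall
  accuracy around 0.85-0.9, a clearly positive response bias, modest
  learning rates.
- **Recovery regime** (`selection.RECOVERY_PARAM_MEAN`, SD 1.0): as above
  but log(gamma) = 0. Recovery experiments depend on the generating
  regime, so they document theirs: the lower instruction sensitivity
  (accuracy ~0.85) leaves more choice variance to the learned values, and
  the wider spread matches the upper end of between-subject variability
  reported by hierarchical RL fits, giving the experiments a regime in
  which the generating structure is actually expressible in behaviour.

Reaction times are descriptive decoration only (lognormal, median 450 ms,
sigma 0.25, errors slower by 0.15 log-units); no likelihood uses them.

What the generator does *not* emulate: attentional lapses and posterror
slowing, perceptual confusability beyond the gamma/zeta mechanisms,
within-session fatigue or practice effects, and any coupling between
parameters and covariates (craving, dependence severity). Passing
recovery tests therefore shows the estimator works when the model family
is correct — not that real PRT data satisfy these models.

## Experiment sizes

Parameter recovery runs at 40 subjects x 300 trials x 5 seeds (punishment
model); model recovery at 40 subjects x 300 trials, 5 replicate cohorts
per generator (punishment and action-only), all five candidates fitted —
at 20 subjects the punishment-vs-stimulus-action information gain is
comparable to the extra-parameter iBIC penalty and self-identification
becomes seed-lottery, while 40 subjects roughly doubles the evidence gap
against a penalty that grows only logarithmically;
the longitudinal contrast at 19 subjects x 3 sessions x 5 seeds. The
analysis drivers under `analysis/` use smaller replicate counts and state
so; `scripts/acceptance.py` runs the full sizes.

## Known limitations

- **beta_reward / beta_punishment ridge.** At steady state the punishment
  model's value differences depend on the two sensitivities mainly through
  their sum, so the split is identified only by early-session dynamics and
  the rich/lean accuracy asymmetry. Posterior uncertainty on the split
  stays large even at thousands of trials; the empirical-Bayes prior means
  for these parameters (and Q0, which trades off against mean value
  offsets) are correspondingly biased at small n, while rank-order
  recovery (correlations >= 0.6 at the design sizes) is preserved.
- **Shrinkage attenuation.** Pooled-prior fitting shrinks session
  contrasts toward zero: the +0.5 generating shift in log punishment
  sensitivity is recovered with mean around +0.15 at n = 19 — reliably
  positive but attenuated, as expected for posterior-mode summaries under
  a common prior.
- **Laplace approximations.** Evidence estimates and the EM objective both
  rest on local Gaussian approximations; the Monte-Carlo evidence is the
  one used for model comparison, the Laplace value a diagnostic.
- Models with near-equal iBIC (differences under ~3) should be treated as
  indistinguishable, not ranked.
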