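# Methods

## Task model

The simulator reproduces the probabilistic reversal-learning task as a state
machine over trials. Defaults (all exposed on `TaskConfig`): 200 trials;
P(win | correct choice) = 0.8 and P(win | incorrect) = 0.2 (the two options'
contingencies are dependent); learning criterion 5 correct out of the last 6
answered trials; once the criterion is met the reversal hazard is "armed" and
fires with probability 0.2 per trial; feedback ±10 SEK with the session
payout clamped to [30, 300] SEK; stimulus window 1.5 s, feedback 1.0 s,
inter-trial interval drawn from an exponential with rate 1.0 s⁻¹ truncated to
[1.5, 6.5] s by inverse-CDF sampling (the rate is not dictated by the task
description; 1.0 s⁻¹ is a conventional choice and configurable).

Criterion semantics: the 5-of-6 window is evaluable only once six answered
trials exist, so the hazard can never arm before trial 7. The armed state is
re-evaluated from the sliding window after every trial and additionally
forced off on the trial a reversal fires; because the window may still
straddle the reversal, the hazard can re-arm quickly afterwards — this is the
literal reading of the task rule ("until the reversal has occurred or the
criterion is no longer fulfilled") and is what the empirical 20%-when-armed
check validates. Missed trials (simulated with `miss_probability`, default 0)
produce no outcome, never count toward the criterion window, and do not
update the agent's values; they mirror "too slow" trials, which are treated
as regressors of no interest downstream.

## Model family and likelihood

Eight Q-learning variants form a 2×2×2 factorial over {double update,
separate sensitivities, free initial value}. Parameters in natural space:
learning rate α ∈ (0,1), reward sensitivity β_rew, punishment sensitivity
β_pun, initial value q_init assigned to option A. The softmax temperature is
fixed at 1: a free temperature would be confounded with the sensitivities,
which carry the reinforcement magnitude (R_t ∈ {β_rew, β_pun}). β_pun is not
constrained to be negative; only the prior is centred on a negative value.
Under double update the unchosen option is driven toward −R_t, the standard
anticorrelated-outcome reading of the dependent contingencies; a consequence
worth knowing is that Q(A)+Q(B) contracts by (1−α) per answered trial toward
0, so the two values become mirror images in the long run.

Inference space: a = logit(α), all other coordinates identity; restricted
variants simply drop the tied/fixed dimensions. The likelihood kernel (and
its analytic gradient, propagated forward through the value recursion) is
compiled with numba; the test suite checks both against a literal pure-Python
per-trial loop (likelihood to 1e-10, gradient against central differences).

## Hierarchical EM

Empirical Bayes with a diagonal group Gaussian per model. E-step: per-session
MAP by multi-start L-BFGS (prior mean plus prior draws; 5 starts by default;
within `run_em`, later iterations warm-start from the previous MAP, which can
only improve the located optimum). The Laplace covariance is the inverse
central-finite-difference Hessian (step 1e-4) of the negative log posterior,
ridged to positive-definiteness if needed (flagged on the fit). Log evidence
is the Laplace marginal: log p(y|θ̂) + log N(θ̂; μ, σ²) + (d/2)·log 2π +
½·log det Σ̂. M-step: μ_k = mean of MAPs; σ²_k = mean(θ̂² + Σ̂_kk) − μ_k²,
floored at 1e-6 — including the Laplace variances keeps the prior from
collapsing onto the point estimates. The objective trace recorded per
iteration is the summed penalized log-likelihood; it is monotone in practice
(audited over seeded cohorts) though the variance-inflation term means exact
monotonicity is not a theorem.

Convergence: weakly identified dimensions (q_init above all, whose generating
spread is small) make σ² converge slowly — parameter estimates stabilise
within a few tens of iterations while σ²(q0) keeps creeping. The default
`tol=1e-2, max_iter=100` is adequate for parameter estimates; model
*evidence* comparisons are sensitive to the prior width (an unconverged,
too-wide prior on q0 overpenalises the free-Q-init variants), so recovery
and selection studies in the tests run with `tol=1e-3` and a higher
iteration cap. Both drug sessions enter one pooled group prior and get
separate per-session estimates; the fitting procedure itself never sees the
session labels.

Initial prior: μ = (a=0, b_rew=1, b_pun=−1, q0=0), σ² = 6.25 per dimension —
weakly informative, centred near the group scales this task produces.

## Model selection

Random-effects group BMS on the sessions-by-models Laplace log-evidence
matrix: the standard variational Dirichlet scheme (α₀ = 1 uniform prior),
iterated to Δα < 1e-6; exceedance probabilities from 1e5 Monte-Carlo
Dirichlet draws. Evidence, not raw likelihood, enters the comparison —
that is what corrects for parameter count. A winning model is declared only
when the per-session-label BMS runs agree; the pooled result is reported
alongside. The fixed-effects iBIC is −2·Σ log evidence + 2d·log(total
answered trials), with 2d counting the group prior's mean and variance
hyperparameters.

## Synthetic cohorts

`generate_cohort` draws one inference-space parameter vector per subject and
session from a group Gaussian (i.e. the two sessions of a subject are
exchangeable draws — a deliberate null across session labels), simulates each
session independently, and records the generating truth in a sidecar table.
Defaults: 30 subjects, group means (a=−0.85 → α≈0.30, b_rew=2.0, b_pun=−1.0,
q0=0) with SDs (0.8, 0.87, 0.5, 0.3) — sensitivity means at the observed
group scales of this task, learning-rate and spread values chosen as
realistic for reversal-learning cohorts. What the generator does *not*
emulate: reaction times (so the RT comparison runs only on real data that
carries an `rt` column), practice effects, session-order effects, within-
subject parameter correlation across sessions, and any true drug effect —
passing recovery tests therefore demonstrates estimator correctness under
the model, not robustness to model misspecification in human data.

## Behavioral statistics

Percent correct, switches and reversals are counted over answered trials;
subjects with fewer than 5 reversals in either session are excluded (both
sessions removed). Paired t-tests report Cohen's d = t/√n, the paired-design
effect size. The Wilcoxon signed-rank test is reported as a z statistic:
zero differences dropped, mid-ranks for ties, tie-corrected normal
approximation without continuity correction (cross-checked against exact
sign-permutation enumeration in the tests). The exploratory switch analysis
computes, per session, P(switch | previous answered trial was a win / loss)
over consecutive answered trials, takes per-subject session deltas, and
contrasts the loss-delta against the win-delta with a paired t.

Type-I calibration of the punishment-sensitivity comparison is verified at
the parameter level: 1000 replicate cohorts with identical generating
distributions for both session labels, paired-t p-values tested for
uniformity (χ², 10 bins, α = 0.01). Running the full hierarchical fit 1000
times is computationally out of scope; the parameter-level check validates
the statistical path on exactly the quantity the session comparison uses.

## Export

Prediction-error modulators are written as tab-separated events tables
(onset, duration, trial_type, modulator, trial) with onsets at feedback
onset, duration the feedback duration, and values exactly equal to the
fitted trajectory's δ_t (no recomputation). Mean-centering is on by default
(conventional for parametric modulators, toggleable since downstream GLM
orthogonalization can make it redundant). Missed trials go to a separate
no-response table with no modulator column.

## Problem sizes and numerical choices

Recovery studies in the test suite use the study-scale cohort (30 subjects ×
2 sessions × 200 trials) for parameter recovery and exceedance, and 20
subjects per generator condition for the 8×8 model-recovery grid — sizes at
which the checks are informative while the full suite stays comfortably
runnable on a single CPU. Group-mean recovery is judged against the realized
draw means of the simulated cohort (the known truth), within two empirical
standard errors; comparison against the asymptotic generating means would
mostly measure the sampling noise of the draw itself. Ties in multi-start
optimization go to the first-found optimum; degenerate inputs (no answered
trials, zero-variance differences, non-finite evidence) raise typed errors
rather than propagating NaNs.

## Known limitations

No response-time model, eligibility traces, or forgetting/decay variants;
group covariance is diagonal (no parameter correlations at the group level);
evidence is a Laplace approximation, which can be optimistic for strongly
non-Gaussian subject posteriors; the drug condition is not a group-level
regressor (sessions are fitted exchangeably and compared post hoc).
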