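"""Shared test utilities: independent likelihood oracle and scripted sessions.

``naive_loglik`` is a deliberately literal, unvectorised transcription of the
Q-learning equations (explicit two-term softmax, dict-indexed values) kept
independent of the package's kernel so it can serve as an oracle.
"""

import math

from revlearn.task import SessionData, TaskConfig, TrialRecord


def naive_loglik(choices, outcomes, alpha, beta_rew, beta_pun, q_init, double_update):
    """Straight-line per-trial log-likelihood oracle.

    choices: list of 'A' | 'B' | None; outcomes: 'win' | 'loss' | None.
    """
    q = {"A": q_init, "B": 0.0}
    ll = 0.0
    for c, o in zip(choices, outcomes):
        if c is None:
            continue
        p_a = math.exp(q["A"]) / (math.exp(q["A"]) + math.exp(q["B"]))
        p = p_a if c == "A" else 1.0 - p_a
        ll += math.log(p)
        r = beta_rew if o == "win" else beta_pun
        u = "B" if c == "A" else "A"
        q[c] = q[c] + alpha * (r - q[c])
        if double_update:
            q[u] = q[u] + alpha * (-r - q[u])
    return ll


def make_session(
    choices,
    outcomes,
    config=None,
    subject_id="s1",
    session_label="synthetic",
    good="A",
):
    """Build a SessionData from explicit choice/outcome sequences."""
    config = config or TaskConfig(n_trials=len(choices))
    assert len(choices) == config.n_trials
    trials = []
    onset = 0.0
    for i, (c, o) in enumerate(zip(choices, outcomes)):
        answered = c is not None
        trials.append(
            TrialRecord(
                t=i + 1,
                good_stimulus=good,
                choice=c,
                outcome=o,
                correct=(c == good) if answered else None,
                criterion_armed=False,
                reversal_here=False,
                onset_stim=onset,
                onset_feedback=onset + config.stim_duration,
                iti=2.0,
            )
        )
        onset += config.stim_duration + config.feedback_duration + 2.0
    return SessionData(subject_id, session_label, trials, config)


def random_session(rng, n_trials=40, p_miss=0.0, **kwargs):
    """Random choice/outcome sequences (not generated from any model)."""
    choices, outcomes = [], []
    for _ in range(n_trials):
        if rng.random() < p_miss:
            choices.append(None)
            outcomes.append(None)
        else:
            choices.append("A" if rng.random() < 0.5 else "B")
            outcomes.append("win" if rng.random() < 0.5 else "loss")
    return make_session(choices, outcomes, **kwargs)
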