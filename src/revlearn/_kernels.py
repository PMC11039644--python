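"""Numba-compiled Q-learning likelihood kernels.

The recursion is inherently sequential over trials, so the inner loop is
compiled rather than vectorised. Choice encoding: 0=A, 1=B, -1=missed;
outcome encoding: 1=win, 0=loss, -1=none. Missed trials contribute no
likelihood term and no value update.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _log_sigmoid(z):
    # log(1/(1+exp(-z))), overflow-safe
    if z >= 0.0:
        return -math.log1p(math.exp(-z))
    return z - math.log1p(math.exp(z))


@njit(cache=True)
def qlearn_loglik(choices, outcomes, alpha, beta_rew, beta_pun, q_init, double_update):
    """Summed log choice probability over answered trials."""
    qa = q_init
    qb = 0.0
    ll = 0.0
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            continue
        x = qa - qb
        ll += _log_sigmoid(x) if c == 0 else _log_sigmoid(-x)
        r = beta_rew if outcomes[t] == 1 else beta_pun
        if c == 0:
            qa += alpha * (r - qa)
            if double_update:
                qb += alpha * (-r - qb)
        else:
            qb += alpha * (r - qb)
            if double_update:
                qa += alpha * (-r - qa)
    return ll


@njit(cache=True)
def qlearn_loglik_grad(choices, outcomes, alpha, beta_rew, beta_pun, q_init, double_update):
    """Log-likelihood and its gradient w.r.t. (alpha, beta_rew, beta_pun, q_init).

    Forward-mode accumulation through the value recursion: dqa/dqb hold the
    running derivatives of the two Q-values with respect to the four natural
    parameters.
    """
    qa = q_init
    qb = 0.0
    dqa = np.zeros(4)
    dqb = np.zeros(4)
    dqa[3] = 1.0  # d qa / d q_init at t=1
    ll = 0.0
    grad = np.zeros(4)
    for t in range(choices.shape[0]):
        c = choices[t]
        if c < 0:
            continue
        x = qa - qb
        # p(A) = sigmoid(x); d log p(choice) / dx
        if c == 0:
            ll += _log_sigmoid(x)
            dll_dx = 1.0 / (1.0 + math.exp(x)) if x < 50.0 else math.exp(-x)
        else:
            ll += _log_sigmoid(-x)
            dll_dx = -(1.0 / (1.0 + math.exp(-x)) if x > -50.0 else math.exp(x))
        for k in range(4):
            grad[k] += dll_dx * (dqa[k] - dqb[k])
        won = outcomes[t] == 1
        r = beta_rew if won else beta_pun
        dr = np.zeros(4)
        dr[1] = 1.0 if won else 0.0
        dr[2] = 0.0 if won else 1.0
        if c == 0:
            delta = r - qa
            for k in range(4):
                dqa[k] = (1.0 - alpha) * dqa[k] + alpha * dr[k]
            dqa[0] += delta
            qa += alpha * delta
            if double_update:
                du = -r - qb
                for k in range(4):
                    dqb[k] = (1.0 - alpha) * dqb[k] - alpha * dr[k]
                dqb[0] += du
                qb += alpha * du
        else:
            delta = r - qb
            for k in range(4):
                dqb[k] = (1.0 - alpha) * dqb[k] + alpha * dr[k]
            dqb[0] += delta
            qb += alpha * delta
            if double_update:
                du = -r - qa
                for k in range(4):
                    dqa[k] = (1.0 - alpha) * dqa[k] - alpha * dr[k]
                dqa[0] += du
                qa += alpha * du
    return ll, grad


@njit(cache=True)
def qlearn_forward(choices, outcomes, alpha, beta_rew, beta_pun, q_init, double_update):
    """Full latent trajectory: pre-choice Q-values, choice probabilities,
    prediction errors (NaN on missed trials) and the summed log-likelihood."""
    n = choices.shape[0]
    q_values = np.empty((n, 2))
    choice_prob = np.full(n, np.nan)
    pe = np.full(n, np.nan)
    qa = q_init
    qb = 0.0
    ll = 0.0
    for t in range(n):
        q_values[t, 0] = qa
        q_values[t, 1] = qb
        c = choices[t]
        if c < 0:
            continue
        x = qa - qb
        lp = _log_sigmoid(x) if c == 0 else _log_sigmoid(-x)
        choice_prob[t] = math.exp(lp)
        ll += lp
        r = beta_rew if outcomes[t] == 1 else beta_pun
        if c == 0:
            pe[t] = r - qa
            qa += alpha * pe[t]
            if double_update:
                qb += alpha * (-r - qb)
        else:
            pe[t] = r - qb
            qb += alpha * pe[t]
            if double_update:
                qa += alpha * (-r - qa)
    return q_values, choice_prob, pe, ll
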