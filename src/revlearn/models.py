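"""The 2x2x2 factorial family of Q-learning models for the reversal task.

Each variant is a Rescorla-Wagner learner over the two options with a softmax
choice rule at unit temperature; the reinforcement magnitude on each trial is
the free sensitivity (beta_rew on wins, beta_pun on losses), which absorbs the
softmax temperature. The three binary factors are:

* ``double_update`` — whether the unchosen option is simultaneously updated
  toward the opposite outcome (-R), exploiting the anticorrelated contingency.
* ``separate_sensitivities`` — whether beta_pun is free or tied to -beta_rew.
* ``free_q_init`` — whether option A starts at a free initial value q_init
  (an initial choice bias) or at 0.

The winning variant is the double-update model with separate sensitivities
and a free initial Q-value ("DU-SS-Qi").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._kernels import qlearn_forward, qlearn_loglik, qlearn_loglik_grad

if TYPE_CHECKING:  # pragma: no cover
    from .task import SessionData


class DomainError(ValueError):
    """Raised for non-finite or out-of-domain parameter values."""


@dataclass(frozen=True)
class ModelSpec:
    double_update: bool
    separate_sensitivities: bool
    free_q_init: bool

    @property
    def name(self) -> str:
        return "-".join(
            (
                "DU" if self.double_update else "SU",
                "SS" if self.separate_sensitivities else "CS",
                "Qi" if self.free_q_init else "Q0",
            )
        )

    @property
    def active_names(self) -> tuple[str, ...]:
        """Free inference-space dimensions, in canonical order."""
        names = ["a", "b_rew"]
        if self.separate_sensitivities:
            names.append("b_pun")
        if self.free_q_init:
            names.append("q0")
        return tuple(names)

    @property
    def n_active(self) -> int:
        return len(self.active_names)


MODEL_FAMILY: tuple[ModelSpec, ...] = tuple(
    ModelSpec(du, ss, qi) for du, ss, qi in product((False, True), repeat=3)
)
WINNING_MODEL = ModelSpec(True, True, True)


def get_model(name: str) -> ModelSpec:
    for m in MODEL_FAMILY:
        if m.name == name:
            return m
    raise KeyError(f"unknown model {name!r}; known: {[m.name for m in MODEL_FAMILY]}")


@dataclass(frozen=True)
class ParameterSet:
    """Natural-space parameters of one model variant.

    alpha in (0,1) is the learning rate; beta_rew/beta_pun scale the
    subjective magnitude of wins/losses; q_init is the initial Q-value of
    option A (option B always starts at 0).
    """

    alpha: float
    beta_rew: float
    beta_pun: float
    q_init: float = 0.0

    def validate(self, spec: ModelSpec) -> None:
        vals = (self.alpha, self.beta_rew, self.beta_pun, self.q_init)
        if not all(np.isfinite(vals)):
            raise DomainError(f"non-finite parameters: {self}")
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must lie strictly in (0,1), got {self.alpha}")
        if not spec.separate_sensitivities and self.beta_pun != -self.beta_rew:
            raise DomainError("common-sensitivity model requires beta_pun == -beta_rew")
        if not spec.free_q_init and self.q_init != 0.0:
            raise DomainError("fixed-Q-init model requires q_init == 0")


def to_natural(spec: ModelSpec, vec: np.ndarray) -> ParameterSet:
    """Map an inference-space vector (over ``spec.active_names``) to natural
    parameters: alpha = logistic(a), other coordinates identity; inactive
    dimensions take their tied/fixed values."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (spec.n_active,):
        raise DomainError(f"expected {spec.n_active} coordinates, got {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise DomainError(f"non-finite inference vector: {vec}")
    d = dict(zip(spec.active_names, vec))
    beta_rew = d["b_rew"]
    return ParameterSet(
        alpha=float(expit(d["a"])),
        beta_rew=float(beta_rew),
        beta_pun=float(d["b_pun"]) if spec.separate_sensitivities else -float(beta_rew),
        q_init=float(d["q0"]) if spec.free_q_init else 0.0,
    )


def from_natural(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """Inverse of :func:`to_natural` on the active dimensions."""
    params.validate(spec)
    d = {
        "a": float(logit(params.alpha)),
        "b_rew": params.beta_rew,
        "b_pun": params.beta_pun,
        "q0": params.q_init,
    }
    return np.array([d[k] for k in spec.active_names])


@dataclass
class LatentTrajectory:
    """Per-trial latents of one session under one parameterisation."""

    q_values: np.ndarray  # (n_trials, 2) pre-choice values
    choice_prob: np.ndarray  # probability of the chosen option; NaN on missed
    pe: np.ndarray  # prediction error of the chosen option; NaN on missed
    loglik: float


def session_loglik(
    spec: ModelSpec, params: ParameterSet, session: "SessionData"
) -> LatentTrajectory:
    """Evaluate the model's trial-wise likelihood on a session.

    Q-values start at (q_init, 0); the chosen option moves toward the
    reinforcement value R (beta_rew on win, beta_pun on loss) by alpha times
    the prediction error R - Q; under double update the unchosen option moves
    toward -R. Missed trials are skipped with Q carried forward.
    """
    params.validate(spec)
    choices, outcomes = session.encode()
    q_values, choice_prob, pe, ll = qlearn_forward(
        choices,
        outcomes,
        params.alpha,
        params.beta_rew,
        params.beta_pun,
        params.q_init,
        spec.double_update,
    )
    return LatentTrajectory(q_values, choice_prob, pe, float(ll))


def loglik_arrays(
    spec: ModelSpec,
    choices: np.ndarray,
    outcomes: np.ndarray,
    vec: np.ndarray,
) -> float:
    """Fast log-likelihood from pre-encoded arrays and an inference vector."""
    p = to_natural(spec, vec)
    return float(
        qlearn_loglik(
            choices, outcomes, p.alpha, p.beta_rew, p.beta_pun, p.q_init,
            spec.double_update,
        )
    )


def loglik_grad_arrays(
    spec: ModelSpec,
    choices: np.ndarray,
    outcomes: np.ndarray,
    vec: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Log-likelihood and its gradient over the active inference dimensions.

    Chains the natural-parameter gradient through alpha = logistic(a) and the
    tied/fixed coordinates of restricted variants.
    """
    p = to_natural(spec, vec)
    ll, g_nat = qlearn_loglik_grad(
        choices, outcomes, p.alpha, p.beta_rew, p.beta_pun, p.q_init,
        spec.double_update,
    )
    g_alpha, g_brew, g_bpun, g_qinit = g_nat
    g = {"a": g_alpha * p.alpha * (1.0 - p.alpha)}
    g["b_rew"] = g_brew if spec.separate_sensitivities else g_brew - g_bpun
    if spec.separate_sensitivities:
        g["b_pun"] = g_bpun
    if spec.free_q_init:
        g["q0"] = g_qinit
    return float(ll), np.array([g[k] for k in spec.active_names])


def simulate_choice(
    spec: ModelSpec, params: ParameterSet, q_pair: tuple[float, float], draw: float
) -> int:
    """Agent-side softmax: returns option 0 (A) iff ``draw < P(A)``."""
    qa, qb = q_pair
    if not (np.isfinite(qa) and np.isfinite(qb)):
        raise DomainError("non-finite Q-values")
    p_a = float(expit(qa - qb))
    return 0 if draw < p_a else 1


def trajectory_frame(session: "SessionData", traj: LatentTrajectory) -> pd.DataFrame:
    """Per-trial export table (trial, qA, qB, p_choice, pe)."""
    return pd.DataFrame(
        {
            "trial": [tr.t for tr in session.trials],
            "qA": traj.q_values[:, 0],
            "qB": traj.q_values[:, 1],
            "p_choice": traj.choice_prob,
            "pe": traj.pe,
        }
    )
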