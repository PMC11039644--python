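"""Hierarchical expectation-maximization fitting of the Q-learning models.

Empirical-Bayes scheme: each session's parameters get a MAP estimate under a
group-level Gaussian prior with diagonal covariance (E-step, multi-start
quasi-Newton with a finite-difference Laplace covariance at the optimum); the
prior moments are then re-estimated from the subject-level posteriors
(M-step), with the second moment including the Laplace variances so the group
variance does not collapse onto the point estimates. Iterated until the
summed penalized log-likelihood stabilises.

Each session is fitted as an independent unit: placebo and ghrelin sessions
share the group prior but receive separate parameter estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import ModelSpec, loglik_arrays, loglik_grad_arrays, to_natural
from .task import SessionData

_LOG2PI = float(np.log(2.0 * np.pi))
_HESS_STEP = 1e-4
_VARIANCE_FLOOR = 1e-6
# weakly informative starting prior, centred near the group scales of the task
_DEFAULT_MU = {"a": 0.0, "b_rew": 1.0, "b_pun": -1.0, "q0": 0.0}
_DEFAULT_SIGMA2 = 6.25


class FitError(RuntimeError):
    """Raised when optimization or EM fails irrecoverably."""


@dataclass
class GroupPrior:
    """Diagonal Gaussian over the model's active inference-space dimensions."""

    mu: np.ndarray
    sigma2: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape or self.mu.shape != (len(self.names),):
            raise ValueError("prior moment shapes must match the named dimensions")
        if not np.all(self.sigma2 > 0):
            raise ValueError("prior variances must be positive")

    def logpdf(self, theta: np.ndarray) -> float:
        z2 = (theta - self.mu) ** 2 / self.sigma2
        return float(-0.5 * np.sum(z2 + np.log(self.sigma2) + _LOG2PI))


def default_prior(spec: ModelSpec) -> GroupPrior:
    names = spec.active_names
    mu = np.array([_DEFAULT_MU[k] for k in names])
    return GroupPrior(mu, np.full(len(names), _DEFAULT_SIGMA2), names)


@dataclass
class SubjectFit:
    """MAP fit of one session with its Laplace approximation."""

    theta_map: np.ndarray
    laplace_cov: np.ndarray
    loglik: float
    log_evidence: float
    regularized: bool = False  # True if the Hessian needed a ridge to be PD

    def penalized_loglik(self, prior: GroupPrior) -> float:
        return self.loglik + prior.logpdf(self.theta_map)


@dataclass
class FitResult:
    model: ModelSpec
    prior: GroupPrior
    subject_fits: dict[tuple[str, str], SubjectFit]
    n_iterations: int
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def log_evidences(self) -> np.ndarray:
        return np.array([f.log_evidence for f in self.subject_fits.values()])


def _neg_log_post(spec, choices, outcomes, prior, theta):
    return -(loglik_arrays(spec, choices, outcomes, theta) + prior.logpdf(theta))


def _fd_hessian(f, x: np.ndarray, h: float = _HESS_STEP) -> np.ndarray:
    """Central finite-difference Hessian."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h**2)
    return H


def _safe_cov(H: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert a Hessian, ridging it toward PD if necessary."""
    regularized = False
    eigmin = float(np.linalg.eigvalsh(H).min())
    if eigmin <= 1e-10:
        H = H + (abs(eigmin) + 1e-6) * np.eye(len(H))
        regularized = True
    return np.linalg.inv(H), regularized


def fit_map_session(
    spec: ModelSpec,
    session: SessionData,
    prior: GroupPrior,
    n_restarts: int = 5,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> SubjectFit:
    """MAP estimate of one session under the group prior.

    Multi-start quasi-Newton (L-BFGS-B): the prior mean plus ``n_restarts - 1``
    draws from the prior, and optionally a caller-supplied warm start ``x0``;
    the best posterior wins, ties broken by first occurrence. The Laplace
    covariance is the inverse finite-difference Hessian of the negative log
    posterior at the optimum, and the log evidence is the Laplace-approximated
    log marginal likelihood of the session.
    """
    if session.n_answered < 1:
        raise FitError(f"session {session.key()} has no answered trials")
    choices, outcomes = session.encode()
    rng = np.random.default_rng(seed)
    sd = np.sqrt(prior.sigma2)
    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(prior.mu.copy())
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(prior.mu + sd * rng.standard_normal(len(prior.mu)))

    def objective(theta):
        return _neg_log_post(spec, choices, outcomes, prior, theta)

    def objective_grad(theta):
        ll, g = loglik_grad_arrays(spec, choices, outcomes, theta)
        f = -(ll + prior.logpdf(theta))
        g = -(g - (theta - prior.mu) / prior.sigma2)
        return f, g

    best = None
    for s in starts:
        res = minimize(objective_grad, s, method="L-BFGS-B", jac=True)
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise FitError(f"all optimizer restarts failed for session {session.key()}")

    theta = np.asarray(best.x, dtype=float)
    H = _fd_hessian(objective, theta)
    cov, regularized = _safe_cov(H)
    ll = loglik_arrays(spec, choices, outcomes, theta)
    d = len(theta)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:  # ridge guarantees PD, but guard against numerical drift
        raise FitError(f"non-PD Laplace covariance for session {session.key()}")
    log_evidence = ll + prior.logpdf(theta) + 0.5 * d * _LOG2PI + 0.5 * logdet
    return SubjectFit(theta, cov, float(ll), float(log_evidence), regularized)


def run_em(
    spec: ModelSpec,
    sessions: list[SessionData],
    init_prior: GroupPrior | None = None,
    tol: float = 1e-2,
    max_iter: int = 100,
    seed: int = 0,
    n_restarts: int = 5,
) -> FitResult:
    """Fit all sessions under a shared group prior by expectation-maximization.

    E-step: :func:`fit_map_session` per session (full multi-start on the first
    iteration, warm-started at the previous MAP afterwards). M-step: the prior
    mean is the average MAP and the prior variance the average second moment
    (MAP^2 plus Laplace variance) minus the squared mean, floored at a small
    positive constant. Stops when the summed penalized log-likelihood changes
    by less than ``tol``.
    """
    if len(sessions) < 2:
        raise FitError("EM requires at least two sessions")
    prior = init_prior or default_prior(spec)
    if tuple(prior.names) != spec.active_names:
        raise FitError("prior dimensions do not match the model's active parameters")
    rng = np.random.default_rng(seed)
    d = len(prior.mu)

    fits: dict[tuple[str, str], SubjectFit] = {}
    trace: list[float] = []
    converged = False
    n_iter = 0
    warm: dict[tuple[str, str], np.ndarray] = {}

    for it in range(max_iter):
        n_iter = it + 1
        for sess in sessions:
            key = sess.key()
            fits[key] = fit_map_session(
                spec,
                sess,
                prior,
                n_restarts=n_restarts if it == 0 else 1,
                seed=int(rng.integers(0, 2**31 - 1)),
                x0=warm.get(key),
            )
            warm[key] = fits[key].theta_map
        objective = float(sum(f.penalized_loglik(prior) for f in fits.values()))
        if not np.isfinite(objective):
            raise FitError(f"EM objective diverged; trace so far: {trace}")
        trace.append(objective)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

        thetas = np.array([f.theta_map for f in fits.values()])
        covs = np.array([np.diag(f.laplace_cov) for f in fits.values()])
        mu = thetas.mean(axis=0)
        sigma2 = np.maximum(
            (thetas**2 + covs).mean(axis=0) - mu**2,
            _VARIANCE_FLOOR,
        )
        prior = GroupPrior(mu, sigma2, prior.names)

    return FitResult(spec, prior, fits, n_iter, trace, converged)


def fit_parameter_frame(fit: FitResult) -> pd.DataFrame:
    """Natural-space parameter table of a fit, one row per session."""
    rows = []
    for (sid, label), sf in fit.subject_fits.items():
        p = to_natural(fit.model, sf.theta_map)
        rows.append(
            {
                "subject_id": sid,
                "session_label": label,
                "alpha": p.alpha,
                "beta_rew": p.beta_rew,
                "beta_pun": p.beta_pun,
                "q_init": p.q_init,
                "loglik": sf.loglik,
                "log_evidence": sf.log_evidence,
            }
        )
    return pd.DataFrame.from_records(rows)
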