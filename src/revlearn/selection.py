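"""Random-effects Bayesian model selection over the fitted model family.

Given per-session log evidences for each model, a Dirichlet posterior over
population model frequencies is obtained by the standard variational
iteration; exceedance probabilities (the posterior probability that a model
is the most frequent one) are estimated by Monte-Carlo sampling of that
Dirichlet. A fixed-effects integrated BIC is provided as a secondary
criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .hierfit import FitResult
from .task import SessionData


class EvidenceError(ValueError):
    """Raised for non-finite or malformed evidence matrices."""


@dataclass
class BMSResult:
    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    assignments: np.ndarray  # (n_sessions, n_models) posterior model probabilities

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_names,
                "dirichlet_alpha": self.dirichlet_alpha,
                "expected_frequency": self.expected_frequencies,
                "exceedance_probability": self.exceedance_prob,
            }
        )


def bms(
    evidence: pd.DataFrame | np.ndarray,
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Group Bayesian model selection from a sessions-by-models evidence matrix.

    Variational update: u_ik = exp(lme_ik + psi(alpha_k) - psi(sum_j alpha_j)),
    g_ik the row-normalised u, alpha_k = alpha0 + sum_i g_ik, iterated until
    the alpha change falls below ``tol``. Exceedance probabilities by
    Monte-Carlo over the converged Dirichlet.
    """
    if isinstance(evidence, pd.DataFrame):
        names = tuple(str(c) for c in evidence.columns)
        lme = evidence.to_numpy(dtype=float)
    else:
        lme = np.asarray(evidence, dtype=float)
        names = tuple(f"m{k}" for k in range(lme.shape[1]))
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise EvidenceError("evidence must be (>=2 sessions) x (>=2 models)")
    if not np.all(np.isfinite(lme)):
        raise EvidenceError("evidence matrix contains non-finite entries")
    if alpha0 <= 0:
        raise EvidenceError("alpha0 must be positive")

    n, k = lme.shape
    alpha = np.full(k, alpha0, dtype=float)
    g = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        log_u = lme + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = alpha0 + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=int(n_samples))
    winners = np.argmax(samples, axis=1)
    xp = np.bincount(winners, minlength=k) / float(n_samples)
    return BMSResult(names, alpha, expected, xp, g)


def ibic(fit: FitResult, sessions: list[SessionData]) -> float:
    """Fixed-effects integrated BIC of a hierarchical fit.

    -2 * sum_i log_evidence_i + p_prior * log(total answered trials), where
    p_prior = 2 * (active dimensions): each group-prior dimension contributes
    a mean and a variance hyperparameter.
    """
    total_trials = sum(s.n_answered for s in sessions)
    p_prior = 2 * fit.model.n_active
    return float(-2.0 * fit.log_evidences.sum() + p_prior * np.log(total_trials))


def evidence_matrix(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Sessions-by-models log-evidence table from per-model fit results.

    Rows are indexed by (subject_id, session_label); session ordering is
    taken from the first model and enforced across all of them.
    """
    names = list(fits)
    keys = list(next(iter(fits.values())).subject_fits)
    data = {}
    for name in names:
        sf = fits[name].subject_fits
        if set(sf) != set(keys):
            raise EvidenceError(f"model {name} was fitted on a different session set")
        data[name] = [sf[k].log_evidence for k in keys]
    return pd.DataFrame(data, index=pd.MultiIndex.from_tuples(keys))


def select_winning_model(
    fits: dict[str, FitResult],
    alpha0: float = 1.0,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[str | None, dict[str, BMSResult]]:
    """BMS per session label plus pooled; the winner must agree across labels.

    Returns (winner or None if the labels disagree, results keyed by
    "placebo"/"ghrelin"/... and "pooled").
    """
    ev = evidence_matrix(fits)
    labels = sorted({k[1] for k in ev.index})
    results: dict[str, BMSResult] = {}
    winners = []
    for i, label in enumerate(labels):
        sub = ev.loc[[k for k in ev.index if k[1] == label]]
        res = bms(sub, alpha0=alpha0, n_samples=n_samples, seed=seed + i)
        results[label] = res
        winners.append(res.model_names[int(np.argmax(res.expected_frequencies))])
    results["pooled"] = bms(ev, alpha0=alpha0, n_samples=n_samples, seed=seed + len(labels))
    winner = winners[0] if len(set(winners)) == 1 else None
    return winner, results
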