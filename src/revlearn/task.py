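"""Probabilistic reversal-learning task engine and synthetic-cohort generator.

The task: two symbols, one of which ("good") pays a monetary win with
probability ``p_reward_good`` and a loss otherwise; the other symbol has the
complementary contingency. Once the participant makes ``criterion_hits``
correct choices within the last ``criterion_window`` trials, a reversal of the
contingencies fires with probability ``reversal_hazard`` on each subsequent
trial until it fires or the criterion is no longer met.

This module simulates sessions of that task played by Q-learning agents (or
scripted agents) and generates two-session within-subject cohorts whose
parameters are drawn from a group-level Gaussian in inference space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (
    ModelSpec,
    ParameterSet,
    WINNING_MODEL,
    simulate_choice,
    to_natural,
)

OPTIONS = ("A", "B")


class ConfigurationError(ValueError):
    """Raised for invalid task or cohort configuration."""


@dataclass(frozen=True)
class TaskConfig:
    """All structural constants of the reversal-learning task.

    Defaults reproduce the in-scanner task: 200 trials, 80/20 dependent
    contingencies, 5-of-6 learning criterion, 20% per-trial reversal hazard
    once armed, +/-10 SEK feedback, payout clamped to [30, 300] SEK,
    1.5 s stimulus window, 1 s feedback, truncated-exponential ITI on
    [1.5, 6.5] s.
    """

    n_trials: int = 200
    p_reward_good: float = 0.8
    criterion_hits: int = 5
    criterion_window: int = 6
    reversal_hazard: float = 0.2
    win_amount: float = 10.0
    loss_amount: float = -10.0
    payout_min: float = 30.0
    payout_max: float = 300.0
    stim_duration: float = 1.5
    feedback_duration: float = 1.0
    iti_range: tuple[float, float] = (1.5, 6.5)
    iti_rate: float = 1.0  # 1/s, rate of the truncated exponential ITI
    miss_probability: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_reward_good < 1.0:
            raise ConfigurationError("p_reward_good must lie strictly in (0, 1)")
        if self.criterion_hits > self.criterion_window:
            raise ConfigurationError("criterion_hits must not exceed criterion_window")
        if self.criterion_hits < 1 or self.criterion_window < 1:
            raise ConfigurationError("criterion counts must be positive")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be positive")
        if self.payout_min > self.payout_max:
            raise ConfigurationError("payout_min must not exceed payout_max")
        lo, hi = self.iti_range
        if not lo < hi:
            raise ConfigurationError("iti_range lower bound must be below upper bound")
        if min(self.stim_duration, self.feedback_duration, self.iti_rate) <= 0:
            raise ConfigurationError("durations and iti_rate must be positive")
        if not 0.0 <= self.miss_probability < 1.0:
            raise ConfigurationError("miss_probability must lie in [0, 1)")
        if not 0.0 <= self.reversal_hazard <= 1.0:
            raise ConfigurationError("reversal_hazard must lie in [0, 1]")


@dataclass
class TrialRecord:
    """One trial of a session.

    ``criterion_armed`` is the hazard state *entering* the trial;
    ``reversal_here`` flags a contingency flip immediately before this trial.
    Missed trials carry ``choice``/``outcome``/``correct`` of ``None``.
    """

    t: int
    good_stimulus: str
    choice: Optional[str]
    outcome: Optional[str]  # "win" | "loss" | None
    correct: Optional[bool]
    criterion_armed: bool
    reversal_here: bool
    onset_stim: float
    onset_feedback: float
    iti: float

    @property
    def answered(self) -> bool:
        return self.choice is not None


@dataclass
class SessionData:
    """Ordered trials of one subject-session; the unit of likelihood evaluation."""

    subject_id: str
    session_label: str
    trials: list[TrialRecord]
    config: TaskConfig = field(default_factory=TaskConfig)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_answered(self) -> int:
        return sum(tr.answered for tr in self.trials)

    def encode(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer encoding for the likelihood kernels.

        Returns ``(choices, outcomes)`` int8 arrays: choice 0=A, 1=B,
        -1=missed; outcome 1=win, 0=loss, -1=none.
        """
        n = len(self.trials)
        choices = np.full(n, -1, dtype=np.int8)
        outcomes = np.full(n, -1, dtype=np.int8)
        for i, tr in enumerate(self.trials):
            if tr.answered:
                if tr.outcome not in ("win", "loss"):
                    raise ValueError(
                        f"answered trial {tr.t} of {self.subject_id}/"
                        f"{self.session_label} has no outcome"
                    )
                choices[i] = OPTIONS.index(tr.choice)
                outcomes[i] = 1 if tr.outcome == "win" else 0
            elif tr.outcome is not None:
                raise ValueError(f"missed trial {tr.t} carries an outcome")
        return choices, outcomes

    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.session_label)


# ---------------------------------------------------------------------------
# agents

class QLearningAgent:
    """Simulated participant: softmax choices over Q-values it updates itself."""

    def __init__(self, spec: ModelSpec, params: ParameterSet):
        params.validate(spec)
        self.spec = spec
        self.params = params
        self.q = [params.q_init, 0.0]

    def choose(self, draw: float, good_index: int) -> int:
        return simulate_choice(self.spec, self.params, tuple(self.q), draw)

    def observe(self, choice: int, won: bool) -> None:
        p = self.params
        r = p.beta_rew if won else p.beta_pun
        self.q[choice] += p.alpha * (r - self.q[choice])
        if self.spec.double_update:
            other = 1 - choice
            self.q[other] += p.alpha * (-r - self.q[other])


class OracleAgent:
    """Scripted agent that always chooses the currently good stimulus."""

    def choose(self, draw: float, good_index: int) -> int:
        return good_index

    def observe(self, choice: int, won: bool) -> None:
        pass


class ScriptedAgent:
    """Plays back a fixed choice sequence (indices into ``OPTIONS``)."""

    def __init__(self, choices: Sequence[int]):
        self._choices = list(choices)
        self._i = 0

    def choose(self, draw: float, good_index: int) -> int:
        c = self._choices[self._i]
        self._i += 1
        return c

    def observe(self, choice: int, won: bool) -> None:
        pass


# ---------------------------------------------------------------------------
# reversal state machine

def criterion_met(recent_correct: Sequence[bool], config: TaskConfig) -> bool:
    """True iff >= criterion_hits correct among the last criterion_window
    completed trials; evaluable only once a full window exists."""
    if len(recent_correct) < config.criterion_window:
        return False
    window = recent_correct[-config.criterion_window:]
    return sum(window) >= config.criterion_hits


def update_reversal_state(
    recent_correct: Sequence[bool],
    armed: bool,
    config: TaskConfig,
    draw: float,
) -> tuple[bool, bool]:
    """Advance the reversal hazard state machine by one trial.

    Parameters
    ----------
    recent_correct
        Correctness flags of all completed (answered) trials so far.
    armed
        Hazard state entering the current trial.
    draw
        Uniform variate deciding whether an armed hazard fires.

    Returns
    -------
    (armed', reverse_now)
        ``reverse_now`` is True iff the state entering the trial was armed and
        ``draw < reversal_hazard``; ``armed'`` is re-evaluated from the
        sliding window and reset to False when a reversal fires.
    """
    reverse_now = bool(armed) and draw < config.reversal_hazard
    armed_next = False if reverse_now else criterion_met(recent_correct, config)
    return armed_next, reverse_now


def _draw_iti(rng: np.random.Generator, config: TaskConfig) -> float:
    # inverse-CDF sample of an exponential(iti_rate) truncated to iti_range
    lo, hi = config.iti_range
    u = rng.random()
    mass = 1.0 - math.exp(-config.iti_rate * (hi - lo))
    return lo - math.log(1.0 - u * mass) / config.iti_rate


# ---------------------------------------------------------------------------
# session / cohort generation

def generate_session(
    config: TaskConfig,
    agent,
    seed: int,
    subject_id: str = "sim",
    session_label: str = "synthetic",
) -> SessionData:
    """Simulate one complete session of the task.

    The agent is any object with ``choose(draw, good_index) -> 0|1`` and
    ``observe(choice, won)``. Outcomes are Bernoulli(p_reward_good) given a
    correct choice and Bernoulli(1 - p_reward_good) otherwise; the reversal
    state machine follows :func:`update_reversal_state`. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    good = 0  # index into OPTIONS
    armed = False
    flags: list[bool] = []
    trials: list[TrialRecord] = []
    onset_stim = 0.0

    for t in range(1, config.n_trials + 1):
        u_rev = rng.random()
        entering_armed = armed
        _, reverse_now = update_reversal_state(flags, armed, config, u_rev)
        if reverse_now:
            good = 1 - good

        u_miss = rng.random()
        missed = u_miss < config.miss_probability
        choice = outcome = correct = None
        if not missed:
            c = agent.choose(rng.random(), good)
            if c not in (0, 1):
                raise ValueError(f"agent returned invalid choice {c!r}")
            is_correct = c == good
            p_win = config.p_reward_good if is_correct else 1.0 - config.p_reward_good
            won = rng.random() < p_win
            agent.observe(c, won)
            choice = OPTIONS[c]
            outcome = "win" if won else "loss"
            correct = is_correct
            flags.append(is_correct)

        armed = False if reverse_now else criterion_met(flags, config)

        iti = _draw_iti(rng, config)
        onset_feedback = onset_stim + config.stim_duration
        trials.append(
            TrialRecord(
                t=t,
                good_stimulus=OPTIONS[good],
                choice=choice,
                outcome=outcome,
                correct=correct,
                criterion_armed=entering_armed,
                reversal_here=reverse_now,
                onset_stim=onset_stim,
                onset_feedback=onset_feedback,
                iti=iti,
            )
        )
        onset_stim = onset_feedback + config.feedback_duration + iti

    return SessionData(subject_id, session_label, trials, config)


def compute_payout(session: SessionData) -> float:
    """Session payout in SEK: summed feedback clamped to [payout_min, payout_max]."""
    cfg = session.config
    raw = 0.0
    for tr in session.trials:
        if tr.outcome == "win":
            raw += cfg.win_amount
        elif tr.outcome == "loss":
            raw += cfg.loss_amount
    return float(min(max(raw, cfg.payout_min), cfg.payout_max))


# group-level generating distribution in inference space (a, b_rew, b_pun, q0);
# means chosen so the sensitivity means sit at the reported group scales
DEFAULT_GROUP_MEAN = {"a": -0.85, "b_rew": 2.0, "b_pun": -1.0, "q0": 0.0}
DEFAULT_GROUP_SD = {"a": 0.8, "b_rew": 0.87, "b_pun": 0.5, "q0": 0.3}
SESSION_LABELS = ("placebo", "ghrelin")


@dataclass
class AgentPopulationSpec:
    """Group-level Gaussian over inference-space parameters for a synthetic cohort."""

    n_subjects: int = 30
    group_mean: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_MEAN))
    group_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_SD))
    model: ModelSpec = WINNING_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        for name in self.model.active_names:
            if name not in self.group_mean or name not in self.group_sd:
                raise ConfigurationError(f"group moments missing dimension {name!r}")
            if not self.group_sd[name] > 0:
                raise ConfigurationError(f"group_sd[{name!r}] must be positive")


@dataclass
class SyntheticCohort:
    """Paired placebo/ghrelin sessions plus the generating truth per session."""

    sessions: list[SessionData]
    true_parameters: pd.DataFrame  # subject_id, session_label, alpha, beta_rew, beta_pun, q_init
    spec: AgentPopulationSpec

    def by_subject(self) -> dict[str, dict[str, SessionData]]:
        out: dict[str, dict[str, SessionData]] = {}
        for s in self.sessions:
            out.setdefault(s.subject_id, {})[s.session_label] = s
        return out


def generate_cohort(
    spec: AgentPopulationSpec,
    config: TaskConfig | None = None,
) -> SyntheticCohort:
    """Simulate a two-session within-subject cohort.

    Per subject and session, an inference-space parameter vector is drawn from
    the group Gaussian and mapped to natural space; the two sessions are
    independent (labels ``placebo`` and ``ghrelin``). The generating
    parameters are recorded in the ``true_parameters`` table for recovery
    studies. Reproducible given ``spec.seed``.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(spec.seed)
    names = spec.model.active_names
    mu = np.array([spec.group_mean[k] for k in names])
    sd = np.array([spec.group_sd[k] for k in names])

    sessions: list[SessionData] = []
    records: list[dict] = []
    for i in range(spec.n_subjects):
        sid = f"sub{i + 1:03d}"
        for label in SESSION_LABELS:
            vec = mu + sd * rng.standard_normal(len(names))
            params = to_natural(spec.model, vec)
            agent = QLearningAgent(spec.model, params)
            session_seed = int(rng.integers(0, 2**31 - 1))
            sessions.append(
                generate_session(config, agent, session_seed, sid, label)
            )
            records.append(
                {
                    "subject_id": sid,
                    "session_label": label,
                    "alpha": params.alpha,
                    "beta_rew": params.beta_rew,
                    "beta_pun": params.beta_pun,
                    "q_init": params.q_init,
                }
            )
    return SyntheticCohort(sessions, pd.DataFrame.from_records(records), spec)
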