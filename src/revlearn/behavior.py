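"""Model-free behavioral summaries and the within-subject statistics battery.

Covers percent-correct / switch / reversal summaries, the reversal-count
exclusion rule, paired t-tests with Cohen's d, a z-style Wilcoxon signed-rank
test, Pearson correlations, and the exploratory win/loss feedback switch
analysis comparing the two drug sessions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import SessionData


class StatsError(ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass
class BehavioralSummary:
    pct_correct: float
    n_switches: int
    n_reversals: int
    n_missed: int


@dataclass
class PairedTestResult:
    statistic: float  # t for the paired t, z for the Wilcoxon
    df: Optional[int]
    p_value: float
    cohen_d: Optional[float]
    method: str


def cohen_d_from_t(t: float, n: int) -> float:
    """Paired-design effect size d = t / sqrt(n)."""
    return float(t) / math.sqrt(n)


def summarize_session(session: SessionData) -> BehavioralSummary:
    """Percent correct, switches between consecutive answered trials,
    reversals reached, and missed trials for one session."""
    answered = [tr for tr in session.trials if tr.answered]
    if not answered:
        raise StatsError(f"session {session.key()} has no answered trials")
    n_correct = sum(tr.correct for tr in answered)
    n_switches = sum(
        prev.choice != cur.choice for prev, cur in zip(answered, answered[1:])
    )
    return BehavioralSummary(
        pct_correct=100.0 * n_correct / len(answered),
        n_switches=int(n_switches),
        n_reversals=sum(tr.reversal_here for tr in session.trials),
        n_missed=len(session.trials) - len(answered),
    )


def apply_exclusion(
    sessions: Sequence[SessionData], min_reversals: int = 5
) -> tuple[list[SessionData], pd.DataFrame]:
    """Drop subjects with fewer than ``min_reversals`` reversals in any session.

    Both of an excluded subject's sessions are removed. Returns the kept
    sessions and an exclusion log (subject_id, session_label, n_reversals).
    """
    by_subject: dict[str, list[SessionData]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
    kept: list[SessionData] = []
    log_rows = []
    for sid, subj_sessions in by_subject.items():
        counts = {
            s.session_label: sum(tr.reversal_here for tr in s.trials)
            for s in subj_sessions
        }
        if any(c < min_reversals for c in counts.values()):
            for label, c in counts.items():
                log_rows.append(
                    {"subject_id": sid, "session_label": label, "n_reversals": c}
                )
        else:
            kept.extend(subj_sessions)
    return kept, pd.DataFrame(log_rows, columns=["subject_id", "session_label", "n_reversals"])


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Classic paired t-test with Cohen's d = t / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise StatsError("paired_t needs two equal-length 1-d samples, n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0) and not np.allclose(d, 0.0):
        raise StatsError("paired differences have zero variance")
    if np.allclose(d, 0.0):
        return PairedTestResult(0.0, len(x) - 1, 1.0, 0.0, "paired t")
    t, p = stats.ttest_rel(x, y)
    return PairedTestResult(
        float(t), len(x) - 1, float(p), cohen_d_from_t(float(t), len(x)), "paired t"
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Wilcoxon signed-rank test reported as a z statistic.

    Zero differences are dropped, tied absolute differences get mid-ranks,
    and the two-sided p comes from the tie-corrected normal approximation
    without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("wilcoxon needs two equal-length 1-d samples")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n < 2:
        raise StatsError("fewer than 2 non-zero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        raise StatsError("all paired differences are tied")
    z = (w_pos - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return PairedTestResult(float(z), None, float(p), None, "wilcoxon signed-rank")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise StatsError("pearson_r needs equal-length samples, n >= 3")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise StatsError("zero variance input to pearson_r")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SwitchAnalysis:
    """Per-subject switch probabilities after win/loss feedback and their
    placebo-to-ghrelin changes."""

    table: pd.DataFrame  # subject_id, session_label, p_switch_after_win, p_switch_after_loss
    delta_win: np.ndarray  # ghrelin - placebo, per subject
    delta_loss: np.ndarray
    contrast: PairedTestResult  # paired test of delta_loss vs delta_win
    dropped_subjects: list[str]


def switch_probabilities(session: SessionData) -> dict[str, float]:
    """P(switch | previous answered trial was a win / a loss) for one session.

    Consecutive answered trials only; missed trials are skipped. A cell with
    no qualifying transitions is NaN.
    """
    answered = [tr for tr in session.trials if tr.answered]
    counts = {"win": [0, 0], "loss": [0, 0]}  # outcome -> [switches, total]
    for prev, cur in zip(answered, answered[1:]):
        c = counts[prev.outcome]
        c[1] += 1
        c[0] += prev.choice != cur.choice
    return {
        f"p_switch_after_{k}": (c[0] / c[1] if c[1] else float("nan"))
        for k, c in counts.items()
    }


def switch_feedback_analysis(
    sessions: Sequence[SessionData],
    labels: tuple[str, str] = ("placebo", "ghrelin"),
) -> SwitchAnalysis:
    """Exploratory analysis: does the session change switch behavior more
    after losses than after wins?

    Per subject and session, switch probabilities after win and loss feedback
    are computed; per subject, deltas (second label minus first) are formed
    and the loss-delta is compared to the win-delta with a paired t-test.
    Subjects lacking either session or a defined cell are dropped with a log.
    """
    by_subject: dict[str, dict[str, SessionData]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, {})[s.session_label] = s

    rows = []
    deltas_win, deltas_loss, dropped = [], [], []
    for sid in sorted(by_subject):
        have = by_subject[sid]
        if not all(lbl in have for lbl in labels):
            dropped.append(sid)
            continue
        probs = {lbl: switch_probabilities(have[lbl]) for lbl in labels}
        for lbl in labels:
            rows.append({"subject_id": sid, "session_label": lbl, **probs[lbl]})
        dw = probs[labels[1]]["p_switch_after_win"] - probs[labels[0]]["p_switch_after_win"]
        dl = probs[labels[1]]["p_switch_after_loss"] - probs[labels[0]]["p_switch_after_loss"]
        if math.isnan(dw) or math.isnan(dl):
            dropped.append(sid)
            continue
        deltas_win.append(dw)
        deltas_loss.append(dl)

    contrast = paired_t(deltas_loss, deltas_win)
    return SwitchAnalysis(
        table=pd.DataFrame(rows),
        delta_win=np.array(deltas_win),
        delta_loss=np.array(deltas_loss),
        contrast=contrast,
        dropped_subjects=dropped,
    )


def cohort_summary_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Long-format behavioral summary table, one row per session."""
    rows = []
    for s in sessions:
        summ = summarize_session(s)
        rows.append(
            {
                "subject_id": s.subject_id,
                "session_label": s.session_label,
                "pct_correct": summ.pct_correct,
                "n_switches": summ.n_switches,
                "n_reversals": summ.n_reversals,
                "n_missed": summ.n_missed,
            }
        )
    return pd.DataFrame.from_records(rows)
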