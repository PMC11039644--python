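"""Reading and writing the tab-separated session tables and task configs."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .task import SessionData, TaskConfig, TrialRecord

SESSION_COLUMNS = [
    "subject_id",
    "session_label",
    "trial",
    "good_stimulus",
    "choice",
    "outcome",
    "correct",
    "reversal",
    "onset_stim",
    "onset_feedback",
    "iti",
]


def sessions_to_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for tr in s.trials:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "session_label": s.session_label,
                    "trial": tr.t,
                    "good_stimulus": tr.good_stimulus,
                    "choice": tr.choice if tr.answered else "NA",
                    "outcome": tr.outcome if tr.answered else "NA",
                    "correct": int(tr.correct) if tr.answered else "NA",
                    "reversal": int(tr.reversal_here),
                    "onset_stim": round(tr.onset_stim, 6),
                    "onset_feedback": round(tr.onset_feedback, 6),
                    "iti": round(tr.iti, 6),
                }
            )
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_sessions(sessions: Sequence[SessionData], path: str | Path) -> None:
    """One row per trial, header required, missed trials encoded as NA."""
    sessions_to_frame(sessions).to_csv(path, sep="\t", index=False)


def read_sessions(path: str | Path, config: TaskConfig | None = None) -> list[SessionData]:
    """Rebuild SessionData objects from a session table.

    ``config`` supplies the task constants (defaults used when omitted); the
    table itself carries everything the likelihood needs.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA"])
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session table missing columns: {sorted(missing)}")
    config = config or TaskConfig()
    sessions = []
    for (sid, label), grp in df.groupby(["subject_id", "session_label"], sort=False):
        grp = grp.sort_values("trial")
        trials = []
        for row in grp.itertuples(index=False):
            answered = isinstance(row.choice, str) and row.choice in ("A", "B")
            trials.append(
                TrialRecord(
                    t=int(row.trial),
                    good_stimulus=str(row.good_stimulus),
                    choice=row.choice if answered else None,
                    outcome=row.outcome if answered else None,
                    correct=bool(int(row.correct)) if answered else None,
                    criterion_armed=False,  # not serialised; derived state
                    reversal_here=bool(int(row.reversal)),
                    onset_stim=float(row.onset_stim),
                    onset_feedback=float(row.onset_feedback),
                    iti=float(row.iti),
                )
            )
        sessions.append(SessionData(str(sid), str(label), trials, config))
    return sessions


def write_true_parameters(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["subject_id", "session_label", "alpha", "beta_rew", "beta_pun", "q_init"]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.8f")


def load_config(path: str | Path) -> TaskConfig:
    """Task config from a key: value text file (YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "iti_range" in raw:
        raw["iti_range"] = tuple(float(v) for v in raw["iti_range"])
    return TaskConfig(**raw)
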