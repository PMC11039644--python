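"""Prediction-error parametric-modulator event files for neuroimaging GLMs.

Under the fitted winning-model parameters, trial-by-trial prediction errors
are attached as a parametric modulator to a feedback-onset regressor; missed
trials go to a separate no-response events table. Files are written as
tab-separated events tables (onset, duration, trial_type, modulator, trial)
with onset origin at session start.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ModelSpec, ParameterSet, session_loglik
from .task import SessionData


class ExportError(ValueError):
    """Raised when a session lacks the timing needed for export."""


@dataclass
class ModulatorEvents:
    events: pd.DataFrame  # answered trials: onset, duration, trial_type, modulator, trial
    no_response: pd.DataFrame  # missed trials: onset, duration, trial_type, trial
    subject_id: str
    session_label: str
    model_name: str
    params: ParameterSet
    mean_centered: bool


def export_pe_events(
    session: SessionData,
    spec: ModelSpec,
    params: ParameterSet,
    mean_center: bool = True,
    path: str | Path | None = None,
) -> ModulatorEvents:
    """Compute the modulator table for one fitted session.

    The modulator values are exactly the prediction errors of the model
    trajectory (optionally mean-centered over answered trials); onsets are
    feedback onsets and durations the feedback duration. When ``path`` is
    given, ``<path>`` gets the modulator table and ``<path stem>_noresp.tsv``
    the no-response table.
    """
    for tr in session.trials:
        if tr.onset_feedback is None or not np.isfinite(tr.onset_feedback):
            raise ExportError(f"trial {tr.t} lacks a feedback onset")
    traj = session_loglik(spec, params, session)
    dur = session.config.feedback_duration

    answered = [tr for tr in session.trials if tr.answered]
    pe = np.array([traj.pe[tr.t - 1] for tr in answered])
    if mean_center and len(pe):
        pe = pe - pe.mean()
    events = pd.DataFrame(
        {
            "onset": [tr.onset_feedback for tr in answered],
            "duration": dur,
            "trial_type": "feedback",
            "modulator": pe,
            "trial": [tr.t for tr in answered],
        }
    )
    missed = [tr for tr in session.trials if not tr.answered]
    no_response = pd.DataFrame(
        {
            "onset": [tr.onset_feedback for tr in missed],
            "duration": dur,
            "trial_type": "no_response",
            "trial": [tr.t for tr in missed],
        }
    )
    out = ModulatorEvents(
        events,
        no_response,
        session.subject_id,
        session.session_label,
        spec.name,
        params,
        mean_center,
    )
    if path is not None:
        path = Path(path)
        events.to_csv(path, sep="\t", index=False, float_format="%.6f")
        noresp_path = path.with_name(path.stem + "_noresp.tsv")
        no_response.to_csv(noresp_path, sep="\t", index=False, float_format="%.6f")
    return out
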