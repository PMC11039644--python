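"""Export trial-by-trial prediction errors as parametric-modulator events.

Simulates one session, fits the winning model to it under a group prior,
and writes the feedback-onset events file whose modulator column holds the
fitted model's prediction errors (mean-centered), plus a separate
no-response table for missed trials.
"""

from pathlib import Path

from revlearn import (
    ParameterSet,
    QLearningAgent,
    TaskConfig,
    WINNING_MODEL,
    generate_session,
    to_natural,
)
from revlearn.events import export_pe_events
from revlearn.hierfit import default_prior, fit_map_session

config = TaskConfig(miss_probability=0.03)
true = ParameterSet(alpha=0.3, beta_rew=2.0, beta_pun=-1.0, q_init=0.0)
session = generate_session(config, QLearningAgent(WINNING_MODEL, true), seed=21,
                           subject_id="sub001", session_label="placebo")

fit = fit_map_session(WINNING_MODEL, session, default_prior(WINNING_MODEL), seed=0)
fitted = to_natural(WINNING_MODEL, fit.theta_map)
print(f"fitted: alpha={fitted.alpha:.2f}, beta_rew={fitted.beta_rew:+.2f}, "
      f"beta_pun={fitted.beta_pun:+.2f}, q_init={fitted.q_init:+.2f}")

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
path = out / "sub001_placebo_pe.tsv"
ev = export_pe_events(session, WINNING_MODEL, fitted, path=path)
print(f"wrote {len(ev.events)} modulator rows and {len(ev.no_response)} "
      f"no-response rows to {path}")
print(ev.events.head(3).to_string(index=False))
# The modulator column is the reward prediction error at each feedback onset;
# downstream GLMs use it to weight the feedback regressor trial by trial.
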