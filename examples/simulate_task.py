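"""Simulate the probabilistic reversal-learning task.

Builds one session played by a Q-learning agent and a small two-session
cohort, then prints the behavioral summary: percent correct, switches,
reversals reached, and the clamped monetary payout.
"""

from revlearn import (
    AgentPopulationSpec,
    ParameterSet,
    QLearningAgent,
    TaskConfig,
    WINNING_MODEL,
    compute_payout,
    generate_cohort,
    generate_session,
    summarize_session,
)

config = TaskConfig()  # 200 trials, 80/20 contingencies, 5-of-6 criterion, 20% hazard
agent = QLearningAgent(WINNING_MODEL, ParameterSet(alpha=0.3, beta_rew=2.0, beta_pun=-1.0))
session = generate_session(config, agent, seed=7)

s = summarize_session(session)
print(f"one session: {s.pct_correct:.1f}% correct, {s.n_switches} switches, "
      f"{s.n_reversals} reversals, payout {compute_payout(session):.0f} SEK")

cohort = generate_cohort(AgentPopulationSpec(n_subjects=4, seed=1), config)
print(f"cohort: {len(cohort.sessions)} sessions "
      f"({cohort.true_parameters['session_label'].nunique()} per subject), "
      f"true beta_rew mean {cohort.true_parameters['beta_rew'].mean():.2f}, "
      f"beta_pun mean {cohort.true_parameters['beta_pun'].mean():.2f}")
# The percent correct reflects how sharply the agent's learned value gap
# separates the options; reversals reached tracks task engagement.
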