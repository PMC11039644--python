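"""Q-learning model family: likelihoods, latents, parameter maps."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revlearn.models import (
    MODEL_FAMILY,
    WINNING_MODEL,
    DomainError,
    ModelSpec,
    ParameterSet,
    from_natural,
    get_model,
    loglik_grad_arrays,
    session_loglik,
    simulate_choice,
    to_natural,
    trajectory_frame,
)

from helpers import make_session, naive_loglik, random_session


def random_params(rng, spec):
    alpha = rng.uniform(0.05, 0.95)
    b_rew = rng.normal(1.5, 1.0)
    b_pun = rng.normal(-1.0, 1.0) if spec.separate_sensitivities else -b_rew
    q0 = rng.normal(0.0, 0.5) if spec.free_q_init else 0.0
    return ParameterSet(alpha, b_rew, b_pun, q0)


class TestModelFamily:
    def test_eight_distinct_variants(self):
        assert len(MODEL_FAMILY) == 8
        assert len({m.name for m in MODEL_FAMILY}) == 8
        assert WINNING_MODEL in MODEL_FAMILY
        assert WINNING_MODEL.name == "DU-SS-Qi"
        assert get_model("SU-CS-Q0") == ModelSpec(False, False, False)

    @pytest.mark.parametrize("spec", MODEL_FAMILY, ids=lambda m: m.name)
    def test_active_dimensions(self, spec):
        n = 2 + spec.separate_sensitivities + spec.free_q_init
        assert spec.n_active == n
        assert spec.active_names[:2] == ("a", "b_rew")


class TestLikelihood:
    @pytest.mark.parametrize("spec", MODEL_FAMILY, ids=lambda m: m.name)
    def test_matches_naive_oracle(self, spec, rng):
        """Kernel likelihood equals a literal per-trial loop to 1e-10."""
        for _ in range(25):
            sess = random_session(rng, n_trials=50, p_miss=0.1)
            p = random_params(rng, spec)
            traj = session_loglik(spec, p, sess)
            expected = naive_loglik(
                [tr.choice for tr in sess.trials],
                [tr.outcome for tr in sess.trials],
                p.alpha, p.beta_rew, p.beta_pun, p.q_init, spec.double_update,
            )
            assert traj.loglik == pytest.approx(expected, abs=1e-10)

    def test_hand_computed_three_trial_session(self):
        """Single update, alpha=.5, b_rew=2, b_pun=-1: first trial p=.5,
        then Q_A=1 so p(A)=sigmoid(1), then Q_A back to 0 so p(B)=.5."""
        sess = make_session(["A", "A", "B"], ["win", "loss", "win"])
        spec = ModelSpec(False, True, False)
        traj = session_loglik(spec, ParameterSet(0.5, 2.0, -1.0, 0.0), sess)
        expected = 2 * math.log(0.5) + math.log(1.0 / (1.0 + math.exp(-1.0)))
        assert traj.loglik == pytest.approx(expected, abs=1e-10)
        assert traj.q_values[1, 0] == pytest.approx(1.0)
        assert traj.pe[0] == pytest.approx(2.0)

    def test_zero_sensitivities_give_chance_likelihood(self):
        sess = make_session(["A"] * 200, ["win", "loss"] * 100)
        for spec in MODEL_FAMILY:
            p = ParameterSet(0.4, 0.0, 0.0, 0.0)
            traj = session_loglik(spec, p, sess)
            assert traj.loglik == pytest.approx(200 * math.log(0.5), abs=1e-9)

    def test_first_win_prediction_error_is_beta_rew(self, rng):
        sess = make_session(["B", "A"], ["win", "loss"])
        p = ParameterSet(0.3, 2.5, -1.5, 0.0)
        traj = session_loglik(WINNING_MODEL, p, sess)
        assert traj.pe[0] == pytest.approx(2.5)

    def test_nested_models_agree_on_tied_parameters(self, rng):
        """The full model with beta_pun=-beta_rew and q_init=0 reproduces the
        restricted variants' likelihood on identical data."""
        sess = random_session(rng, n_trials=60)
        full = ModelSpec(True, True, True)
        p = ParameterSet(0.35, 1.8, -1.8, 0.0)
        ll_full = session_loglik(full, p, sess).loglik
        for restricted in (ModelSpec(True, False, True), ModelSpec(True, True, False),
                           ModelSpec(True, False, False)):
            assert session_loglik(restricted, p, sess).loglik == pytest.approx(
                ll_full, abs=1e-12
            )

    def test_tiny_alpha_freezes_values(self):
        """As alpha -> 0 the Q-values never move, so the likelihood depends
        only on the initial bias."""
        sess = make_session(["A", "B"] * 30, ["win", "loss"] * 30)
        p = ParameterSet(1e-12, 2.0, -1.0, 0.7)
        traj = session_loglik(WINNING_MODEL, p, sess)
        p_a = 1.0 / (1.0 + math.exp(-0.7))
        expected = 30 * (math.log(p_a) + math.log(1 - p_a))
        assert traj.loglik == pytest.approx(expected, abs=1e-6)
        assert np.allclose(traj.q_values[:, 0], 0.7, atol=1e-9)

    def test_missed_trials_skipped_with_q_carried_forward(self, rng):
        base = random_session(rng, n_trials=30)
        choices = [tr.choice for tr in base.trials]
        outcomes = [tr.outcome for tr in base.trials]
        with_miss = make_session(
            choices[:10] + [None, None] + choices[10:],
            outcomes[:10] + [None, None] + outcomes[10:],
        )
        p = random_params(rng, WINNING_MODEL)
        assert session_loglik(WINNING_MODEL, p, with_miss).loglik == pytest.approx(
            session_loglik(WINNING_MODEL, p, base).loglik, abs=1e-12
        )
        traj = session_loglik(WINNING_MODEL, p, with_miss)
        assert np.isnan(traj.pe[10]) and np.isnan(traj.choice_prob[10])

    def test_double_update_drives_value_sum_to_zero(self):
        """Paired update: S = Q(A)+Q(B) contracts by (1-alpha) each answered
        trial, so the sum decays geometrically toward 0."""
        n = 100
        sess = make_session(["A"] * n, ["win"] * n)
        p = ParameterSet(0.5, 2.0, -1.0, 4.0)
        traj = session_loglik(WINNING_MODEL, p, sess)
        sums = traj.q_values.sum(axis=1)
        assert sums[0] == pytest.approx(4.0)
        for t in range(1, n):
            assert sums[t] == pytest.approx(4.0 * 0.5**t, abs=1e-12)

    def test_answered_trial_without_outcome_rejected(self):
        sess = make_session(["A"], ["win"])
        sess.trials[0].outcome = None
        with pytest.raises(ValueError, match="outcome"):
            session_loglik(WINNING_MODEL, ParameterSet(0.5, 1, -1, 0), sess)

    def test_analytic_gradient_matches_finite_differences(self, rng):
        sess = random_session(rng, n_trials=40)
        choices, outcomes = sess.encode()
        for spec in MODEL_FAMILY:
            v = rng.normal(0, 1, spec.n_active)
            _, g = loglik_grad_arrays(spec, choices, outcomes, v)
            for i in range(spec.n_active):
                e = np.zeros(spec.n_active)
                e[i] = 1e-6
                lo = session_loglik(spec, to_natural(spec, v - e), sess).loglik
                hi = session_loglik(spec, to_natural(spec, v + e), sess).loglik
                assert g[i] == pytest.approx((hi - lo) / 2e-6, rel=1e-4, abs=1e-6)


class TestParameterMaps:
    def test_logistic_midpoint(self):
        p = to_natural(WINNING_MODEL, np.zeros(4))
        assert p.alpha == pytest.approx(0.5)

    def test_alpha_monotone_in_a(self):
        alphas = [
            to_natural(WINNING_MODEL, np.array([a, 0, 0, 0])).alpha
            for a in np.linspace(-10, 10, 21)
        ]
        assert all(x < y for x, y in zip(alphas, alphas[1:]))
        assert alphas[-1] > 0.9999

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.floats(-5, 5),
        b_rew=st.floats(-3, 3),
        b_pun=st.floats(-3, 3),
        q0=st.floats(-2, 2),
    )
    def test_roundtrip_identity(self, a, b_rew, b_pun, q0):
        for spec in MODEL_FAMILY:
            vec = np.array([a, b_rew, b_pun, q0][: spec.n_active])
            # reorder to active names (b_pun/q0 slots differ by spec)
            vec = np.array(
                [dict(zip(("a", "b_rew", "b_pun", "q0"), (a, b_rew, b_pun, q0)))[k]
                 for k in spec.active_names]
            )
            back = from_natural(spec, to_natural(spec, vec))
            assert np.allclose(back, vec, atol=1e-12)

    def test_constraint_violations_rejected(self):
        with pytest.raises(DomainError):
            ParameterSet(1.2, 1.0, -1.0, 0.0).validate(WINNING_MODEL)
        with pytest.raises(DomainError):
            ParameterSet(0.5, 1.0, -0.5, 0.0).validate(ModelSpec(True, False, True))
        with pytest.raises(DomainError):
            ParameterSet(0.5, 1.0, -1.0, 0.3).validate(ModelSpec(True, True, False))
        with pytest.raises(DomainError):
            to_natural(WINNING_MODEL, np.array([np.nan, 0, 0, 0]))


class TestChoiceRule:
    def test_equal_values_give_even_odds(self):
        p = ParameterSet(0.5, 1.0, -1.0, 0.0)
        assert simulate_choice(WINNING_MODEL, p, (1.3, 1.3), 0.499) == 0
        assert simulate_choice(WINNING_MODEL, p, (1.3, 1.3), 0.501) == 1

    def test_large_difference_saturates(self):
        p = ParameterSet(0.5, 1.0, -1.0, 0.0)
        assert simulate_choice(WINNING_MODEL, p, (20.0, 0.0), 0.9999) == 0

    def test_softmax_depends_only_on_value_difference(self, rng):
        p = ParameterSet(0.5, 1.0, -1.0, 0.0)
        for _ in range(20):
            qa, qb, c, draw = rng.normal(size=4)
            u = (draw + 1) % 1.0
            assert simulate_choice(WINNING_MODEL, p, (qa, qb), u) == simulate_choice(
                WINNING_MODEL, p, (qa + c, qb + c), u
            )

    def test_nonfinite_values_rejected(self):
        with pytest.raises(DomainError):
            simulate_choice(WINNING_MODEL, ParameterSet(0.5, 1, -1, 0), (np.inf, 0), 0.5)


def test_trajectory_frame_columns(rng):
    sess = random_session(rng, n_trials=10)
    traj = session_loglik(WINNING_MODEL, random_params(rng, WINNING_MODEL), sess)
    df = trajectory_frame(sess, traj)
    assert list(df.columns) == ["trial", "qA", "qB", "p_choice", "pe"]
    assert len(df) == 10
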