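"""RL models: transforms, prediction errors, softmax, likelihood oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prtlearn as pl
from prtlearn.models import (
    MODELS,
    LatentState,
    get_model,
    init_state,
    inverse_transform_params,
    transform_params,
    trials_to_arrays,
)

from conftest import make_trials


# ---------------------------------------------------------------------------
# Independent oracle: a from-scratch, dict-based implementation of the five
# models, written directly from their definitions, sharing no code with the
# package.  Used to pin session_loglik on short toy sessions.
# ---------------------------------------------------------------------------

def oracle_loglik(model, p, trials, aversive=True):
    """trials: list of (stimulus, action, reward) in 0/1 coding."""
    q = {(a, s): 0.0 for a in (0, 1) for s in (0, 1)}
    qa = {0: 0.0, 1: 0.0}
    zeta = p.get("zeta", 1.0)
    ll = 0.0
    for s, a, r in trials:
        if model == "action_only":
            vals = {act: qa[act] for act in (0, 1)}
        elif model == "belief":
            vals = {
                act: zeta * q[(act, s)] + (1 - zeta) * q[(act, 1 - s)]
                for act in (0, 1)
            }
        else:
            vals = {act: q[(act, s)] for act in (0, 1)}
        vals[0] += p["q0"]
        vals[s] += p["gamma"]  # instructed response equals the stimulus
        p0 = 1.0 / (1.0 + math.exp(vals[1] - vals[0]))
        ll += math.log(p0 if a == 0 else 1.0 - p0)
        outcome = p["beta_reward"] * r
        if model == "punishment":
            outcome += (-1 if aversive else 1) * p["beta_punishment"] * (1 - r)
        if model == "action_only":
            pe = outcome - qa[a]
            qa[a] += p["alpha"] * pe
        elif model == "belief":
            pe = outcome - (zeta * q[(a, s)] + (1 - zeta) * q[(a, 1 - s)])
            q[(a, s)] += p["alpha"] * zeta * pe
            q[(a, 1 - s)] += p["alpha"] * (1 - zeta) * pe
        else:
            pe = outcome - q[(a, s)]
            q[(a, s)] += p["alpha"] * pe
            if model == "counterfactual":
                q[(1 - a, 1 - s)] -= p["alpha"] * pe
    return ll


TOY_TRIALS = [(0, 0, 1), (1, 0, 0), (0, 1, 0), (1, 1, 1), (0, 0, 0), (1, 0, 0)]

ORACLE_PARAMS = {
    "alpha": 0.35, "beta_reward": 1.8, "beta_punishment": 0.9,
    "q0": 0.25, "gamma": 0.6, "zeta": 0.7,
}


def toy_frame(trials=TOY_TRIALS):
    stimuli = ["rich" if s == 0 else "lean" for s, _, _ in trials]
    corrects = [a == s for s, a, _ in trials]
    rewards = [r for _, _, r in trials]
    return make_trials(stimuli, corrects, rewards)


def oracle_param_vector():
    return pl.ParamVector(**ORACLE_PARAMS)


class TestTransforms:
    def test_reference_points(self):
        p = pl.ParamVector(alpha=0.5, beta_reward=1.0, beta_punishment=1.0,
                           q0=1.0, gamma=1.0)
        theta = transform_params(p, "punishment")
        np.testing.assert_allclose(theta, np.zeros(5), atol=1e-15)

    def test_alpha_closed_form_roundtrip(self):
        p = pl.ParamVector(alpha=0.8, beta_reward=1.0, beta_punishment=1.0,
                           q0=1.0, gamma=1.0)
        theta = transform_params(p, "punishment")
        assert theta[0] == pytest.approx(math.log(4), abs=1e-12)
        back = inverse_transform_params(theta, "punishment")
        assert back.alpha == pytest.approx(0.8, abs=1e-12)

    @given(theta=st.lists(st.floats(-8, 8), min_size=5, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_identity(self, theta):
        theta = np.array(theta)
        p = inverse_transform_params(theta, "belief")
        back = transform_params(p, "belief")
        np.testing.assert_allclose(back, theta, atol=1e-10)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError, match="logit"):
            transform_params(pl.ParamVector(alpha=1.0), "action_only")
        with pytest.raises(ValueError, match="log"):
            transform_params(pl.ParamVector(q0=0.0), "action_only")

    def test_monotone_componentwise(self):
        lo = transform_params(pl.ParamVector(alpha=0.2, beta_reward=0.5,
                                             q0=0.1, gamma=0.3), "action_only")
        hi = transform_params(pl.ParamVector(alpha=0.4, beta_reward=1.5,
                                             q0=0.2, gamma=0.9), "action_only")
        assert (hi > lo).all()


class TestPredictionError:
    def test_action_only_zero(self):
        state = init_state("action_only")
        p = pl.ParamVector(beta_reward=2.0)
        assert pl.prediction_error("action_only", p, 0, state, 0, 0) == 0.0

    def test_action_only_substitution(self):
        state = init_state("action_only")
        state.q_action[0] = 0.5
        p = pl.ParamVector(beta_reward=2.0)
        assert pl.prediction_error("action_only", p, 1, state, 0, 0) == pytest.approx(1.5)

    def test_punishment_aversive_sign(self):
        state = init_state("punishment")
        state.q_stim_action[0, 0] = 0.2
        p = pl.ParamVector(beta_punishment=0.5)
        pe = pl.prediction_error("punishment", p, 0, state, 0, 0)
        assert pe == pytest.approx(-0.7)

    def test_punishment_literal_sign_switch(self):
        state = init_state("punishment")
        state.q_stim_action[0, 0] = 0.2
        p = pl.ParamVector(beta_punishment=0.5)
        pe = pl.prediction_error("punishment", p, 0, state, 0, 0,
                                 punishment_sign="literal")
        assert pe == pytest.approx(0.3)

    def test_reward_sensitivity_scales_linearly(self):
        state = init_state("stimulus_action")
        p1 = pl.ParamVector(beta_reward=1.0)
        p2 = pl.ParamVector(beta_reward=2.0)
        pe1 = pl.prediction_error("stimulus_action", p1, 1, state, 0, 0)
        pe2 = pl.prediction_error("stimulus_action", p2, 1, state, 0, 0)
        assert pe2 == pytest.approx(2 * pe1)

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="unknown model"):
            pl.prediction_error("sarsa", pl.ParamVector(), 1, init_state(), 0, 0)


class TestUpdate:
    def test_zero_learning_rate(self):
        state = init_state("stimulus_action")
        pl.update_state(state, pe=1.0, alpha=0.0, a=0, s=0, model="stimulus_action")
        assert (state.q_stim_action == 0).all()

    def test_full_update_jumps_to_target(self):
        state = init_state("action_only")
        pl.update_state(state, pe=2.0, alpha=1.0, a=1, s=0, model="action_only")
        assert state.q_action[1] == pytest.approx(2.0)
        assert state.q_action[0] == 0.0

    def test_geometric_convergence_to_beta(self):
        p = pl.ParamVector(alpha=0.3, beta_reward=1.5)
        state = init_state("stimulus_action")
        gaps = []
        for _ in range(30):
            pe = pl.prediction_error("stimulus_action", p, 1, state, 0, 0)
            pl.update_state(state, pe, p.alpha, 0, 0, "stimulus_action")
            gaps.append(abs(p.beta_reward - state.q_stim_action[0, 0]))
        ratios = np.array(gaps[1:]) / np.array(gaps[:-1])
        np.testing.assert_allclose(ratios, 1 - p.alpha, atol=1e-9)

    def test_counterfactual_mirror(self):
        state = init_state("counterfactual")
        pl.update_state(state, pe=1.0, alpha=0.5, a=0, s=0, model="counterfactual")
        assert state.q_stim_action[0, 0] == pytest.approx(0.5)
        assert state.q_stim_action[1, 1] == pytest.approx(-0.5)
        assert state.q_stim_action[0, 1] == state.q_stim_action[1, 0] == 0.0


class TestChoiceProbability:
    def test_equal_values_chance(self):
        p = pl.ParamVector(q0=0.0, gamma=0.0)
        probs = pl.choice_probability("stimulus_action", p, init_state(), 0)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_unit_value_difference_logistic(self):
        p = pl.ParamVector(q0=1.0, gamma=0.0)  # V(0)-V(1) = 1
        probs = pl.choice_probability("stimulus_action", p, init_state(), 0)
        assert probs[0] == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)
        assert probs[0] == pytest.approx(0.7311, abs=1e-4)

    @pytest.mark.parametrize("model", sorted(MODELS))
    @given(q=st.lists(st.floats(-5, 5), min_size=4, max_size=4), s=st.integers(0, 1))
    @settings(max_examples=40, deadline=None)
    def test_normalisation(self, model, q, s):
        state = init_state(model)
        state.q_action[:] = q[:2]
        state.q_stim_action[:] = np.array(q).reshape(2, 2)
        p = pl.ParamVector(q0=0.3, gamma=0.4, zeta=0.6, beta_punishment=1.0)
        probs = pl.choice_probability(model, p, state, s)
        assert probs.sum() == pytest.approx(1.0)
        assert (probs > 0).all() and (probs < 1).all()


class TestNesting:
    def test_punishment_at_zero_equals_stimulus_action(self):
        df = toy_frame()
        p = oracle_param_vector()
        p.beta_punishment = 0.0
        ll_p = pl.session_loglik("punishment", p, df)
        ll_sa = pl.session_loglik("stimulus_action", p, df)
        assert ll_p == pytest.approx(ll_sa, abs=1e-12)

    def test_belief_at_one_equals_stimulus_action(self):
        df = toy_frame()
        p = oracle_param_vector()
        p.zeta = 1.0
        ll_b = pl.session_loglik("belief", p, df)
        ll_sa = pl.session_loglik("stimulus_action", p, df)
        assert ll_b == pytest.approx(ll_sa, abs=1e-12)

    def test_gamma_zero_removes_instruction_effect(self):
        """With gamma=0 (and no bias or learning signal) the agent cannot
        tell the instructed response apart: every choice is at chance."""
        p = pl.ParamVector(alpha=0.3, beta_reward=0.0, q0=0.0, gamma=0.0)
        state = init_state("stimulus_action")
        for s in (0, 1):
            probs = pl.choice_probability("stimulus_action", p, state, s)
            np.testing.assert_allclose(probs, [0.5, 0.5])


class TestSessionLoglik:
    def test_indifferent_parameters_exact_chance(self):
        df = toy_frame()
        p = pl.ParamVector(alpha=0.3, beta_reward=0.0, q0=0.0, gamma=0.0)
        assert pl.session_loglik("stimulus_action", p, df) == pytest.approx(
            len(df) * math.log(0.5), abs=1e-12
        )

    @pytest.mark.parametrize("model", sorted(MODELS))
    def test_matches_hand_enumeration_oracle(self, model):
        df = toy_frame()
        ll = pl.session_loglik(model, oracle_param_vector(), df)
        expected = oracle_loglik(model, ORACLE_PARAMS, TOY_TRIALS)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_literal_sign_matches_oracle(self):
        df = toy_frame()
        ll = pl.session_loglik("punishment", oracle_param_vector(), df,
                               punishment_sign="literal")
        expected = oracle_loglik("punishment", ORACLE_PARAMS, TOY_TRIALS,
                                 aversive=False)
        assert ll == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("model", sorted(MODELS))
    def test_kernel_equals_reference_engine(self, model, default_config):
        p = pl.ParamVector(alpha=0.3, beta_reward=1.2, beta_punishment=0.8,
                           q0=0.2, gamma=0.7, zeta=0.8)
        df = pl.simulate_agent_session(default_config, model, p, rng=13)
        ll_k = pl.session_loglik(model, p, df, engine="kernel")
        ll_r = pl.session_loglik(model, p, df, engine="reference")
        assert ll_k == pytest.approx(ll_r, abs=1e-10)

    def test_generating_params_beat_perturbed(self, default_config):
        """On average the generating parameters out-score +-2 transformed-
        space perturbations of themselves on their own simulated data."""
        model = "punishment"
        p = oracle_param_vector()
        theta = transform_params(p, model)
        rng = np.random.default_rng(0)
        wins = 0
        n_sim = 40
        for i in range(n_sim):
            df = pl.simulate_agent_session(default_config, model, p, rng=rng,
                                           rt_settings=None)
            ll_true = pl.session_loglik(model, p, df)
            j = rng.integers(len(theta))
            pert = theta.copy()
            pert[j] += rng.choice([-2.0, 2.0])
            ll_pert = pl.session_loglik(
                model, inverse_transform_params(pert, model), df
            )
            wins += ll_true > ll_pert
        assert wins / n_sim > 0.8

    def test_unordered_trials_rejected(self):
        df = toy_frame().iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="ordered"):
            pl.session_loglik("punishment", oracle_param_vector(), df)

    def test_mixed_sessions_rejected(self):
        df = toy_frame()
        df.loc[3:, "session"] = "ABS2"
        with pytest.raises(ValueError, match="session"):
            pl.session_loglik("punishment", oracle_param_vector(), df)


def test_model_registry_parameter_counts():
    assert MODELS["action_only"].n_params == 4
    assert MODELS["punishment"].n_params == 5
    assert MODELS["stimulus_action"].n_params == 4
    assert MODELS["belief"].n_params == 5
    assert MODELS["counterfactual"].n_params == 4
    assert "beta_punishment" in MODELS["punishment"].free_params
    assert "zeta" in MODELS["belief"].free_params
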