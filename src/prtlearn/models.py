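"""Reinforcement-learning models of probabilistic-reward-task choice.

Five candidate models of trial-by-trial choice in the PRT, all sharing a
softmax decision rule over the two response options and a delta-rule update
driven by a sensitivity-scaled prediction error:

``action_only``
    Values are attached to actions alone, ``Q_t(a)``; the agent ignores which
    stimulus was shown.  PE = beta_reward * R_t - Q_t(a_t).
``stimulus_action``
    Values are attached to stimulus-action pairs, ``Q_t(a, s)``; only
    rewarded outcomes carry learning signal.
``punishment``
    As ``stimulus_action`` but trials without reward are treated as aversive:
    PE = beta_reward * R_t - beta_punishment * (1 - R_t) - Q_t(a_t, s_t)
    (the default "aversive" sign convention; a "literal" switch flips the
    sign of the punishment term).
``belief``
    As ``stimulus_action`` but the agent is uncertain which of the two
    near-identical stimuli was shown: the value entering the softmax is
    zeta * Q(a, s_shown) + (1 - zeta) * Q(a, s_other), and credit is
    assigned to the two stimulus entries with the same weights.
``counterfactual``
    As ``stimulus_action`` with an additional mirrored update: the
    unchosen action / unshown stimulus pair receives ``-alpha * PE``.

On every trial the softmax acts on action values
``V(a) = Q-term(a) + gamma * 1[a is the instructed response to s_t]
+ Q0 * 1[a is the rich-paired action]``, so ``gamma`` measures adherence to
the task instruction and ``Q0`` a constant bias toward the richly rewarded
response.  Parameters live on constrained natural scales and are mapped to
the real line for fitting: logit for ``alpha`` and ``zeta``, log for the
rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MODELS",
    "ModelSpec",
    "ParamVector",
    "LatentState",
    "init_state",
    "transform_params",
    "inverse_transform_params",
    "choice_values",
    "choice_probability",
    "prediction_error",
    "update_state",
    "session_loglik",
    "trials_to_arrays",
]

PARAM_ORDER = ("alpha", "beta_reward", "beta_punishment", "q0", "gamma", "zeta")

#: parameters mapped through logit (the rest are log-transformed)
_LOGIT_PARAMS = frozenset({"alpha", "zeta"})


@dataclass(frozen=True)
class ModelSpec:
    """A named model: its free parameters and its integer kernel id."""

    name: str
    free_params: tuple[str, ...]
    model_id: int

    @property
    def n_params(self) -> int:
        return len(self.free_params)


MODELS: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in (
        ModelSpec("action_only", ("alpha", "beta_reward", "q0", "gamma"), 0),
        ModelSpec("stimulus_action", ("alpha", "beta_reward", "q0", "gamma"), 1),
        ModelSpec(
            "punishment",
            ("alpha", "beta_reward", "beta_punishment", "q0", "gamma"),
            2,
        ),
        ModelSpec("belief", ("alpha", "beta_reward", "q0", "gamma", "zeta"), 3),
        ModelSpec("counterfactual", ("alpha", "beta_reward", "q0", "gamma"), 4),
    )
}


def get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; available: {sorted(MODELS)}"
        ) from None


@dataclass
class ParamVector:
    """Model parameters on their natural scales.

    ``beta_punishment`` defaults to 0 (no punishment term: the value fixed
    by every model except ``punishment``) and ``zeta`` to 1 (full trust in
    the shown stimulus: fixed by every model except ``belief``).
    """

    alpha: float = 0.2
    beta_reward: float = 1.0
    beta_punishment: float = 0.0
    q0: float = 0.0
    gamma: float = 0.0
    zeta: float = 1.0

    def validate(self, model: str | ModelSpec | None = None) -> None:
        """Raise ValueError if any parameter is outside its support.

        Boundary values (0 for the positive parameters, 1 for zeta) are
        allowed for forward evaluation; the log/logit transforms reject them.
        """
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("beta_reward", "beta_punishment", "q0", "gamma"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 < self.zeta <= 1.0:
            raise ValueError(f"zeta must be in (0, 1], got {self.zeta}")
        if model is not None:
            get_model(model)  # raises on unknown model names

    def as_array(self) -> np.ndarray:
        """Full natural-scale vector in canonical PARAM_ORDER."""
        return np.array([getattr(self, p) for p in PARAM_ORDER], dtype=float)


def _fwd(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name}={value} outside (0, 1); logit undefined")
        return math.log(value / (1.0 - value))
    if value <= 0.0:
        raise ValueError(f"{name}={value} not > 0; log undefined")
    return math.log(value)


def _inv(name: str, value: float) -> float:
    if name in _LOGIT_PARAMS:
        return 1.0 / (1.0 + math.exp(-value))
    return math.exp(value)


def transform_params(params: ParamVector, model: str | ModelSpec) -> np.ndarray:
    """Map natural parameters to the unconstrained fitting scale.

    Returns the transformed values of the model's free parameters, in the
    order given by ``MODELS[model].free_params``:
    log(alpha/(1-alpha)), log(beta_reward), log(beta_punishment), log(q0),
    log(gamma), log(zeta/(1-zeta)) as applicable.
    """
    spec = get_model(model)
    return np.array([_fwd(p, getattr(params, p)) for p in spec.free_params])


def inverse_transform_params(theta: np.ndarray, model: str | ModelSpec) -> ParamVector:
    """Inverse of :func:`transform_params`; fixed parameters take defaults."""
    spec = get_model(model)
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_params,):
        raise ValueError(
            f"expected {spec.n_params} transformed values for {spec.name}, "
            f"got shape {theta.shape}"
        )
    kwargs = {p: _inv(p, t) for p, t in zip(spec.free_params, theta)}
    return ParamVector(**kwargs)


@dataclass
class LatentState:
    """Q-values carried across trials within one session.

    ``q_action`` (shape (2,)) is used by the action-only model, indexed by
    action in rich-paired coordinates (0 = the action that is correct for
    the rich stimulus).  ``q_stim_action`` (shape (2, 2)) is used by the
    other models, indexed [action, stimulus] with 0 = rich, 1 = lean.
    """

    q_action: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q_stim_action: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))


def init_state(model: str | ModelSpec | None = None) -> LatentState:
    """Fresh all-zero state (initial preference is carried by Q0)."""
    return LatentState()


def choice_values(
    model: str | ModelSpec, params: ParamVector, state: LatentState, s: int
) -> np.ndarray:
    """Softmax input values V(a) for both actions given shown stimulus ``s``."""
    spec = get_model(model)
    if spec.name == "action_only":
        q = state.q_action.copy()
    elif spec.name == "belief":
        z = params.zeta
        q = z * state.q_stim_action[:, s] + (1.0 - z) * state.q_stim_action[:, 1 - s]
    else:
        q = state.q_stim_action[:, s].copy()
    v = q.astype(float)
    v[0] += params.q0  # constant bias toward the rich-paired action
    v[s] += params.gamma  # instructed (correct) response for this stimulus
    return v


def choice_probability(
    model: str | ModelSpec, params: ParamVector, state: LatentState, s: int
) -> np.ndarray:
    """Probability of each action under the two-option softmax."""
    v = choice_values(model, params, state, s)
    d = v[0] - v[1]
    p0 = 1.0 / (1.0 + math.exp(-d)) if d >= 0 else 1.0 - 1.0 / (1.0 + math.exp(d))
    return np.array([p0, 1.0 - p0])


def prediction_error(
    model: str | ModelSpec,
    params: ParamVector,
    r: int,
    state: LatentState,
    a: int,
    s: int,
    punishment_sign: str = "aversive",
) -> float:
    """Sensitivity-scaled prediction error for the experienced outcome.

    ``punishment_sign`` selects how the no-reward term enters for the
    punishment model: "aversive" (default) subtracts beta_punishment*(1-R),
    "literal" adds it.
    """
    spec = get_model(model)
    if punishment_sign not in ("aversive", "literal"):
        raise ValueError(f"unknown punishment_sign {punishment_sign!r}")
    sgn = -1.0 if punishment_sign == "aversive" else 1.0
    outcome = params.beta_reward * r
    if spec.name == "punishment":
        outcome += sgn * params.beta_punishment * (1 - r)
    if spec.name == "action_only":
        expected = state.q_action[a]
    elif spec.name == "belief":
        z = params.zeta
        expected = (
            z * state.q_stim_action[a, s] + (1.0 - z) * state.q_stim_action[a, 1 - s]
        )
    else:
        expected = state.q_stim_action[a, s]
    return outcome - expected


def update_state(
    state: LatentState,
    pe: float,
    alpha: float,
    a: int,
    s: int,
    model: str | ModelSpec,
    zeta: float = 1.0,
) -> LatentState:
    """Delta-rule update in place; returns the state for convenience."""
    spec = get_model(model)
    if spec.name == "action_only":
        state.q_action[a] += alpha * pe
    elif spec.name == "belief":
        state.q_stim_action[a, s] += alpha * zeta * pe
        state.q_stim_action[a, 1 - s] += alpha * (1.0 - zeta) * pe
    else:
        state.q_stim_action[a, s] += alpha * pe
        if spec.name == "counterfactual":
            state.q_stim_action[1 - a, 1 - s] -= alpha * pe
    return state


def trials_to_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode a single-session trial table for the likelihood.

    Returns ``(stim, action, reward)`` int8 arrays in rich-paired
    coordinates: stimulus 0 = rich, 1 = lean; action 0 = the response that
    is correct for the rich stimulus.  The action coordinate is derived
    from stimulus and correctness, so it is independent of the subject's
    (randomised) mouth-length mapping.
    """
    required = {"stimulus", "correct", "reward"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if len(trials) == 0:
        raise ValueError("empty trial table")
    for key in ("subject_id", "session"):
        if key in trials.columns and trials[key].nunique() > 1:
            raise ValueError(f"trials span multiple values of {key!r}")
    if "trial" in trials.columns:
        t = np.asarray(trials["trial"])
        if not np.all(np.diff(t) > 0):
            raise ValueError("trials must be ordered by increasing trial index")
    stim = np.where(np.asarray(trials["stimulus"]) == "rich", 0, 1).astype(np.int8)
    correct = np.asarray(trials["correct"]).astype(bool)
    action = np.where(correct, stim, 1 - stim).astype(np.int8)
    reward = np.asarray(trials["reward"]).astype(np.int8)
    return stim, action, reward


def _loglik_reference(
    model: ModelSpec,
    params: ParamVector,
    stim: np.ndarray,
    action: np.ndarray,
    reward: np.ndarray,
    punishment_sign: str,
) -> float:
    state = init_state(model)
    ll = 0.0
    for s, a, r in zip(stim, action, reward):
        p = choice_probability(model, params, state, int(s))
        ll += math.log(p[int(a)])
        pe = prediction_error(
            model, params, int(r), state, int(a), int(s), punishment_sign
        )
        update_state(state, pe, params.alpha, int(a), int(s), model, params.zeta)
    return ll


def session_loglik(
    model: str | ModelSpec,
    params: ParamVector,
    trials: pd.DataFrame,
    punishment_sign: str = "aversive",
    engine: str = "kernel",
) -> float:
    """Log-likelihood of one session's choices under a model.

    The state is initialised afresh at the session start and persists
    across blocks.  ``engine="kernel"`` uses the compiled recursion;
    ``engine="reference"`` composes the per-trial operations in Python
    (same result, used for cross-checking).
    """
    spec = get_model(model)
    params.validate()
    stim, action, reward = trials_to_arrays(trials)
    if engine == "reference":
        return _loglik_reference(spec, params, stim, action, reward, punishment_sign)
    if engine != "kernel":
        raise ValueError(f"unknown engine {engine!r}")
    from . import kernels

    sgn = -1.0 if punishment_sign == "aversive" else 1.0
    return kernels.session_loglik_kernel(
        spec.model_id,
        params.alpha,
        params.beta_reward,
        params.beta_punishment,
        params.q0,
        params.gamma,
        params.zeta,
        sgn,
        stim,
        action,
        reward,
    )
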