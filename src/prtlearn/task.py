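"""Probabilistic reward task: schedules and simulated agents.

The PRT is a two-alternative discrimination: on each trial a face with a
short (11.5 mm) or long (13 mm) mouth appears for 100 ms and the subject
reports the mouth length.  Sessions run 3 blocks of 100 trials, half of
each block per stimulus.  Correct responses are rewarded ("Correct!! You
won 20pts") on a controlled asymmetric schedule: per block 30 rewards are
planned for correct responses to one stimulus (the *rich* stimulus) and 10
for the other (the *lean* stimulus), a 3:1 asymmetry delivering rewards on
40% of trials when responding is perfect.  Subjects are never told about
the asymmetry.  Which mouth length is rich is randomised per subject.

This module generates stimulus sequences and reward schedules, simulates
choice (and optional reaction-time) data from the RL agents defined in
:mod:`prtlearn.models`, and builds longitudinal synthetic cohorts that
stand in for the smoking-cessation study design: sessions S0 (smoking as
usual), ABS2 (48 h abstinent) and ABS30 (30 days abstinent), with optional
session shifts of the generating parameters in transformed space (e.g. a
raised log punishment sensitivity at ABS30).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import models as _models
from .models import ParamVector, get_model, inverse_transform_params

__all__ = [
    "TaskConfig",
    "RTSettings",
    "CohortSpec",
    "Cohort",
    "DEFAULT_PARAM_MEAN",
    "DEFAULT_PARAM_SD",
    "generate_stimulus_sequence",
    "build_reward_schedule",
    "RewardDeliverer",
    "simulate_agent_session",
    "sample_reaction_time",
    "generate_cohort",
]

SESSIONS = ("S0", "ABS2", "ABS30")

TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "block",
    "trial",
    "stimulus",
    "action",
    "correct",
    "reward",
    "points",
    "rt",
]


class ConfigError(ValueError):
    """A task configuration violates one of its invariants."""


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class TaskConfig:
    """Schedule constants of one PRT session.

    Mouth sizes and presentation duration are carried as metadata only; no
    perceptual process is simulated beyond the models' gamma/zeta terms.
    """

    n_blocks: int = 3
    trials_per_block: int = 100
    rich_rewards_per_block: int = 30
    lean_rewards_per_block: int = 10
    points_per_reward: int = 20
    rich_stimulus: str = "short"
    schedule: str = "carryover"  # or "bernoulli"
    seed: int | None = None
    stimulus_duration_ms: float = 100.0
    mouth_lengths_mm: tuple[float, float] = (11.5, 13.0)

    @property
    def trials_per_stimulus(self) -> int:
        return self.trials_per_block // 2

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def asymmetry_ratio(self) -> float:
        return self.rich_rewards_per_block / self.lean_rewards_per_block

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.trials_per_block < 2 or self.trials_per_block % 2:
            raise ConfigError(
                "trials_per_block must be even (equal rich/lean split), got "
                f"{self.trials_per_block}"
            )
        if self.lean_rewards_per_block < 1 or self.rich_rewards_per_block < 1:
            raise ConfigError("reward counts per block must be >= 1")
        for name, n in (
            ("rich_rewards_per_block", self.rich_rewards_per_block),
            ("lean_rewards_per_block", self.lean_rewards_per_block),
        ):
            if n > self.trials_per_stimulus:
                raise ConfigError(
                    f"{name}={n} exceeds {self.trials_per_stimulus} trials of "
                    "that stimulus per block"
                )
        if self.rich_rewards_per_block % self.lean_rewards_per_block:
            raise ConfigError(
                "rich_rewards_per_block must be an integer multiple of "
                "lean_rewards_per_block (asymmetry ratio)"
            )
        if self.rich_stimulus not in ("short", "long"):
            raise ConfigError("rich_stimulus must be 'short' or 'long'")
        if self.schedule not in ("carryover", "bernoulli"):
            raise ConfigError("schedule must be 'carryover' or 'bernoulli'")
        if self.points_per_reward <= 0:
            raise ConfigError("points_per_reward must be > 0")

    @property
    def action_labels(self) -> tuple[str, str]:
        """Mouth-length labels in rich-paired coordinates (index 0 = rich)."""
        other = "long" if self.rich_stimulus == "short" else "short"
        return (self.rich_stimulus, other)


def generate_stimulus_sequence(
    config: TaskConfig, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Random stimulus order: per block, exactly half rich (0), half lean (1)."""
    config.validate()
    rng = _as_rng(config.seed if rng is None else rng)
    half = config.trials_per_stimulus
    blocks = []
    for _ in range(config.n_blocks):
        block = np.array([0] * half + [1] * half, dtype=np.int8)
        rng.shuffle(block)
        blocks.append(block)
    return np.concatenate(blocks)


def build_reward_schedule(
    sequence: np.ndarray,
    config: TaskConfig,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-trial planned-reward flags.

    Under the default controlled ("carryover") schedule, exactly
    ``rich_rewards_per_block`` rich-trial and ``lean_rewards_per_block``
    lean-trial positions per block are marked planned; delivery (and the
    carry-forward of rewards missed through errors) is handled by
    :class:`RewardDeliverer`.  Under the "bernoulli" alternative each trial
    is independently planned with the matching marginal probability.
    """
    config.validate()
    sequence = np.asarray(sequence, dtype=np.int8)
    if sequence.shape != (config.n_trials,):
        raise ConfigError(
            f"sequence length {sequence.shape} does not match config "
            f"({config.n_trials} trials)"
        )
    rng = _as_rng(config.seed if rng is None else rng)
    planned = np.zeros(config.n_trials, dtype=np.int8)
    tpb = config.trials_per_block
    if config.schedule == "bernoulli":
        p_rich = config.rich_rewards_per_block / config.trials_per_stimulus
        p_lean = config.lean_rewards_per_block / config.trials_per_stimulus
        p = np.where(sequence == 0, p_rich, p_lean)
        planned = (rng.random(config.n_trials) < p).astype(np.int8)
        return planned
    for b in range(config.n_blocks):
        sl = slice(b * tpb, (b + 1) * tpb)
        block_seq = sequence[sl]
        for stim, n_rewards in (
            (0, config.rich_rewards_per_block),
            (1, config.lean_rewards_per_block),
        ):
            positions = np.flatnonzero(block_seq == stim)
            chosen = rng.choice(positions, size=n_rewards, replace=False)
            planned[sl][chosen] = 1
    return planned


class RewardDeliverer:
    """Trial-by-trial reward delivery with the carry-forward rule.

    A planned reward is delivered only if the response is correct; under the
    controlled schedule a reward missed through an error is carried to the
    next correct same-stimulus trial of the block and dropped at block end.
    """

    def __init__(self, config: TaskConfig):
        self.config = config
        self._pending = [0, 0]
        self._trial_in_block = 0

    def deliver(self, stimulus: int, correct: bool, planned: bool) -> int:
        if self._trial_in_block == self.config.trials_per_block:
            self._pending = [0, 0]  # undelivered rewards die with the block
            self._trial_in_block = 0
        self._trial_in_block += 1
        carryover = self.config.schedule == "carryover"
        if planned:
            if correct:
                return 1
            if carryover:
                self._pending[stimulus] += 1
            return 0
        if carryover and correct and self._pending[stimulus] > 0:
            self._pending[stimulus] -= 1
            return 1
        return 0


@dataclass(frozen=True)
class RTSettings:
    """Lognormal reaction-time generator: descriptive only, never fitted.

    ``error_effect`` is the additive shift of the log-median for error
    trials; a positive value makes errors slower than correct responses.
    """

    median_ms: float = 450.0
    sigma: float = 0.25
    error_effect: float = 0.15


def sample_reaction_time(
    correct: bool,
    settings: RTSettings = RTSettings(),
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw lognormal RTs; errors are slower when ``error_effect`` > 0."""
    rng = _as_rng(rng)
    mu = np.log(settings.median_ms) + (0.0 if correct else settings.error_effect)
    return rng.lognormal(mean=mu, sigma=settings.sigma, size=size)


def simulate_agent_session(
    config: TaskConfig,
    model: str,
    params: ParamVector,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sim",
    session: str = "S0",
    rt_settings: RTSettings | None = RTSettings(),
    punishment_sign: str = "aversive",
) -> pd.DataFrame:
    """Simulate one session of PRT choices from an RL agent.

    Choices are sampled from the model's softmax probabilities; values are
    updated with the model's own prediction-error rule, so simulated data
    are exchangeable with the likelihood in :mod:`prtlearn.models`.
    """
    spec = get_model(model)
    params.validate(spec)
    config.validate()
    rng = _as_rng(config.seed if rng is None else rng)
    sequence = generate_stimulus_sequence(config, rng)
    planned = build_reward_schedule(sequence, config, rng)
    deliverer = RewardDeliverer(config)
    state = _models.init_state(spec)
    labels = config.action_labels
    rows = []
    for t, s in enumerate(sequence):
        s = int(s)
        p = _models.choice_probability(spec, params, state, s)
        a = 0 if rng.random() < p[0] else 1
        correct = a == s
        r = deliverer.deliver(s, correct, bool(planned[t]))
        pe = _models.prediction_error(
            spec, params, r, state, a, s, punishment_sign=punishment_sign
        )
        _models.update_state(state, pe, params.alpha, a, s, spec, params.zeta)
        rt = (
            float(sample_reaction_time(correct, rt_settings, rng))
            if rt_settings is not None
            else np.nan
        )
        rows.append(
            (
                subject_id,
                session,
                t // config.trials_per_block + 1,
                t + 1,
                "rich" if s == 0 else "lean",
                labels[a],
                bool(correct),
                int(r),
                int(r) * config.points_per_reward,
                rt,
            )
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# Transformed-space generating distribution defaults.  Chosen for realistic
# PRT phenomenology (overall accuracy around 0.8, positive response bias,
# modest learning rates); see docs/methods.md.
DEFAULT_PARAM_MEAN: dict[str, float] = {
    "alpha": -1.0,  # logit: alpha ~ 0.27
    "beta_reward": 0.5,  # log: ~ 1.65
    "beta_punishment": 0.0,  # log: ~ 1.0
    "q0": -1.5,  # log: ~ 0.22
    "gamma": 0.5,  # log: ~ 1.65
    "zeta": 1.0,  # logit: ~ 0.73
}
DEFAULT_PARAM_SD: dict[str, float] = {p: 0.7 for p in DEFAULT_PARAM_MEAN}


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic longitudinal cohort of RL agents.

    Parameters are drawn per subject in transformed space from independent
    Gaussians, then shifted per session by ``session_effects`` (e.g.
    ``{"ABS30": {"beta_punishment": 0.5}}`` raises log punishment
    sensitivity at the 30-day-abstinence session).
    """

    n_subjects: int = 19
    sessions: tuple[str, ...] = SESSIONS
    generating_model: str = "punishment"
    param_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_MEAN)
    )
    param_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_SD)
    )
    session_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not self.sessions:
            raise ConfigError("at least one session label required")
        spec = get_model(self.generating_model)
        for p in spec.free_params:
            if p not in self.param_mean:
                raise ConfigError(f"param_mean missing {p!r}")
            if self.param_sd.get(p, -1.0) < 0.0:
                raise ConfigError(f"param_sd[{p!r}] must be >= 0")
        for sess, effects in self.session_effects.items():
            if sess not in self.sessions:
                raise ConfigError(
                    f"session_effects refers to unknown session {sess!r}"
                )
            unknown = set(effects) - set(spec.free_params)
            if unknown:
                raise ConfigError(
                    f"session_effects for {sess!r} name non-free params "
                    f"{sorted(unknown)}"
                )


@dataclass
class Cohort:
    """Simulated trial data plus ground truth for recovery experiments."""

    trials: pd.DataFrame
    truth: pd.DataFrame  # subject_id, session, model, param, transformed, natural
    rich_stimulus: dict[str, str]  # per-subject mouth-length mapping


def generate_cohort(spec: CohortSpec, config: TaskConfig = TaskConfig()) -> Cohort:
    """Simulate a full cohort: one session per subject per session label."""
    spec.validate()
    config.validate()
    model = get_model(spec.generating_model)
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    trial_frames = []
    truth_rows = []
    mappings: dict[str, str] = {}
    width = max(3, len(str(spec.n_subjects)))
    for i, seed_seq in enumerate(subject_seeds):
        rng = np.random.default_rng(seed_seq)
        subject = f"sub{i + 1:0{width}d}"
        mapping = "short" if rng.random() < 0.5 else "long"
        mappings[subject] = mapping
        sub_config = replace(config, rich_stimulus=mapping, seed=None)
        base = np.array(
            [
                rng.normal(spec.param_mean[p], spec.param_sd[p])
                for p in model.free_params
            ]
        )
        for session in spec.sessions:
            shifts = spec.session_effects.get(session, {})
            theta = base + np.array(
                [shifts.get(p, 0.0) for p in model.free_params]
            )
            params = inverse_transform_params(theta, model)
            trials = simulate_agent_session(
                sub_config,
                model.name,
                params,
                rng=rng,
                subject_id=subject,
                session=session,
            )
            trial_frames.append(trials)
            for p, tv in zip(model.free_params, theta):
                truth_rows.append(
                    (subject, session, model.name, p, tv, getattr(params, p))
                )
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "subject_id",
            "session",
            "model",
            "param",
            "transformed_value",
            "natural_value",
        ],
    )
    return Cohort(trials=trials, truth=truth, rich_stimulus=mappings)
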