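import numpy as np
import pandas as pd
import pytest

from prtlearn import ParamVector, TaskConfig, simulate_agent_session


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def tiny_config() -> TaskConfig:
    """One 20-trial block with the same 3:1, 40% reward structure."""
    return TaskConfig(
        n_blocks=1, trials_per_block=20, rich_rewards_per_block=6,
        lean_rewards_per_block=2,
    )


@pytest.fixture(scope="session")
def punishment_params() -> ParamVector:
    return ParamVector(
        alpha=0.27, beta_reward=1.65, beta_punishment=1.0, q0=0.22, gamma=1.0
    )


@pytest.fixture(scope="session")
def sim_session(default_config, punishment_params) -> pd.DataFrame:
    return simulate_agent_session(
        default_config, "punishment", punishment_params, rng=7,
        subject_id="s1", session="S0",
    )


def make_trials(stimuli, corrects, rewards, rts=None, subject="s1", session="S0"):
    """Hand-built single-session trial table in the canonical schema."""
    n = len(stimuli)
    rewards = list(rewards)
    return pd.DataFrame(
        {
            "subject_id": [subject] * n,
            "session": [session] * n,
            "block": [1] * n,
            "trial": list(range(1, n + 1)),
            "stimulus": list(stimuli),
            "action": [
                ("short" if s == "rich" else "long")
                if c
                else ("long" if s == "rich" else "short")
                for s, c in zip(stimuli, corrects)
            ],
            "correct": [bool(c) for c in corrects],
            "reward": rewards,
            "points": [20 * r for r in rewards],
            "rt": list(rts) if rts is not None else [np.nan] * n,
        }
    )
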