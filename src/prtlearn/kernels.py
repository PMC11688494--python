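"""Compiled likelihood recursions used by the fitting routines.

The per-trial operations in :mod:`prtlearn.models` define the models; the
kernels here re-implement the same recursion as numba-compiled loops so that
hierarchical fitting (which evaluates the session likelihood tens of
thousands of times) stays fast.  ``tests`` assert exact agreement between
the two paths.

Model ids: 0 action_only, 1 stimulus_action, 2 punishment, 3 belief,
4 counterfactual.  Arrays are int8 in rich-paired coordinates (see
:func:`prtlearn.models.trials_to_arrays`).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["session_loglik_kernel", "loglik_batch"]


@njit(cache=True)
def _softplus(x):
    # log(1 + exp(x)), overflow-safe
    if x > 35.0:
        return x
    return np.log1p(np.exp(x))


@njit(cache=True)
def session_loglik_kernel(
    model_id, alpha, beta_r, beta_p, q0, gamma, zeta, psign, stim, action, reward
):
    n = stim.shape[0]
    qa = np.zeros(2)
    qs = np.zeros((2, 2))  # [action, stimulus]
    ll = 0.0
    for t in range(n):
        s = stim[t]
        a = action[t]
        r = reward[t]
        if model_id == 0:
            v0 = qa[0]
            v1 = qa[1]
        elif model_id == 3:
            v0 = zeta * qs[0, s] + (1.0 - zeta) * qs[0, 1 - s]
            v1 = zeta * qs[1, s] + (1.0 - zeta) * qs[1, 1 - s]
        else:
            v0 = qs[0, s]
            v1 = qs[1, s]
        v0 += q0
        if s == 0:
            v0 += gamma
        else:
            v1 += gamma
        d = v0 - v1
        if a == 0:
            ll -= _softplus(-d)
        else:
            ll -= _softplus(d)
        outcome = beta_r * r
        if model_id == 2:
            outcome += psign * beta_p * (1.0 - r)
        if model_id == 0:
            pe = outcome - qa[a]
            qa[a] += alpha * pe
        elif model_id == 3:
            expected = zeta * qs[a, s] + (1.0 - zeta) * qs[a, 1 - s]
            pe = outcome - expected
            qs[a, s] += alpha * zeta * pe
            qs[a, 1 - s] += alpha * (1.0 - zeta) * pe
        else:
            pe = outcome - qs[a, s]
            qs[a, s] += alpha * pe
            if model_id == 4:
                qs[1 - a, 1 - s] -= alpha * pe
    return ll


@njit(cache=True)
def loglik_batch(model_id, naturals, psign, stim, action, reward):
    """Session log-likelihood for K natural-parameter vectors.

    ``naturals`` has shape (K, 6) in the canonical order
    (alpha, beta_reward, beta_punishment, q0, gamma, zeta).
    """
    k = naturals.shape[0]
    out = np.empty(k)
    for i in range(k):
        out[i] = session_loglik_kernel(
            model_id,
            naturals[i, 0],
            naturals[i, 1],
            naturals[i, 2],
            naturals[i, 3],
            naturals[i, 4],
            naturals[i, 5],
            psign,
            stim,
            action,
            reward,
        )
    return out
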