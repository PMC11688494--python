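"""Hierarchical empirical-Bayes estimation of RL model parameters.

Each subject-session is one hierarchical unit.  Transformed parameters
theta_i get an independent-Gaussian group prior N(mu, diag(sigma^2));
fitting alternates

- E-step: per unit, a MAP estimate of theta_i (quasi-Newton on the
  penalised log-likelihood in transformed space, multi-start) with a
  Laplace (inverse-Hessian) posterior covariance, and
- M-step: re-estimation of mu and sigma^2 from the posterior moments,

until the prior stops moving.  Subject-level marginal likelihoods
p(data_i | prior) are estimated by Monte-Carlo draws from the fitted prior
(with the Laplace value as a cross-check); these feed the integrated-BIC
model comparison in :mod:`prtlearn.selection`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from . import kernels
from .models import PARAM_ORDER, ModelSpec, get_model, trials_to_arrays

__all__ = [
    "GroupPrior",
    "FitResult",
    "EMResult",
    "EvidenceResult",
    "map_fit_subject",
    "em_group_fit",
    "m_step",
    "subject_evidence",
]

logger = logging.getLogger(__name__)

_LOGIT = ("alpha", "zeta")
_FIXED_NATURAL = {"beta_punishment": 0.0, "zeta": 1.0}

#: spec defaults for the EM initial prior: diffuse, centred at zero
DEFAULT_PRIOR_MEAN = 0.0
DEFAULT_PRIOR_VAR = 3.0
VAR_FLOOR = 1e-6


@dataclass
class GroupPrior:
    """Independent Gaussian prior over a model's transformed parameters."""

    model: str
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        spec = get_model(self.model)
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if self.mean.shape != (spec.n_params,) or self.var.shape != (spec.n_params,):
            raise ValueError(
                f"prior for {spec.name} needs {spec.n_params} means/variances"
            )
        if not np.all(self.var > 0):
            raise ValueError("prior variances must be > 0")

    @classmethod
    def default(cls, model: str | ModelSpec) -> "GroupPrior":
        spec = get_model(model)
        k = spec.n_params
        return cls(spec.name, np.full(k, DEFAULT_PRIOR_MEAN), np.full(k, DEFAULT_PRIOR_VAR))

    @property
    def param_names(self) -> tuple[str, ...]:
        return get_model(self.model).free_params

    @property
    def n_hyperparams(self) -> int:
        """Group-level parameters penalised by iBIC (a mean and a variance each)."""
        return 2 * len(self.mean)

    def logpdf(self, theta: np.ndarray) -> float | np.ndarray:
        """Log density at one point (k,) or a batch (m, k)."""
        theta = np.asarray(theta, dtype=float)
        d = theta - self.mean
        out = -0.5 * np.sum(
            d * d / self.var + np.log(2.0 * math.pi * self.var), axis=-1
        )
        return float(out) if theta.ndim == 1 else out

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.var), size=(size, len(self.mean)))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "param_names": list(self.param_names),
            "mean": self.mean.tolist(),
            "var": self.var.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupPrior":
        return cls(d["model"], np.array(d["mean"]), np.array(d["var"]))


@dataclass
class FitResult:
    subject_id: str
    session: str
    model: str
    mode: np.ndarray  # transformed-space posterior mode
    cov: np.ndarray  # Laplace posterior covariance
    log_posterior: float  # loglik + logprior at the mode
    laplace_evidence: float  # Laplace estimate of log p(data | prior)
    n_trials: int
    converged: bool
    n_iterations: int
    grad_norm: float
    n_restarts: int

    @property
    def param_names(self) -> tuple[str, ...]:
        return get_model(self.model).free_params


@dataclass
class EvidenceResult:
    log_ml: float
    se: float
    n_draws: int


@dataclass
class EMResult:
    prior: GroupPrior
    fits: list[FitResult]
    history: pd.DataFrame  # iteration, approx_ml, max_delta

    def params_table(self) -> pd.DataFrame:
        """Long-format recovered-parameter table (one row per unit x param)."""
        rows = []
        for fit in self.fits:
            names = fit.param_names
            for j, p in enumerate(names):
                t = fit.mode[j]
                natural = expit(t) if p in _LOGIT else math.exp(t)
                rows.append(
                    (fit.subject_id, fit.session, fit.model, p, t, natural)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "subject_id",
                "session",
                "model",
                "param",
                "transformed_value",
                "natural_value",
            ],
        )


def m_step(
    modes: np.ndarray, covs: np.ndarray, var_floor: float = VAR_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Prior re-estimation from unit posterior moments.

    ``modes`` has shape (n_units, k); ``covs`` (n_units, k, k) or
    (n_units, k) for diagonal covariances.  Returns (mean, var) of the
    moment-matched Gaussian prior: mean of the posterior means, and the
    mean posterior second moment minus the squared new mean.
    """
    modes = np.asarray(modes, dtype=float)
    covs = np.asarray(covs, dtype=float)
    diag = covs if covs.ndim == 2 else np.diagonal(covs, axis1=1, axis2=2)
    mean = modes.mean(axis=0)
    var = (modes**2 + diag).mean(axis=0) - mean**2
    return mean, np.maximum(var, var_floor)


class _SessionObjective:
    """Negative penalised log-likelihood of one unit in transformed space."""

    def __init__(self, spec: ModelSpec, trials: pd.DataFrame, punishment_sign: str):
        self.spec = spec
        self.stim, self.action, self.reward = trials_to_arrays(trials)
        self.psign = -1.0 if punishment_sign == "aversive" else 1.0
        self.free_idx = [PARAM_ORDER.index(p) for p in spec.free_params]
        self.is_logit = np.array([p in _LOGIT for p in spec.free_params])
        self.base_natural = np.array(
            [
                _FIXED_NATURAL.get(p, 0.0) if p not in spec.free_params else np.nan
                for p in PARAM_ORDER
            ]
        )
        self.prior: GroupPrior | None = None

    def _naturals(self, thetas: np.ndarray) -> np.ndarray:
        """(m, k) transformed points -> (m, 6) natural parameter rows."""
        nat = np.tile(self.base_natural, (thetas.shape[0], 1))
        vals = np.where(self.is_logit, expit(thetas), np.exp(thetas))
        nat[:, self.free_idx] = vals
        return nat

    def _values(self, thetas: np.ndarray) -> np.ndarray:
        """Objective at a batch of points, via one compiled-kernel call."""
        lls = kernels.loglik_batch(
            self.spec.model_id,
            self._naturals(thetas),
            self.psign,
            self.stim,
            self.action,
            self.reward,
        )
        f = -(lls + self.prior.logpdf(thetas))
        return np.where(np.isfinite(f), f, 1e10)

    def value(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.abs(theta) < 50.0):
            # keep the optimiser away from exp() overflow; gradient points back
            return 1e10 + float(np.sum(theta * theta))
        return float(self._values(theta[None, :])[0])

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        k = theta.shape[0]
        if not np.all(np.abs(theta) < 50.0):
            return 1e10 + float(np.sum(theta * theta)), 2.0 * theta
        h = 1e-5 * (1.0 + np.abs(theta))
        points = np.vstack([theta, theta + np.diag(h), theta - np.diag(h)])
        f = self._values(points)
        g = (f[1 : k + 1] - f[k + 1 :]) / (2.0 * h)
        return float(f[0]), g

    def hessian(self, x: np.ndarray) -> np.ndarray:
        k = x.shape[0]
        h = 1e-4 * (1.0 + np.abs(x))
        points = [x]
        for i in range(k):
            for sign in (1.0, -1.0):
                xp = x.copy()
                xp[i] += sign * h[i]
                points.append(xp)
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        for i, j in pairs:
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                xp = x.copy()
                xp[i] += si * h[i]
                xp[j] += sj * h[j]
                points.append(xp)
        f = self._values(np.array(points))
        f0 = f[0]
        hess = np.empty((k, k))
        for i in range(k):
            fp, fm = f[1 + 2 * i], f[2 + 2 * i]
            hess[i, i] = (fp - 2.0 * f0 + fm) / h[i] ** 2
        base = 1 + 2 * k
        for idx, (i, j) in enumerate(pairs):
            fpp, fpm, fmp, fmm = f[base + 4 * idx : base + 4 * idx + 4]
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
        return hess


def _laplace_cov(hess: np.ndarray) -> tuple[np.ndarray, float]:
    """SPD-projected inverse Hessian and log|cov| (eigenvalue floor 1e-8)."""
    hess = 0.5 * (hess + hess.T)
    eigval, eigvec = np.linalg.eigh(hess)
    eigval = np.clip(eigval, 1e-8, None)
    cov = (eigvec / eigval) @ eigvec.T
    logdet_cov = float(-np.sum(np.log(eigval)))
    return cov, logdet_cov


def map_fit_subject(
    trials: pd.DataFrame,
    model: str | ModelSpec,
    prior: GroupPrior,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = 0,
    x0: np.ndarray | None = None,
    maxiter: int = 300,
    punishment_sign: str = "aversive",
    _objective: _SessionObjective | None = None,
) -> FitResult:
    """MAP + Laplace fit of one subject-session.

    Starts from the prior mean, ``x0`` if given, and ``n_restarts - 1``
    draws from the prior; the best optimum is kept.  Non-convergence of
    every start is flagged on the result, never silent.
    """
    spec = get_model(model)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    obj = _objective or _SessionObjective(spec, trials, punishment_sign)
    obj.prior = prior
    starts = [prior.mean.copy()]
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    while len(starts) < max(1, n_restarts):
        starts.append(prior.sample(rng, 1)[0])
    best = None
    any_converged = False
    for start in starts:
        res = minimize(
            obj.value_and_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    cov, logdet_cov = _laplace_cov(obj.hessian(best.x))
    k = spec.n_params
    log_post = -float(best.fun)
    laplace_ev = log_post + 0.5 * k * math.log(2.0 * math.pi) + 0.5 * logdet_cov
    subject = str(trials["subject_id"].iloc[0]) if "subject_id" in trials else "?"
    session = str(trials["session"].iloc[0]) if "session" in trials else "?"
    return FitResult(
        subject_id=subject,
        session=session,
        model=spec.name,
        mode=best.x.copy(),
        cov=cov,
        log_posterior=log_post,
        laplace_evidence=laplace_ev,
        n_trials=len(obj.stim),
        converged=any_converged,
        n_iterations=int(best.nit),
        grad_norm=float(np.linalg.norm(best.jac)),
        n_restarts=len(starts),
    )


def em_group_fit(
    trials: pd.DataFrame,
    model: str | ModelSpec,
    init_prior: GroupPrior | None = None,
    tol: float = 1e-3,
    max_iter: int = 80,
    n_restarts: int = 3,
    seed: int | np.random.Generator | None = 0,
    punishment_sign: str = "aversive",
    var_floor: float = VAR_FLOOR,
    strict_monotone: bool = False,
    damping: float = 0.5,
    ml_tol: float = 0.02,
) -> EMResult:
    """Empirical-Bayes EM over all subject-sessions in ``trials``.

    After the first iteration each unit is warm-started from its previous
    mode (plus a prior-mean start), which keeps the E-step cheap without
    changing the fixed point.  The M-step is damped (``prior <-
    (1-damping)*prior + damping*estimate``) to suppress mode-flip
    oscillations on ridged likelihoods; the fixed point is unchanged.
    Iteration stops when the prior moves less than ``tol`` or when the
    approximate marginal likelihood (sum of Laplace evidences) has been
    stable within ``ml_tol`` for three iterations.  A decrease of the
    approximate marginal likelihood beyond tolerance is logged as a
    warning, or raises when ``strict_monotone``.
    """
    spec = get_model(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    units = [
        (key, grp.reset_index(drop=True))
        for key, grp in trials.groupby(["subject_id", "session"], sort=True)
    ]
    if len(units) < 2:
        raise ValueError("hierarchical fitting needs at least 2 subject-sessions")
    objectives = [
        _SessionObjective(spec, grp, punishment_sign) for _, grp in units
    ]
    prior = init_prior or GroupPrior.default(spec)
    fits: list[FitResult] = []
    history = []
    ml_trace: list[float] = []
    for iteration in range(1, max_iter + 1):
        new_fits = []
        for idx, (_, grp) in enumerate(units):
            x0 = fits[idx].mode if fits else None
            restarts = 1 if fits else n_restarts
            new_fits.append(
                map_fit_subject(
                    grp,
                    spec,
                    prior,
                    n_restarts=restarts,
                    rng=rng,
                    x0=x0,
                    punishment_sign=punishment_sign,
                    _objective=objectives[idx],
                )
            )
        fits = new_fits
        modes = np.array([f.mode for f in fits])
        covs = np.array([f.cov for f in fits])
        mean_est, var_est = m_step(modes, covs, var_floor)
        if np.any(var_est <= var_floor):
            warnings.warn(
                f"prior variance floored at {var_floor} for "
                f"{[n for n, v in zip(spec.free_params, var_est) if v <= var_floor]}"
            )
        d = damping if iteration > 1 else 1.0
        mean = (1.0 - d) * prior.mean + d * mean_est
        var = (1.0 - d) * prior.var + d * var_est
        approx_ml = float(sum(f.laplace_evidence for f in fits))
        max_delta = float(
            max(np.max(np.abs(mean - prior.mean)), np.max(np.abs(var - prior.var)))
        )
        history.append((iteration, approx_ml, max_delta))
        logger.info(
            "EM iter %d: approx_ml=%.3f max_delta=%.2e", iteration, approx_ml, max_delta
        )
        if ml_trace and approx_ml < ml_trace[-1] - 0.5:
            msg = (
                f"approximate marginal likelihood decreased at iteration "
                f"{iteration} ({ml_trace[-1]:.3f} -> {approx_ml:.3f})"
            )
            if strict_monotone:
                raise RuntimeError(msg)
            logger.warning(msg)
        ml_trace.append(approx_ml)
        prior = GroupPrior(spec.name, mean, var)
        if max_delta < tol:
            break
        if len(ml_trace) >= 4 and max(
            abs(ml_trace[-1] - ml_trace[-1 - j]) for j in (1, 2, 3)
        ) < ml_tol:
            break
    return EMResult(
        prior=prior,
        fits=fits,
        history=pd.DataFrame(history, columns=["iteration", "approx_ml", "max_delta"]),
    )


def subject_evidence(
    model: str | ModelSpec,
    prior: GroupPrior,
    trials: pd.DataFrame,
    n_draws: int = 2000,
    rng: np.random.Generator | int | None = 0,
    punishment_sign: str = "aversive",
) -> EvidenceResult:
    """Monte-Carlo log marginal likelihood of one unit under the prior.

    log(1/K sum_k p(data | theta_k)), theta_k ~ prior.  The reported
    standard error is the delta-method error of the log of the mean.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100 for a usable evidence estimate")
    spec = get_model(model)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    stim, action, reward = trials_to_arrays(trials)
    thetas = prior.sample(rng, n_draws)
    naturals = np.empty((n_draws, len(PARAM_ORDER)))
    for j, p in enumerate(PARAM_ORDER):
        if p in prior.param_names:
            col = thetas[:, prior.param_names.index(p)]
            naturals[:, j] = expit(col) if p in _LOGIT else np.exp(col)
        else:
            naturals[:, j] = _FIXED_NATURAL.get(p, 0.0)
    psign = -1.0 if punishment_sign == "aversive" else 1.0
    ll = kernels.loglik_batch(spec.model_id, naturals, psign, stim, action, reward)
    log_ml = float(logsumexp(ll) - math.log(n_draws))
    ratios = np.exp(ll - log_ml)  # mean 1 by construction
    se = float(np.std(ratios) / math.sqrt(n_draws))
    return EvidenceResult(log_ml=log_ml, se=se, n_draws=n_draws)
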