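"""Hierarchical empirical-Bayes MAP fitting (iterative EM scheme).

Each model is fit to every subject by maximum a posteriori estimation under
a group-level Gaussian prior over *transformed* parameters (learning rates
and the WSLS consistency via logit, temperatures via log, so the search
space is unbounded). The group prior itself is learned by expectation
maximization:

E-step
    For each subject, maximise log-likelihood + log prior density in
    transformed space (multi-start quasi-Newton), keeping the MAP estimate
    and the curvature (finite-difference Hessian) at the optimum.
M-step
    Update the prior mean to the mean of the MAP estimates, and the prior
    variance to the mean of squared deviations plus inverse-Hessian
    diagonals (the usual empirical-Bayes correction for per-subject
    estimation uncertainty), floored to avoid collapse.

Iteration stops when the prior means move less than ``tol`` or after
``max_em_iter`` rounds. Per-subject log model evidence is then computed by
the Laplace approximation around the MAP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .models import ChoiceDataset, ModelSpec, log_likelihood

__all__ = [
    "FitConfig",
    "GroupPrior",
    "SubjectFit",
    "EMResult",
    "transform",
    "untransform",
    "fit_subject_map",
    "em_fit_group",
    "laplace_evidence",
]

LOG_2PI = math.log(2.0 * math.pi)


def _subject_rng(seed: int, subject_id: str, salt: int = 0) -> np.random.Generator:
    """Restart draws keyed to the subject, not the iteration order.

    Keeps group fits invariant to subject ordering and makes adding
    restarts a strict superset of the starts already tried.
    """
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([seed, salt, zlib.crc32(subject_id.encode())])
    )


# ---------------------------------------------------------------------------
# parameter transforms

_LOGIT_PREFIXES = ("alpha", "consistency")


def _is_logit(name: str) -> bool:
    return name.startswith(_LOGIT_PREFIXES)


def transform(params: dict[str, float], spec: ModelSpec) -> np.ndarray:
    """Native -> unbounded space: logit for rates in (0,1), log for betas."""
    out = np.empty(spec.n_params)
    for i, name in enumerate(spec.param_names):
        v = params[name]
        if _is_logit(name):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
            out[i] = logit(v)
        else:
            if v <= 0.0:
                raise ValueError(f"{name}={v} must be positive")
            out[i] = math.log(v)
    return out


def untransform(x: np.ndarray, spec: ModelSpec) -> dict[str, float]:
    """Unbounded -> native space (inverse of :func:`transform`)."""
    params = {}
    for i, name in enumerate(spec.param_names):
        if _is_logit(name):
            params[name] = float(expit(x[i]))
        else:
            # clip to keep exp finite; the softmax saturates long before this
            params[name] = float(math.exp(min(float(x[i]), 50.0)))
    return params


# ---------------------------------------------------------------------------
# containers


@dataclass
class FitConfig:
    n_restarts: int = 5
    max_em_iter: int = 50
    tol: float = 1e-3  # convergence on max |change in prior mean|
    optimizer_tol: float = 1e-6
    var_floor: float = 1e-4
    hess_step: float = 1e-3
    seed: int = 0
    init_prior_mean: float = 0.0  # transformed space: alpha=0.5, beta=1
    init_prior_var: float = 3.0


@dataclass
class GroupPrior:
    """Diagonal Gaussian prior over transformed parameters."""

    mean: np.ndarray
    var: np.ndarray
    param_names: tuple[str, ...]

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if np.any(self.var <= 0):
            raise ValueError("prior variances must be strictly positive")

    @classmethod
    def initial(cls, spec: ModelSpec, config: FitConfig) -> "GroupPrior":
        k = spec.n_params
        return cls(
            mean=np.full(k, config.init_prior_mean),
            var=np.full(k, config.init_prior_var),
            param_names=spec.param_names,
        )

    def log_density(self, x: np.ndarray) -> float:
        z = (x - self.mean) ** 2 / self.var
        return float(-0.5 * np.sum(z + np.log(self.var) + LOG_2PI))


@dataclass
class SubjectFit:
    subject_id: str
    model_id: str
    x_map: np.ndarray  # transformed-space MAP
    params: dict[str, float]  # native-space MAP
    neg_log_posterior: float
    log_lik: float
    hessian: np.ndarray  # of the negative log posterior at the MAP
    converged: bool
    n_restarts_used: int
    n_obs: int
    log_evidence: float = np.nan
    evidence_fallback: bool = False


@dataclass
class EMResult:
    model_id: str
    prior: GroupPrior
    fits: list[SubjectFit]
    prior_trajectory: list[GroupPrior] = field(default_factory=list)
    penalized_ll_trajectory: list[float] = field(default_factory=list)
    iterations_run: int = 0
    seed: int = 0

    @property
    def sum_log_evidence(self) -> float:
        return float(sum(f.log_evidence for f in self.fits))

    def evidence_vector(self) -> np.ndarray:
        return np.array([f.log_evidence for f in self.fits])


# ---------------------------------------------------------------------------
# per-subject MAP


def _neg_log_posterior(x, dataset, spec, prior):
    params = untransform(x, spec)
    return -(log_likelihood(dataset, params, spec) + prior.log_density(x))


def _fd_hessian(f, x, step):
    """Symmetric finite-difference Hessian (central differences)."""
    k = len(x)
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = step
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = step
            fij = f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4.0 * step**2)
    return hess


def fit_subject_map(
    dataset: ChoiceDataset,
    spec: ModelSpec,
    prior: GroupPrior,
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SubjectFit:
    """MAP estimate for one subject under the group prior.

    Runs ``n_restarts`` quasi-Newton searches (first start at the prior
    mean, the rest drawn from the prior) and keeps the best optimum. A fit
    where no restart converges is returned flagged, never raised.
    """
    if len(prior.mean) != spec.n_params:
        raise ValueError(
            f"prior dimension {len(prior.mean)} != model dimension {spec.n_params}"
        )
    config = config or FitConfig()
    if rng is None:
        rng = _subject_rng(config.seed, dataset.subject_id)

    def objective(x):
        return _neg_log_posterior(x, dataset, spec, prior)

    best = None
    any_converged = False
    for start in range(max(1, config.n_restarts)):
        if start == 0:
            x0 = prior.mean.copy()
        else:
            x0 = prior.mean + np.sqrt(prior.var) * rng.standard_normal(spec.n_params)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", tol=config.optimizer_tol
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    x_map = np.asarray(best.x, dtype=float)
    params = untransform(x_map, spec)
    hess = _fd_hessian(objective, x_map, config.hess_step)
    fit = SubjectFit(
        subject_id=dataset.subject_id,
        model_id=spec.model_id,
        x_map=x_map,
        params=params,
        neg_log_posterior=float(best.fun),
        log_lik=log_likelihood(dataset, params, spec),
        hessian=hess,
        converged=any_converged,
        n_restarts_used=max(1, config.n_restarts),
        n_obs=dataset.n_valid_trials,
    )
    fit.log_evidence, fit.evidence_fallback = _laplace(fit)
    return fit


# ---------------------------------------------------------------------------
# Laplace model evidence


def _laplace(fit: SubjectFit) -> tuple[float, bool]:
    k = len(fit.x_map)
    log_post = -fit.neg_log_posterior
    if k == 0:
        return log_post, False
    sign, logdet = np.linalg.slogdet(fit.hessian)
    if sign > 0 and np.isfinite(logdet):
        return log_post + 0.5 * k * LOG_2PI - 0.5 * logdet, False
    # degenerate curvature: BIC-style penalty on the likelihood, flagged
    return fit.log_lik - 0.5 * k * math.log(max(fit.n_obs, 2)), True


def laplace_evidence(fit: SubjectFit) -> float:
    """Laplace approximation to the log model evidence for one subject.

    log p(data | model) ~= log posterior at the MAP + (k/2) log 2*pi
    - 1/2 log det H, with H the Hessian of the negative log posterior. With
    no free parameters this is exactly the log-likelihood. If H is not
    positive definite the fit falls back to a BIC-style penalty and is
    flagged via ``evidence_fallback``.
    """
    value, _fallback = _laplace(fit)
    return float(value)


# ---------------------------------------------------------------------------
# EM over the group


def em_fit_group(
    datasets: list[ChoiceDataset],
    spec: ModelSpec,
    config: FitConfig | None = None,
) -> EMResult:
    """Fit one model to a group of subjects with empirical-Bayes EM."""
    if len(datasets) < 2:
        raise ValueError("em_fit_group needs at least 2 subjects")
    config = config or FitConfig()
    prior = GroupPrior.initial(spec, config)
    result = EMResult(model_id=spec.model_id, prior=prior, fits=[], seed=config.seed)

    fits: list[SubjectFit] = []
    for it in range(config.max_em_iter):
        fits = [
            fit_subject_map(
                d, spec, prior, config, _subject_rng(config.seed, d.subject_id, it)
            )
            for d in datasets
        ]
        result.prior_trajectory.append(prior)
        result.penalized_ll_trajectory.append(
            -sum(f.neg_log_posterior for f in fits)
        )
        # accumulate in subject-id order so fits are order-invariant bit-for-bit
        ordered = sorted(fits, key=lambda f: f.subject_id)
        x = np.stack([f.x_map for f in ordered])
        new_mean = x.mean(axis=0)
        inv_hess_diag = np.stack([_inv_hessian_diag(f.hessian) for f in ordered])
        new_var = np.mean((x - new_mean) ** 2 + inv_hess_diag, axis=0)
        new_var = np.maximum(new_var, config.var_floor)
        shift = float(np.max(np.abs(new_mean - prior.mean)))
        prior = GroupPrior(new_mean, new_var, spec.param_names)
        result.iterations_run = it + 1
        if shift < config.tol:
            break

    result.prior = prior
    result.fits = fits
    return result


def fits_to_json(results: list[EMResult]) -> str:
    """Serialize fitted models: per subject per model the native parameters,
    log evidence and convergence flag, plus the fitted group prior."""
    import json

    payload = {}
    for em in results:
        payload[em.model_id] = {
            "group_prior": {
                "param_names": list(em.prior.param_names),
                "mean": em.prior.mean.tolist(),
                "var": em.prior.var.tolist(),
            },
            "iterations_run": em.iterations_run,
            "seed": em.seed,
            "subjects": {
                f.subject_id: {
                    "params": f.params,
                    "log_evidence": f.log_evidence,
                    "log_lik": f.log_lik,
                    "converged": f.converged,
                    "evidence_fallback": f.evidence_fallback,
                }
                for f in em.fits
            },
        }
    return json.dumps(payload, indent=2)


def _inv_hessian_diag(hess: np.ndarray) -> np.ndarray:
    """diag(H^-1), guarded against indefinite curvature."""
    k = hess.shape[0]
    try:
        inv = np.linalg.inv(hess)
        d = np.diag(inv)
        if np.all(np.isfinite(d)) and np.all(d > 0):
            return d
    except np.linalg.LinAlgError:
        pass
    d = np.diag(hess)
    out = np.where(d > 0, 1.0 / np.maximum(d, 1e-12), 1.0)
    return out
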