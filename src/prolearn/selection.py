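"""Model comparison: summed log evidence, iBIC and exceedance probabilities.

Three complementary metrics, computed per group:

* summed per-subject Laplace log model evidence (higher is better);
* the integrated Bayesian information criterion,
  iBIC = -2 * sum_subjects(log evidence) + h * ln(N), with h the number of
  group-level hyperparameters (a mean and a variance per model parameter,
  so h = 2k) and N the total number of non-missed trials (lower is better);
* random-effects exceedance probabilities: treating the generating model as
  a random effect across subjects, a variational Dirichlet scheme estimates
  the population frequency of each model, and the exceedance probability is
  the posterior probability that a model is the most frequent one,
  estimated by Monte-Carlo sampling of the fitted Dirichlet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .fitting import EMResult
from .models import ModelSpec

__all__ = [
    "ModelComparisonResult",
    "integrated_bic",
    "exceedance_probabilities",
    "compare_models",
    "select_winning_model",
]


@dataclass
class ModelComparisonResult:
    model_ids: list[str]
    sum_log_evidence: np.ndarray
    ibic: np.ndarray
    dirichlet_alpha: np.ndarray
    model_frequency: np.ndarray  # expected population frequency r_m
    exceedance: np.ndarray
    group: str = "all"

    def winner(self) -> str:
        return self.model_ids[int(np.argmax(self.exceedance))]

    def metric_winners(self) -> dict[str, str]:
        return {
            "sum_log_evidence": self.model_ids[int(np.argmax(self.sum_log_evidence))],
            "ibic": self.model_ids[int(np.argmin(self.ibic))],
            "exceedance": self.model_ids[int(np.argmax(self.exceedance))],
        }

    def metrics_agree(self) -> bool:
        return len(set(self.metric_winners().values())) == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_id": self.model_ids,
                "group": self.group,
                "sum_lme": self.sum_log_evidence,
                "ibic": self.ibic,
                "dirichlet_alpha": self.dirichlet_alpha,
                "model_frequency": self.model_frequency,
                "exceedance": self.exceedance,
            }
        )


def integrated_bic(
    evidences, spec: ModelSpec, prior=None, total_observations: int | None = None
) -> float:
    """iBIC = -2 * sum(log evidence) + h * ln(N_total).

    ``evidences`` is the per-subject log model evidences under the fitted
    group prior; ``h = 2 * n_params`` counts the group-level hyperparameters
    (mean and variance per parameter); ``total_observations`` is the total
    number of non-missed trials across subjects.
    """
    if total_observations is None or total_observations <= 0:
        raise ValueError("total_observations must be a positive trial count")
    evidences = np.asarray(evidences, dtype=float)
    h = 2 * spec.n_params
    return float(-2.0 * evidences.sum() + h * math.log(total_observations))


def exceedance_probabilities(
    lme_matrix: np.ndarray,
    *,
    n_samples: int = 100_000,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random-effects Bayesian model selection over a subjects x models
    log-evidence matrix.

    Variational update with a uniform Dirichlet(1) prior: subject-wise model
    responsibilities g_nm are softmaxed log evidences tilted by the current
    Dirichlet expectation, and the concentrations accumulate the
    responsibilities. Exceedance probabilities are Monte-Carlo frequencies
    with which each model has the largest sampled frequency.

    Returns ``(alpha, model_frequency, exceedance)``.
    """
    lme = np.asarray(lme_matrix, dtype=float)
    if lme.ndim != 2 or lme.shape[1] < 2:
        raise ValueError("lme_matrix must be 2-D with at least 2 models")
    if not np.all(np.isfinite(lme)):
        raise ValueError("lme_matrix contains non-finite entries")
    n_sub, n_models = lme.shape
    alpha0 = np.ones(n_models)
    alpha = alpha0.copy()
    for _ in range(max_iter):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        new_alpha = alpha0 + g.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    exceedance = np.bincount(winners, minlength=n_models) / n_samples
    freq = alpha / alpha.sum()
    return alpha, freq, exceedance


def compare_models(
    results: list[EMResult],
    specs: list[ModelSpec],
    *,
    group: str = "all",
    n_samples: int = 100_000,
    seed: int = 0,
) -> ModelComparisonResult:
    """Aggregate fitted models for one group into the three metrics."""
    if len(results) != len(specs):
        raise ValueError("results and specs must align")
    lme = np.stack([r.evidence_vector() for r in results], axis=1)
    total_obs = sum(f.n_obs for f in results[0].fits)
    ibic = np.array(
        [
            integrated_bic(r.evidence_vector(), s, total_observations=total_obs)
            for r, s in zip(results, specs)
        ]
    )
    if lme.shape[1] == 1:  # degenerate single-candidate comparison
        alpha = np.array([1.0 + lme.shape[0]])
        freq = np.array([1.0])
        exceedance = np.array([1.0])
    else:
        alpha, freq, exceedance = exceedance_probabilities(
            lme, n_samples=n_samples, seed=seed
        )
    return ModelComparisonResult(
        model_ids=[s.model_id for s in specs],
        sum_log_evidence=lme.sum(axis=0),
        ibic=ibic,
        dirichlet_alpha=alpha,
        model_frequency=freq,
        exceedance=exceedance,
        group=group,
    )


@dataclass
class WinnerReport:
    winners: dict[str, str]  # group -> model_id
    agreement: dict[str, bool]  # group -> all three metrics agree?
    details: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def any_disagreement(self) -> bool:
        return not all(self.agreement.values())


def select_winning_model(results_by_group: dict[str, ModelComparisonResult]) -> WinnerReport:
    """Winner per group = argmax exceedance; flags metric disagreement."""
    winners, agreement, details = {}, {}, {}
    for group, res in results_by_group.items():
        winners[group] = res.winner()
        agreement[group] = res.metrics_agree()
        details[group] = res.metric_winners()
    return WinnerReport(winners=winners, agreement=agreement, details=details)
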