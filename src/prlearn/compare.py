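"""Bridge-sampling marginal likelihoods and posterior model probabilities.

The marginal likelihood of each model is estimated from its posterior draws
with the iterative (Meng–Wong) bridge estimator using a moment-matched
multivariate-normal proposal on the unconstrained scale.  Half of the draws
calibrate the proposal, the other half enter the estimator, the standard
split that reduces the bias from using the same draws twice.  Posterior
model probabilities follow from the log marginal likelihoods and prior model
probabilities (equal by default, 1/3 each for the three models).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .inference import HierarchicalModel, PriorSpec, log_joint, _prepare_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BridgeResult:
    """Bridge-sampling estimate of one model's log marginal likelihood."""

    log_ml: float
    n_iter: int
    converged: bool
    n_excluded: int = 0


@dataclass(frozen=True)
class ComparisonResult:
    """Marginal-likelihood model comparison over a set of models.

    ``table`` has one row per model: log marginal likelihood, estimator
    iteration count, convergence flag and posterior model probability under
    the supplied prior model probabilities.
    """

    table: pd.DataFrame

    @property
    def best_model(self) -> str:
        return self.table.loc[self.table["post_prob"].idxmax(), "model"]


def log_marginal_bridge(
    draws: np.ndarray,
    log_unnorm_posterior: Callable[[np.ndarray], np.ndarray],
    seed: int = 0,
    max_iter: int = 1000,
    rtol: float = 1e-10,
) -> BridgeResult:
    """Iterative bridge-sampling estimate of the log marginal likelihood.

    Parameters
    ----------
    draws
        [N, D] posterior draws on the unconstrained scale (N >= 1000
        recommended).  The first half fits the multivariate-normal proposal
        (moment matching); the second half enters the estimator.
    log_unnorm_posterior
        Vectorised callable mapping [P, D] points to the [P] unnormalised log
        posterior (prior x likelihood) on the same scale.
    seed
        Seed for the proposal draws.
    max_iter, rtol
        The fixed-point iteration stops when the relative change of the
        estimate falls below ``rtol`` or after ``max_iter`` iterations.

    Notes
    -----
    Proposal points where the posterior density evaluates non-finite are
    excluded with a warning (they contribute zero weight).  All arithmetic is
    carried out in log space with log-sum-exp.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.ndim != 2:
        raise ValueError("draws must be [N, D]")
    if draws.shape[1] == 0:
        # a model with no free parameters has nothing to integrate: the
        # marginal likelihood is the fixed data likelihood itself
        value = float(np.asarray(log_unnorm_posterior(draws[:1]))[0])
        return BridgeResult(log_ml=value, n_iter=0, converged=True)
    n = draws.shape[0]
    if n < 4:
        raise ValueError("need at least 4 draws")
    half = n // 2
    fit_half, est_half = draws[:half], draws[half:]

    mean = fit_half.mean(axis=0)
    cov = np.cov(fit_half, rowvar=False)
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(fit_half.shape[1])
    proposal = multivariate_normal(mean=mean, cov=cov, allow_singular=True)
    rng = np.random.default_rng(seed)
    n2 = est_half.shape[0]
    prop_points = proposal.rvs(size=n2, random_state=rng)
    prop_points = np.atleast_2d(prop_points)
    if prop_points.shape[0] == 1 and n2 > 1:  # 1-D case transposes
        prop_points = prop_points.T

    l1 = np.asarray(log_unnorm_posterior(est_half)) - proposal.logpdf(est_half)
    l2 = np.asarray(log_unnorm_posterior(prop_points)) - proposal.logpdf(prop_points)
    bad = ~np.isfinite(l2)
    n_excluded = int(bad.sum())
    if n_excluded:
        logger.warning(
            "bridge sampling: excluding %d proposal points with non-finite "
            "posterior density", n_excluded)
        l2 = l2[~bad]
    if not np.all(np.isfinite(l1)):
        raise FloatingPointError("non-finite posterior density at posterior draws")

    n1 = l1.size
    n2 = l2.size
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    lstar = float(np.median(l1))
    log_s1, log_s2 = np.log(s1), np.log(s2)

    log_r = 0.0  # log of r / exp(lstar)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        num = logsumexp(
            (l2 - lstar) - np.logaddexp(log_s1 + (l2 - lstar), log_s2 + log_r)
        ) - np.log(n2)
        den = logsumexp(
            -np.logaddexp(log_s1 + (l1 - lstar), log_s2 + log_r)
        ) - np.log(n1)
        log_r_new = num - den
        delta = abs(log_r_new - log_r)
        log_r = log_r_new
        if delta < rtol * max(1.0, abs(log_r)):
            converged = True
            break
    if not converged:
        logger.warning("bridge sampling did not reach tolerance after %d "
                       "iterations (last change %.3g)", max_iter, delta)
    return BridgeResult(log_ml=float(log_r + lstar), n_iter=it,
                        converged=converged, n_excluded=n_excluded)


def posterior_model_probs(
    log_mls: Sequence[float], prior: Optional[Sequence[float]] = None
) -> np.ndarray:
    """Posterior model probabilities from log marginal likelihoods.

    With prior probabilities p_k (equal when omitted), the posterior
    probability of model k is proportional to ``p_k * ML_k``; computed as a
    softmax of ``log ML + log prior``.  Sums to 1.
    """
    log_mls = np.asarray(log_mls, dtype=float)
    if not np.all(np.isfinite(log_mls)):
        raise ValueError("log marginal likelihoods must be finite")
    k = log_mls.size
    if prior is None:
        prior = np.full(k, 1.0 / k)
    prior = np.asarray(prior, dtype=float)
    if prior.shape != log_mls.shape or abs(prior.sum() - 1.0) > 1e-8:
        raise ValueError("prior must match log_mls and sum to 1")
    w = log_mls + np.log(prior)
    w -= logsumexp(w)
    return np.exp(w)


def compare_models(
    fits: Mapping[str, HierarchicalModel],
    dataset: pd.DataFrame,
    prior: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> ComparisonResult:
    """Bridge-sample every fitted model on a dataset and rank them.

    ``fits`` maps model id to a fitted :class:`HierarchicalModel` (all fitted
    to ``dataset`` with the same phase selection).
    """
    rows = []
    log_mls = []
    for model_id, est in fits.items():
        (choices, outcomes, sub_idx, cond_idx, _, _) = _prepare_dataset(
            dataset, est.phase
        )
        priors = est.priors if est.priors is not None else PriorSpec()

        def log_post(theta, _c=choices, _o=outcomes, _s=sub_idx, _ci=cond_idx,
                     _lay=est.layout_, _pr=priors, _v0=est.initial_value):
            return log_joint(theta, _c, _o, _s, _ci, _lay, _pr, _v0)

        res = log_marginal_bridge(est.posterior_.flat(), log_post, seed=seed)
        log_mls.append(res.log_ml)
        rows.append({"model": model_id, "log_ml": res.log_ml,
                     "bridge_iter": res.n_iter, "bridge_converged": res.converged})
    probs = posterior_model_probs(log_mls, prior)
    table = pd.DataFrame(rows)
    table["post_prob"] = probs
    return ComparisonResult(table=table)
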