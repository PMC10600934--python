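"""Hierarchical Bayesian fitting of the reinforcement-learning models.

The hierarchy has *condition* at the top and *subject* below: for each model
parameter, each condition has its own group mean on the unconstrained scale
(logit scale for learning rates, raw scale for the sensitivity and stickiness
weights), with a prior that is identical across conditions, and each subject
contributes one offset shared across both conditions, drawn from a zero-mean
normal whose standard deviation has its own prior.  A subject's
natural-scale parameter in a condition is therefore
``link(mu_condition + delta_subject)``.

Sampling uses ensemble MCMC (differential-evolution and snooker moves over a
large walker population), with the posterior density evaluated for the whole
ensemble at once through the batched likelihood.  A "chain" is one
independent ensemble run with its own seed and initialisation; convergence is
assessed with the split-chain Gelman–Rubin statistic across chains.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .agents import (
    LEARNING_RATE_PARAMS,
    MODEL_PARAMS,
    to_natural,
    to_unconstrained,
)
from .likelihood import batched_loglik
from .task import Phase

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Condition-symmetric priors for the hierarchical model.

    ``mu_sd`` is the standard deviation of the zero-mean normal prior on each
    unconstrained condition mean (identical for the two conditions);
    ``sigma_scale`` is the scale of the half-normal prior on the intersubject
    offset standard deviation.  Defaults are weakly informative: N(0, 1) on
    logit-scale learning-rate means (roughly uniform on the rate itself),
    N(0, 5) on sensitivity/stickiness means whose plausible magnitudes reach
    several units, and half-normal scales wide enough to accommodate
    substantial individual variation.
    """

    mu_sd: Mapping[str, float] = field(default_factory=lambda: {
        "alpha_rew": 1.0, "alpha_pun": 1.0, "alpha_reinf": 1.0,
        "tau_reinf": 5.0, "tau_stim": 5.0,
    })
    sigma_scale: Mapping[str, float] = field(default_factory=lambda: {
        "alpha_rew": 1.0, "alpha_pun": 1.0, "alpha_reinf": 1.0,
        "tau_reinf": 2.0, "tau_stim": 2.0,
    })


class ParamLayout:
    """Packing of the unconstrained parameter vector.

    Per model parameter, one contiguous block: ``[mu_cond0, mu_cond1,
    log_sigma, z_1 .. z_S]``.  Subject offsets are parameterised
    non-centrally: the sampled ``z_s`` are a-priori standard normal and the
    offset is ``delta_s = sigma * z_s``.  This removes the prior funnel
    between the offset scale and the offsets, which general-purpose ensemble
    moves cannot traverse efficiently in the centred form.  ``sigma`` is
    sampled on the log scale with the appropriate Jacobian term in the joint
    density.
    """

    def __init__(self, model_id: str, n_subjects: int, conditions: Tuple[str, str]):
        if model_id not in MODEL_PARAMS:
            raise ValueError(f"unknown model_id {model_id!r}")
        if len(conditions) != 2:
            raise ValueError("the hierarchy is defined for exactly two conditions")
        self.model_id = model_id
        self.params = MODEL_PARAMS[model_id]
        self.n_subjects = n_subjects
        self.conditions = tuple(conditions)
        self.block = 3 + n_subjects
        self.ndim = len(self.params) * self.block

    def slices(self, param: str):
        b = self.params.index(param) * self.block
        return b, b + 1, b + 2, slice(b + 3, b + 3 + self.n_subjects)

    def group_quantity_names(self) -> List[str]:
        names = []
        for p in self.params:
            for c in self.conditions:
                names.append(f"mu[{p},{c}]")
            names.append(f"sigma[{p}]")
            for c in self.conditions:
                names.append(f"mean[{p},{c}]")
        return names


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    # density of |N(0, scale)| for x >= 0, up to no truncation issues
    return (
        np.log(2.0) - 0.5 * _LOG_2PI - np.log(scale)
        - 0.5 * (x / scale) ** 2
    )


def log_joint(
    theta: np.ndarray,
    choices: np.ndarray,
    outcomes: np.ndarray,
    sess_subject: np.ndarray,
    sess_condition: np.ndarray,
    layout: ParamLayout,
    priors: PriorSpec = PriorSpec(),
    initial_value: float = 0.5,
) -> np.ndarray:
    """Unnormalised log posterior density at one or many unconstrained points.

    The density is the sum of the prior log-densities (including the Jacobian
    of the log-sigma transform), the hierarchical offset densities, and the
    session log-likelihoods of every subject x condition cell at the linked
    natural-scale parameters.  Finite for any finite point.

    Parameters
    ----------
    theta
        [D] or [P, D] unconstrained parameter points.
    choices, outcomes
        [S, T] session arrays (every subject x condition cell present).
    sess_subject, sess_condition
        [S] integer indices mapping each session to its subject and condition.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    P = theta.shape[0]
    if theta.shape[1] != layout.ndim:
        raise ValueError(f"expected {layout.ndim} dimensions, got {theta.shape[1]}")
    n_cells = layout.n_subjects * 2
    if choices.shape[0] != n_cells:
        raise ValueError(
            f"dataset has {choices.shape[0]} sessions; expected "
            f"{n_cells} (= {layout.n_subjects} subjects x 2 conditions)"
        )
    lp = np.zeros(P)
    natural: Dict[str, np.ndarray] = {}
    for p in layout.params:
        i0, i1, isig, idel = layout.slices(p)
        mu = theta[:, [i0, i1]]                   # [P, 2]
        log_sigma = theta[:, isig]
        sigma = np.exp(log_sigma)
        z = theta[:, idel]                        # [P, S_sub], standardised
        mu_sd = priors.mu_sd[p]
        lp += -0.5 * ((mu / mu_sd) ** 2).sum(axis=1) - _LOG_2PI - 2 * np.log(mu_sd)
        lp += _halfnormal_logpdf(sigma, priors.sigma_scale[p]) + log_sigma
        lp += (-0.5 * z ** 2 - 0.5 * _LOG_2PI).sum(axis=1)
        delta = sigma[:, None] * z
        u = mu[:, sess_condition] + delta[:, sess_subject]   # [P, S]
        natural[p] = to_natural(p, u) if p in LEARNING_RATE_PARAMS else u
    if layout.model_id == "M2":
        a_rew = a_pun = natural["alpha_reinf"]
    else:
        a_rew, a_pun = natural["alpha_rew"], natural["alpha_pun"]
    t_stim = natural.get("tau_stim")
    if t_stim is None:
        t_stim = np.zeros_like(natural["tau_reinf"])
    ll = batched_loglik(
        choices, outcomes, a_rew, a_pun, natural["tau_reinf"], t_stim,
        initial_value=initial_value,
    )
    return lp + ll.sum(axis=1)


def rhat(chain_draws: np.ndarray) -> float:
    """Split-chain Gelman–Rubin potential scale reduction factor.

    ``chain_draws`` is [m, n] (m >= 2 chains, n >= 2 draws each, even n
    preferred).  Each chain is split in half, the between- and within-chain
    variances are combined into the pooled variance estimate, and the square
    root of its ratio to the within-chain variance is returned.  Approaches 1
    as chains mix.  Returns ``nan`` when every half-chain has zero variance
    (the statistic is undefined for constant chains).
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 chains with at least 2 draws each")
    n = x.shape[1] - (x.shape[1] % 2)
    x = np.concatenate([x[:, : n // 2], x[:, n // 2: n]], axis=0)
    m, n = x.shape
    within = x.var(axis=1, ddof=1)
    W = within.mean()
    if W == 0.0:
        return float("nan")
    B = n * x.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


@dataclass
class PosteriorDraws:
    """Posterior draws of all hierarchical quantities from one fit.

    ``draws`` is [chains, draws_per_chain, D] on the unconstrained scale;
    helper methods expose natural-scale group-level quantities.  Within a
    chain, draws are ordered by ensemble step (all walkers of a step are
    contiguous), so the split-chain diagnostic retains its time-ordering
    interpretation.
    """

    draws: np.ndarray
    layout: ParamLayout
    seed: int
    warmup: int
    thin: int
    subjects: Tuple[str, ...]

    @property
    def model_id(self) -> str:
        return self.layout.model_id

    @property
    def conditions(self) -> Tuple[str, str]:
        return self.layout.conditions

    @property
    def n_pooled(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        """All draws pooled across chains: [chains * draws, D]."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    def mu_draws(self, param: str, condition: str) -> np.ndarray:
        i0, i1, _, _ = self.layout.slices(param)
        idx = {self.conditions[0]: i0, self.conditions[1]: i1}[condition]
        return self.draws[:, :, idx]

    def sigma_draws(self, param: str) -> np.ndarray:
        _, _, isig, _ = self.layout.slices(param)
        return np.exp(self.draws[:, :, isig])

    def group_mean_draws(self, param: str, condition: str) -> np.ndarray:
        """Natural-scale condition-mean draws, [chains, draws_per_chain].

        Learning rates are mapped through the inverse logit, so every draw
        lies in (0, 1); sensitivity parameters are returned as sampled.
        """
        return to_natural(param, self.mu_draws(param, condition))

    def delta_draws(self, param: str) -> np.ndarray:
        """Subject offset draws on the unconstrained scale,
        [chains, draws_per_chain, n_subjects] (``sigma * z`` under the
        non-centred parameterisation)."""
        _, _, isig, idel = self.layout.slices(param)
        sigma = np.exp(self.draws[:, :, isig])
        return sigma[:, :, None] * self.draws[:, :, idel]

    def group_quantities(self) -> Dict[str, np.ndarray]:
        """All group-level quantities by name, each [chains, draws_per_chain]."""
        out: Dict[str, np.ndarray] = {}
        for p in self.layout.params:
            for c in self.conditions:
                out[f"mu[{p},{c}]"] = self.mu_draws(p, c)
            out[f"sigma[{p}]"] = self.sigma_draws(p)
            for c in self.conditions:
                out[f"mean[{p},{c}]"] = self.group_mean_draws(p, c)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Columnar (chain, draw, quantity, value) representation of the
        group-level quantities plus subject offsets."""
        rows = []
        n_chain, n_draw, _ = self.draws.shape
        chain_idx = np.repeat(np.arange(n_chain), n_draw)
        draw_idx = np.tile(np.arange(n_draw), n_chain)
        for name, q in self.group_quantities().items():
            rows.append(pd.DataFrame(
                {"chain": chain_idx, "draw": draw_idx,
                 "quantity": name, "value": q.reshape(-1)}
            ))
        for p in self.layout.params:
            deltas = self.delta_draws(p)
            for j, sid in enumerate(self.subjects):
                rows.append(pd.DataFrame(
                    {"chain": chain_idx, "draw": draw_idx,
                     "quantity": f"delta[{p},{sid}]",
                     "value": deltas[:, :, j].reshape(-1)}
                ))
        return pd.concat(rows, ignore_index=True)


def _prepare_dataset(X: pd.DataFrame, phase: str):
    """Split a tidy trial table into aligned [S, T] arrays.

    Every subject must have exactly one complete session per condition; a
    missing subject x condition cell is an error.
    """
    from .io import STIMULUS_INDEX, validate_sessions

    validate_sessions(X)
    conditions = tuple(sorted(X["condition"].unique()))
    if len(conditions) != 2:
        raise ValueError(f"expected exactly 2 conditions, found {conditions}")
    subjects = tuple(sorted(X["subject"].unique()))
    sel = X
    if phase == "acquisition":
        sel = X[X["phase"] == Phase.ACQUISITION.value]
    elif phase == "reversal":
        sel = X[X["phase"] == Phase.REVERSAL.value]
    elif phase != "all":
        raise ValueError(f"phase must be all/acquisition/reversal, got {phase!r}")
    choices_rows, outcome_rows, sub_idx, cond_idx = [], [], [], []
    for si, sub in enumerate(subjects):
        for ci, cond in enumerate(conditions):
            cell = sel[(sel["subject"] == sub) & (sel["condition"] == cond)]
            if cell.empty:
                raise ValueError(f"missing session for subject {sub!r}, "
                                 f"condition {cond!r}")
            cell = cell.sort_values("trial")
            choices_rows.append(cell["choice"].map(STIMULUS_INDEX).to_numpy())
            outcome_rows.append(cell["outcome"].to_numpy(dtype=int))
            sub_idx.append(si)
            cond_idx.append(ci)
    lengths = {len(r) for r in choices_rows}
    if len(lengths) != 1:
        raise ValueError(f"sessions have unequal lengths {sorted(lengths)}")
    return (
        np.array(choices_rows), np.array(outcome_rows),
        np.array(sub_idx), np.array(cond_idx), subjects, conditions,
    )


class HierarchicalModel(BaseEstimator):
    """Hierarchical Bayesian reinforcement-learning model, scikit-learn style.

    ``fit`` takes a tidy trial table (columns ``subject``, ``condition``,
    ``trial``, ``phase``, ``choice``, ``outcome``, ``chosen_role``) covering
    every subject in both conditions, and samples the posterior over
    condition means, subject offsets and offset scales.

    Parameters
    ----------
    model : {"M1", "M2", "M3"}
        Which choice model to fit.
    phase : {"all", "acquisition", "reversal"}
        Fit all 80 trials or a single 40-trial phase; phase-restricted fits
        re-initialise the agent state at the start of the phase.
    chains : int
        Number of independent ensemble runs (>= 2 for convergence checks).
    warmup : int
        Discarded ensemble steps per chain.
    draws : int
        Target retained draws per chain (pooled over walkers); the number of
        post-warmup steps is ``ceil(draws / nwalkers) * thin``.
    thin : int
        Keep every ``thin``-th post-warmup step.
    nwalkers : int or None
        Ensemble size; default ``2 * ndim`` (rounded up to even).
    priors : PriorSpec or None
        Priors; defaults to the condition-symmetric weakly informative set.
    initial_value : float
        Common initial stimulus value of the agents.
    seed : int
        Base seed; chain c uses ``seed + c`` for initialisation and moves.
    rhat_threshold : float
        Convergence guideline; any group-level quantity at or above it marks
        the fit as unconverged (flagged, not fatal).

    Attributes
    ----------
    posterior_ : PosteriorDraws
    rhat_ : dict mapping group-level quantity name to its split-chain R-hat
    max_rhat_ : float
    converged_ : bool
    group_means_ : DataFrame of natural-scale posterior condition means
    conditions_, subjects_ : labels seen during fit
    """

    def __init__(
        self,
        model: str = "M3",
        phase: str = "all",
        chains: int = 4,
        warmup: int = 1500,
        draws: int = 2000,
        thin: int = 16,
        nwalkers: Optional[int] = None,
        priors: Optional[PriorSpec] = None,
        initial_value: float = 0.5,
        seed: int = 0,
        rhat_threshold: float = 1.2,
    ):
        self.model = model
        self.phase = phase
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.thin = thin
        self.nwalkers = nwalkers
        self.priors = priors
        self.initial_value = initial_value
        self.seed = seed
        self.rhat_threshold = rhat_threshold

    # ---- internals -------------------------------------------------

    def _pooled_ml_init(self, choices, outcomes, cond_idx) -> np.ndarray:
        """Crude per-condition pooled maximum-likelihood starting point.

        All subjects of one condition share a single parameter set; the
        resulting unconstrained means centre the walker initialisation.
        """
        params = MODEL_PARAMS[self.model]
        mu0 = {"alpha_rew": 0.0, "alpha_pun": 0.0, "alpha_reinf": 0.0,
               "tau_reinf": 3.0, "tau_stim": 0.0}
        start = np.array([mu0[p] for p in params])
        out = np.zeros((len(params), 2))
        for ci in range(2):
            mask = cond_idx == ci
            C, O = choices[mask], outcomes[mask]

            def nll(x):
                vals = {p: x[i] for i, p in enumerate(params)}
                nat = {p: to_natural(p, np.full((1, C.shape[0]), v))
                       for p, v in vals.items()}
                if self.model == "M2":
                    ar = ap = nat["alpha_reinf"]
                else:
                    ar, ap = nat["alpha_rew"], nat["alpha_pun"]
                ts = nat.get("tau_stim", np.zeros_like(ar))
                return -batched_loglik(
                    C, O, ar, ap, nat["tau_reinf"], ts,
                    initial_value=self.initial_value,
                ).sum()

            res = minimize(nll, start, method="Nelder-Mead",
                           options=dict(maxiter=600, xatol=1e-3, fatol=1e-3))
            out[:, ci] = res.x
        return out

    # ---- estimator API ---------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalModel":
        t_start = time.time()
        (choices, outcomes, sub_idx, cond_idx,
         subjects, conditions) = _prepare_dataset(X, self.phase)
        layout = ParamLayout(self.model, len(subjects), conditions)
        priors = self.priors if self.priors is not None else PriorSpec()
        ndim = layout.ndim
        nwalkers = self.nwalkers
        if nwalkers is None:
            nwalkers = 2 * ndim + (2 * ndim) % 2
        if nwalkers < 2 * ndim:
            raise ValueError(f"nwalkers must be >= {2 * ndim}")

        def log_prob(theta):
            return log_joint(theta, choices, outcomes, sub_idx, cond_idx,
                             layout, priors, self.initial_value)

        logger.info("fit %s phase=%s: %d sessions, ndim=%d, %d walkers",
                    self.model, self.phase, choices.shape[0], ndim, nwalkers)
        mu_init = self._pooled_ml_init(choices, outcomes, cond_idx)
        center = np.zeros(ndim)
        for i, p in enumerate(layout.params):
            i0, i1, isig, _ = layout.slices(p)
            center[i0], center[i1] = mu_init[i]
            center[isig] = np.log(min(0.3, priors.sigma_scale[p]))

        kept_steps = int(np.ceil(self.draws / nwalkers))
        sample_steps = kept_steps * self.thin
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        chain_list = []
        for c in range(self.chains):
            rng = np.random.default_rng(self.seed + c)
            p0 = center + rng.normal(0.0, 0.15, size=(nwalkers, ndim))
            sampler = emcee.EnsembleSampler(
                nwalkers, ndim, log_prob, vectorize=True, moves=moves
            )
            sampler.random_state = np.random.RandomState(
                (self.seed + c) % (2 ** 31)
            ).get_state()
            sampler.run_mcmc(p0, self.warmup + sample_steps, progress=False)
            kept = sampler.get_chain(discard=self.warmup, thin=self.thin)
            chain_list.append(kept.reshape(-1, ndim))
            logger.debug("chain %d/%d done, mean acceptance %.2f",
                         c + 1, self.chains,
                         float(sampler.acceptance_fraction.mean()))
        draws = np.stack(chain_list)

        self.layout_ = layout
        self.conditions_ = conditions
        self.subjects_ = subjects
        self.posterior_ = PosteriorDraws(
            draws=draws, layout=layout, seed=self.seed,
            warmup=self.warmup, thin=self.thin, subjects=subjects,
        )
        self.rhat_ = {
            name: rhat(q) for name, q in self.posterior_.group_quantities().items()
        }
        finite = [v for v in self.rhat_.values() if np.isfinite(v)]
        self.max_rhat_ = float(max(finite)) if finite else float("nan")
        self.converged_ = bool(self.max_rhat_ < self.rhat_threshold)
        if not self.converged_:
            logger.warning("fit flagged unconverged: max R-hat %.3f", self.max_rhat_)
        rows = []
        for p in layout.params:
            for cond in conditions:
                g = self.posterior_.group_mean_draws(p, cond)
                rows.append({"parameter": p, "condition": cond,
                             "posterior_mean": float(g.mean())})
        self.group_means_ = pd.DataFrame(rows)
        self.runtime_s_ = time.time() - t_start
        logger.info("fit finished in %.0fs, max R-hat %.3f",
                    self.runtime_s_, self.max_rhat_)
        return self

    def log_likelihood(self, X: pd.DataFrame) -> np.ndarray:
        """Pooled-draw unnormalised log posterior of new data is not defined;
        this scores the fitted dataset structure at the posterior draws."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "posterior_")
        (choices, outcomes, sub_idx, cond_idx, _, _) = _prepare_dataset(X, self.phase)
        priors = self.priors if self.priors is not None else PriorSpec()
        return log_joint(self.posterior_.flat(), choices, outcomes, sub_idx,
                         cond_idx, self.layout_, priors, self.initial_value)


def fit(
    dataset: pd.DataFrame,
    model_id: str = "M3",
    priors: Optional[PriorSpec] = None,
    chains: int = 4,
    warmup: int = 1500,
    draws: int = 2000,
    thin: int = 16,
    seed: int = 0,
    phase: str = "all",
) -> HierarchicalModel:
    """Functional wrapper: construct and fit a :class:`HierarchicalModel`."""
    est = HierarchicalModel(
        model=model_id, phase=phase, chains=chains, warmup=warmup,
        draws=draws, thin=thin, priors=priors, seed=seed,
    )
    return est.fit(dataset)
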