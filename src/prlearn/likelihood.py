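"""Exact per-trial choice log-likelihoods for observed sessions.

The scorer replays a session: before each trial it computes the model's
choice probabilities from the current state, scores the observed choice,
then applies the value update with the observed outcome.  The scalar path
shares its update and softmax code with the generative agent, so a replay of
a simulated session reproduces the simulator's internal quantities exactly.

A separate batched path evaluates many parameter vectors on many sessions at
once with numpy; it is the computational core of the hierarchical fit and is
checked against the scalar path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .agents import AgentParams, AgentState, action_probabilities, update_values
from .task import STIMULI, Phase, TrialRecord


@dataclass(frozen=True)
class SessionLikelihoodTrace:
    """Full replay trace of one session under one parameter set.

    ``values[t]`` and ``q[t]`` are the stimulus values and choice scores in
    force *before* the choice on trial ``t``; ``choice_prob[t]`` /
    ``log_prob[t]`` score the observed choice.  ``total`` is the session
    log-likelihood, the sum of the per-trial log-probabilities.
    """

    values: np.ndarray      # [T, 3]
    q: np.ndarray           # [T, 3]
    choice_prob: np.ndarray  # [T]
    log_prob: np.ndarray     # [T]

    @property
    def total(self) -> float:
        return float(self.log_prob.sum())


def _validate_session(trials: Sequence[TrialRecord]) -> None:
    if not trials:
        raise ValueError("empty session")
    first = trials[0].trial
    for k, rec in enumerate(trials):
        if rec.trial != first + k:
            raise ValueError(
                f"non-consecutive trial indices: expected {first + k}, "
                f"got {rec.trial}"
            )
        if rec.outcome not in (0, 1):
            raise ValueError(f"trial {rec.trial}: outcome {rec.outcome!r} not in {{0,1}}")
        if rec.choice not in STIMULI:
            raise ValueError(f"trial {rec.trial}: unknown stimulus {rec.choice!r}")


def session_loglik(
    trials: Sequence[TrialRecord], params: AgentParams
) -> SessionLikelihoodTrace:
    """Replay one complete session in trial order and score the observed choices.

    State (stimulus values, previous choice) starts from the model's initial
    conditions at the first trial of the given sequence, so a phase-restricted
    subset is scored with re-initialised state.
    """
    _validate_session(trials)
    state = AgentState.initial(params)
    T = len(trials)
    values = np.empty((T, 3))
    q = np.empty((T, 3))
    choice_prob = np.empty(T)
    for t, rec in enumerate(trials):
        probs = action_probabilities(state, params)
        values[t] = state.values
        qt = params.tau_reinf * state.values
        if state.prev_choice is not None:
            qt = qt.copy()
            qt[STIMULI.index(state.prev_choice)] += params.stickiness
        q[t] = qt
        choice_prob[t] = probs[STIMULI.index(rec.choice)]
        state = update_values(state, rec.choice, rec.outcome, params)
    return SessionLikelihoodTrace(
        values=values, q=q, choice_prob=choice_prob, log_prob=np.log(choice_prob)
    )


def phase_subset(
    trials: Sequence[TrialRecord], phase: Optional[Phase]
) -> List[TrialRecord]:
    """Trials belonging to one phase (or all trials when ``phase`` is None)."""
    if phase is None:
        return list(trials)
    phase = Phase(phase)
    return [t for t in trials if t.phase is phase]


def batched_loglik(
    choices: np.ndarray,
    outcomes: np.ndarray,
    alpha_rew: np.ndarray,
    alpha_pun: np.ndarray,
    tau_reinf: np.ndarray,
    tau_stim: np.ndarray,
    initial_value: float = 0.5,
) -> np.ndarray:
    """Session log-likelihoods for many parameter points at once.

    Parameters
    ----------
    choices, outcomes
        Integer arrays of shape [S, T]: stimulus index (0..2) chosen and
        outcome (0/1) on each trial of each session.
    alpha_rew, alpha_pun, tau_reinf, tau_stim
        Arrays of shape [P, S]: per-point, per-session parameter values.
        For M2 pass the shared rate as both alphas; for M1 pass zeros for
        ``tau_stim``.

    Returns
    -------
    ndarray of shape [P, S] with total log-likelihood per point and session.

    Notes
    -----
    Softmax log-probabilities use a max-shifted log-sum-exp; no clipping is
    needed because softmax of finite scores is strictly positive.
    """
    choices = np.asarray(choices)
    outcomes = np.asarray(outcomes)
    P, S = alpha_rew.shape
    T = choices.shape[1]
    V = np.full((P, S, 3), float(initial_value))
    prev = np.full(S, -1)
    ll = np.zeros((P, S))
    sidx = np.arange(S)
    for t in range(T):
        c = choices[:, t]
        o = outcomes[:, t]
        Q = tau_reinf[:, :, None] * V
        seen = prev >= 0
        if seen.any():
            Q[:, sidx[seen], prev[seen]] += tau_stim[:, seen]
        qmax = Q.max(axis=2, keepdims=True)
        lse = qmax[:, :, 0] + np.log(np.exp(Q - qmax).sum(axis=2))
        ll += Q[:, sidx, c] - lse
        alpha = np.where(o == 1, alpha_rew, alpha_pun)
        V[:, sidx, c] += alpha * (o - V[:, sidx, c])
        prev = c
    return ll


def sessions_to_arrays(sessions: Sequence[Sequence[TrialRecord]]):
    """Stack equal-length sessions into [S, T] choice-index / outcome arrays."""
    lengths = {len(s) for s in sessions}
    if len(lengths) != 1:
        raise ValueError(f"sessions have unequal lengths {sorted(lengths)}")
    for s in sessions:
        _validate_session(s)
    choices = np.array([[STIMULI.index(r.choice) for r in s] for s in sessions])
    outcomes = np.array([[r.outcome for r in s] for s in sessions])
    return choices, outcomes
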