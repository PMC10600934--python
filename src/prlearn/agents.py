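"""Generative reinforcement-learning agents and synthetic cohorts.

Three nested Rescorla–Wagner choice models are implemented:

* **M1** — separate reward and punishment learning rates (``alpha_rew``,
  ``alpha_pun``) and a reinforcement-sensitivity weight ``tau_reinf``; no
  stickiness.
* **M2** — a single learning rate ``alpha_reinf``, reinforcement sensitivity
  and a stimulus-stickiness weight ``tau_stim`` on the previously chosen
  stimulus.
* **M3** — the full model: separate reward/punishment rates plus stickiness.

The chosen stimulus' value is updated by ``V <- V + alpha * (R - V)`` with
``R`` in {0, 1}; the choice score is ``Q_i = tau_reinf * V_i + tau_stim *
s_i`` where ``s_i`` indicates the previous choice (zero on trial 1), and
choice probabilities are ``softmax(Q)`` over the three stimuli with no
additional inverse temperature (beta = 1).

A synthetic cohort mirrors the within-subject two-condition design of the
human study: 19 subjects, one 80-trial session per condition, with one
normally distributed subject offset per parameter on the unconstrained scale
shared across both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit, softmax

from .task import (
    STIMULI,
    Phase,
    Role,
    RoleAssignment,
    TaskConfig,
    TrialRecord,
    sample_outcome,
)

#: Free parameters of each model, in canonical order.
MODEL_PARAMS: Dict[str, Tuple[str, ...]] = {
    "M1": ("alpha_rew", "alpha_pun", "tau_reinf"),
    "M2": ("alpha_reinf", "tau_reinf", "tau_stim"),
    "M3": ("alpha_rew", "alpha_pun", "tau_reinf", "tau_stim"),
}

#: Parameters constrained to (0, 1); mapped through logit/inverse-logit.
LEARNING_RATE_PARAMS = frozenset({"alpha_rew", "alpha_pun", "alpha_reinf"})

#: Default generating condition means for synthetic cohorts, on the natural
#: scale.  These are group-level estimates representative of published
#: hierarchical fits of the full model to this task under an acute
#: serotonergic-psychedelic (LSD) challenge versus placebo, modelling all 80
#: trials: markedly elevated reward learning rate and mildly elevated
#: punishment learning rate under the drug, reduced stickiness, and similar
#: reinforcement sensitivity.
DEFAULT_GROUP_MEANS: Dict[str, Dict[str, float]] = {
    "drug": {"alpha_rew": 0.87, "alpha_pun": 0.48, "alpha_reinf": 0.60,
             "tau_reinf": 4.70, "tau_stim": 0.23},
    "placebo": {"alpha_rew": 0.28, "alpha_pun": 0.39, "alpha_reinf": 0.35,
                "tau_reinf": 5.57, "tau_stim": 0.43},
}

#: Default intersubject standard deviations on the unconstrained scale
#: (logit units for learning rates, raw units for sensitivities).  Chosen as
#: a modest degree of individual variation: learning-rate offsets of +-0.5
#: logit units move a mid-range rate by roughly +-0.12, and sensitivity
#: offsets are small relative to the group means.
DEFAULT_SUBJECT_SD: Dict[str, float] = {
    "alpha_rew": 0.5, "alpha_pun": 0.5, "alpha_reinf": 0.5,
    "tau_reinf": 1.0, "tau_stim": 0.25,
}


def to_unconstrained(param: str, value: float) -> float:
    """Map a natural-scale parameter value to the unconstrained (fitting) scale."""
    return float(logit(value)) if param in LEARNING_RATE_PARAMS else float(value)


def to_natural(param: str, value):
    """Inverse of :func:`to_unconstrained`; works elementwise on arrays."""
    return expit(value) if param in LEARNING_RATE_PARAMS else value


@dataclass(frozen=True)
class AgentParams:
    """One subject-condition parameter set for a given model.

    Fields irrelevant to ``model_id`` are ignored (M1 has no stickiness term;
    M2 uses the single rate ``alpha_reinf`` for both outcomes).
    ``initial_value`` is the common starting value of all three stimuli,
    midway between the reward (1) and punishment (0) outcomes.
    """

    model_id: str
    alpha_rew: Optional[float] = None
    alpha_pun: Optional[float] = None
    alpha_reinf: Optional[float] = None
    tau_reinf: float = 0.0
    tau_stim: Optional[float] = None
    initial_value: float = 0.5

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAMS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        for name in MODEL_PARAMS[self.model_id]:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{self.model_id} requires parameter {name!r}")
            if name in LEARNING_RATE_PARAMS and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if not 0.0 <= self.initial_value <= 1.0:
            raise ValueError("initial_value must lie in [0, 1]")

    def learning_rate(self, outcome: int) -> float:
        """Learning rate applied to an outcome (1 reward, 0 punishment)."""
        if self.model_id == "M2":
            return self.alpha_reinf
        return self.alpha_rew if outcome == 1 else self.alpha_pun

    @property
    def stickiness(self) -> float:
        """Stickiness weight; zero for M1, which has no stickiness term."""
        if self.model_id == "M1":
            return 0.0
        return self.tau_stim

    @classmethod
    def from_dict(cls, model_id: str, values: Mapping[str, float], **kwargs) -> "AgentParams":
        relevant = {k: values[k] for k in MODEL_PARAMS[model_id]}
        return cls(model_id=model_id, **relevant, **kwargs)


@dataclass(frozen=True)
class AgentState:
    """Stimulus values and the previous choice of a running agent."""

    values: np.ndarray
    prev_choice: Optional[str] = None

    @classmethod
    def initial(cls, params: AgentParams) -> "AgentState":
        return cls(values=np.full(len(STIMULI), params.initial_value), prev_choice=None)


def update_values(
    state: AgentState, choice: str, outcome: int, params: AgentParams
) -> AgentState:
    """Rescorla–Wagner update of the chosen stimulus' value.

    Only the chosen stimulus changes, by ``alpha * (R - V)`` where the rate
    depends on the outcome valence (M1/M3) or is shared (M2).
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    idx = STIMULI.index(choice)
    alpha = params.learning_rate(outcome)
    values = state.values.copy()
    values[idx] += alpha * (outcome - values[idx])
    return AgentState(values=values, prev_choice=choice)


def action_probabilities(state: AgentState, params: AgentParams) -> np.ndarray:
    """Softmax choice probabilities over the three stimuli.

    ``Q_i = tau_reinf * V_i + tau_stim * 1[i == previous choice]``; the
    stickiness indicator is zero for every stimulus on the first trial.
    """
    q = params.tau_reinf * state.values
    if state.prev_choice is not None and params.stickiness != 0.0:
        q = q.copy()
        q[STIMULI.index(state.prev_choice)] += params.stickiness
    return softmax(q)


def simulate_session(
    params: AgentParams,
    config: TaskConfig = TaskConfig(),
    rng: Union[int, np.random.Generator] = 0,
    subject: str = "sim",
    condition: str = "none",
    return_trace: bool = False,
):
    """Simulate one complete session of an agent on the task.

    Choices are sampled from the model's softmax probabilities; feedback is
    sampled by the task engine given the (lazily assigned) stimulus roles.
    Deterministic given an integer seed or a prepared generator.

    Returns the list of :class:`TrialRecord`; with ``return_trace=True`` also
    returns a dict of per-trial values, choice probabilities and indices used
    by simulator/scorer consistency checks.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    state = AgentState.initial(params)
    assignment = RoleAssignment()
    records: List[TrialRecord] = []
    trace = {"values": [], "probs": []} if return_trace else None
    for trial in range(1, config.n_total + 1):
        phase = config.phase_of(trial)
        probs = action_probabilities(state, params)
        choice = STIMULI[rng.choice(len(STIMULI), p=probs)]
        assignment.observe_choice(choice)
        acq_role = assignment.role_of(choice)
        outcome = sample_outcome(acq_role, phase, trial, config, rng)
        if return_trace:
            trace["values"].append(state.values.copy())
            trace["probs"].append(probs)
        records.append(
            TrialRecord(
                subject=subject,
                condition=condition,
                trial=trial,
                phase=phase,
                choice=choice,
                outcome=outcome,
                chosen_role=assignment.current_role(choice, phase),
            )
        )
        state = update_values(state, choice, outcome, params)
    assignment.finalize()
    if return_trace:
        trace = {k: np.asarray(v) for k, v in trace.items()}
        return records, trace
    return records


@dataclass(frozen=True)
class PopulationSpec:
    """Population structure of a synthetic two-condition cohort.

    ``condition_means`` maps condition label -> parameter -> natural-scale
    group mean.  One offset per subject and parameter is drawn from
    ``N(0, subject_sd)`` on the unconstrained scale and added to the
    unconstrained condition mean in *both* conditions, matching the
    within-subject construction of the hierarchical model.
    """

    n_subjects: int = 19
    condition_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_GROUP_MEANS.items()}
    )
    subject_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBJECT_SD)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if any(sd < 0 for sd in self.subject_sd.values()):
            raise ValueError("subject_sd must be >= 0")
        for cond, means in self.condition_means.items():
            for p, v in means.items():
                if p in LEARNING_RATE_PARAMS and not 0.0 < v < 1.0:
                    raise ValueError(
                        f"condition {cond!r}: learning rate {p}={v} outside (0, 1)"
                    )

    @property
    def conditions(self) -> Tuple[str, ...]:
        return tuple(self.condition_means)


def simulate_cohort(
    spec: PopulationSpec = PopulationSpec(),
    config: TaskConfig = TaskConfig(),
    model_id: str = "M3",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a whole cohort; returns (trial data, ground-truth parameters).

    The trial table is tidy (one row per trial, all subjects and conditions
    stacked); the truth table has one row per subject x condition x parameter
    with the exact generating natural-scale value, so that recovery analyses
    never re-derive it.
    """
    params_needed = MODEL_PARAMS[model_id]
    rng = np.random.default_rng(spec.seed)
    offsets = {p: rng.normal(0.0, spec.subject_sd[p], spec.n_subjects)
               for p in params_needed}
    width = len(str(spec.n_subjects))
    frames: List[TrialRecord] = []
    truth_rows = []
    for s in range(spec.n_subjects):
        sid = f"s{s + 1:0{width}d}"
        for cond in spec.conditions:
            natural = {}
            for p in params_needed:
                u = to_unconstrained(p, spec.condition_means[cond][p]) + offsets[p][s]
                natural[p] = float(to_natural(p, u))
                truth_rows.append(
                    {"subject": sid, "condition": cond, "parameter": p,
                     "value": natural[p]}
                )
            agent = AgentParams.from_dict(model_id, natural)
            frames.extend(
                simulate_session(agent, config, rng, subject=sid, condition=cond)
            )
    from .io import records_to_frame  # local import to avoid a cycle

    return records_to_frame(frames), pd.DataFrame(truth_rows)
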