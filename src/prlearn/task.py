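"""Three-stimulus probabilistic reversal learning task.

On each trial the participant (or simulated agent) chooses one of three
stimuli.  During the acquisition phase one stimulus yields positive feedback
on 75% of trials ("rich"), one on 50% ("neutral") and one on 25% ("lean").
Which physical stimulus plays which role is determined by the participant's
own early choices: the first stimulus ever selected becomes the rich one,
the second distinct stimulus selected becomes the lean one, and the remaining
stimulus is neutral by elimination.  After the acquisition phase the rich and
lean contingencies swap (reversal); the neutral stimulus is unaffected.  The
very first choice of a session is always rewarded.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

#: Canonical stimulus identifiers for the three on-screen stimuli.
STIMULI: Tuple[str, str, str] = ("A", "B", "C")


class Role(str, enum.Enum):
    """Contingency role of a stimulus during the acquisition phase."""

    RICH = "RICH"
    NEUTRAL = "NEUTRAL"
    LEAN = "LEAN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Phase(str, enum.Enum):
    """Task phase: initial learning or post-reversal."""

    ACQUISITION = "ACQUISITION"
    REVERSAL = "REVERSAL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class MalformedSessionError(ValueError):
    """A session violates the task contract (e.g. unassigned stimulus role)."""


@dataclass(frozen=True)
class TaskConfig:
    """Task structure and feedback contingencies.

    Parameters
    ----------
    n_acquisition, n_reversal
        Number of trials in each phase (40 + 40 by default).
    p_rich, p_neutral, p_lean
        Probability of positive feedback for the rich / neutral / lean
        stimulus during acquisition.  At reversal the rich and lean
        probabilities swap; the neutral probability is unchanged.
    force_first_reward
        If true, the choice on trial 1 is always rewarded regardless of the
        chosen stimulus' contingency.
    """

    n_acquisition: int = 40
    n_reversal: int = 40
    p_rich: float = 0.75
    p_neutral: float = 0.50
    p_lean: float = 0.25
    force_first_reward: bool = True

    def __post_init__(self) -> None:
        if self.n_acquisition < 1 or self.n_reversal < 1:
            raise ValueError("phase trial counts must be >= 1")
        for name in ("p_rich", "p_neutral", "p_lean"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not (self.p_rich > self.p_neutral > self.p_lean):
            raise ValueError("require p_rich > p_neutral > p_lean")

    @property
    def n_total(self) -> int:
        return self.n_acquisition + self.n_reversal

    def phase_of(self, trial: int) -> Phase:
        """Phase of a 1-based trial index."""
        if not 1 <= trial <= self.n_total:
            raise ValueError(f"trial {trial} outside [1, {self.n_total}]")
        return Phase.ACQUISITION if trial <= self.n_acquisition else Phase.REVERSAL


@dataclass(frozen=True)
class TrialRecord:
    """One observed or simulated trial.

    ``chosen_role`` is the role of the chosen stimulus under the contingencies
    in force on that trial, i.e. after the reversal the stimulus that was
    initially rich is recorded as LEAN (it is now the mostly-punished one).
    ``outcome`` is 1 for positive and 0 for negative feedback.
    """

    subject: str
    condition: str
    trial: int
    phase: Phase
    choice: str
    outcome: int
    chosen_role: Role


class RoleAssignment:
    """Lazy choice-order-dependent assignment of roles to stimuli.

    The first stimulus chosen becomes RICH, the second distinct stimulus
    chosen becomes LEAN, and as soon as two roles are fixed the remaining
    stimulus is NEUTRAL by elimination.  Observing an already-assigned
    stimulus never changes the assignment.
    """

    def __init__(self, stimuli: Tuple[str, ...] = STIMULI) -> None:
        if len(stimuli) != 3 or len(set(stimuli)) != 3:
            raise ValueError("exactly three distinct stimuli required")
        self.stimuli = tuple(stimuli)
        self._roles: Dict[str, Role] = {}

    def observe_choice(self, choice: str) -> "RoleAssignment":
        """Update the assignment for a choice; idempotent on assigned stimuli."""
        if choice not in self.stimuli:
            raise ValueError(f"unknown stimulus {choice!r}")
        if choice in self._roles:
            return self
        if not self._roles:
            self._roles[choice] = Role.RICH
        elif len(self._roles) == 1:
            self._roles[choice] = Role.LEAN
            (remaining,) = [s for s in self.stimuli if s not in self._roles]
            self._roles[remaining] = Role.NEUTRAL
        return self

    def finalize(self) -> "RoleAssignment":
        """Assign NEUTRAL to any still-unassigned stimulus at session end.

        Only relevant when fewer than two distinct stimuli were ever chosen.
        """
        if len(self._roles) == 1:
            for s in self.stimuli:
                self._roles.setdefault(s, Role.NEUTRAL)
        return self

    @property
    def complete(self) -> bool:
        return len(self._roles) == 3

    def role_of(self, stimulus: str) -> Role:
        """Acquisition-phase role of a stimulus; raises if not yet assigned."""
        try:
            return self._roles[stimulus]
        except KeyError:
            raise MalformedSessionError(
                f"stimulus {stimulus!r} has no assigned role"
            ) from None

    def current_role(self, stimulus: str, phase: Phase) -> Role:
        """Role under the contingencies in force during ``phase``.

        In the reversal phase the initially rich stimulus plays the LEAN role
        and vice versa; NEUTRAL is unchanged.
        """
        role = self.role_of(stimulus)
        if phase is Phase.REVERSAL:
            if role is Role.RICH:
                return Role.LEAN
            if role is Role.LEAN:
                return Role.RICH
        return role

    def as_dict(self) -> Dict[str, Role]:
        return dict(self._roles)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        inner = ", ".join(f"{s}:{r.value}" for s, r in self._roles.items())
        return f"RoleAssignment({inner})"


def assign_role_on_first_choice(assignment: RoleAssignment, choice: str) -> RoleAssignment:
    """Functional alias for :meth:`RoleAssignment.observe_choice`."""
    return assignment.observe_choice(choice)


def current_reward_probability(
    role: Optional[Role], phase: Phase, config: TaskConfig
) -> float:
    """Probability of positive feedback for a stimulus with acquisition-phase
    ``role`` during ``phase``.

    Reversal swaps the rich and lean probabilities only.
    """
    if role is None:
        raise MalformedSessionError("reward probability requested for unassigned role")
    role = Role(role)
    phase = Phase(phase)
    if phase is Phase.ACQUISITION:
        table = {Role.RICH: config.p_rich, Role.NEUTRAL: config.p_neutral,
                 Role.LEAN: config.p_lean}
    else:
        table = {Role.RICH: config.p_lean, Role.NEUTRAL: config.p_neutral,
                 Role.LEAN: config.p_rich}
    return table[role]


def sample_outcome(
    role: Role,
    phase: Phase,
    trial: int,
    config: TaskConfig,
    rng: np.random.Generator,
) -> int:
    """Sample feedback (1 positive, 0 negative) for a choice.

    Feedback is Bernoulli with the role's current reward probability, except
    that trial 1 is always rewarded when ``config.force_first_reward`` is set.
    """
    if trial == 1 and config.force_first_reward:
        return 1
    p = current_reward_probability(role, phase, config)
    return int(rng.random() < p)
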