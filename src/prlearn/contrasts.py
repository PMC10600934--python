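"""Posterior condition contrasts and highest-posterior-density intervals.

A condition effect is summarised by the per-draw difference of the two
conditions' group-level quantities (e.g. drug minus placebo learning rate,
computed for every posterior simulation run) and its shortest credible
interval.  An effect "excludes zero" at mass m when 0 lies outside the m-HDI
of the difference draws.  Differences are taken on the natural scale, the
scale on which group means are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

DEFAULT_MASSES: Tuple[float, ...] = (0.90, 0.95, 0.99, 0.999)


def hdi(samples: np.ndarray, mass: float = 0.95) -> Tuple[float, float]:
    """Highest-density interval: the shortest contiguous interval containing
    ``ceil(mass * n)`` of the sorted samples.

    Ties between equally short windows are broken toward the lowest start
    index, making the result deterministic.  Requires at least 100 samples.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HDI, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: lowest start
    return float(x[i]), float(x[i + k - 1])


@dataclass(frozen=True)
class ContrastResult:
    """Posterior difference draws with HDIs at several masses.

    ``hdis`` maps mass -> (lower, upper); ``excludes_zero`` maps mass -> flag.
    """

    draws: np.ndarray
    hdis: Dict[float, Tuple[float, float]]
    excludes_zero: Dict[float, bool]

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    def hdi(self, mass: float) -> Tuple[float, float]:
        return self.hdis[mass]


def _summarise(diff: np.ndarray, masses: Sequence[float]) -> ContrastResult:
    hdis = {m: hdi(diff, m) for m in masses}
    excludes = {m: not (lo <= 0.0 <= hi) for m, (lo, hi) in hdis.items()}
    return ContrastResult(draws=diff, hdis=hdis, excludes_zero=excludes)


def drug_contrast(
    draws_a: np.ndarray,
    draws_b: np.ndarray,
    masses: Sequence[float] = DEFAULT_MASSES,
) -> ContrastResult:
    """Condition contrast: per-draw difference (A minus B) with HDIs.

    The two draw vectors must be aligned by simulation run (same chain and
    draw index) and of equal length.
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"mismatched draw counts: {a.size} vs {b.size}")
    return _summarise(a - b, masses)


def difference_of_differences(
    rew_a: np.ndarray,
    rew_b: np.ndarray,
    pun_a: np.ndarray,
    pun_b: np.ndarray,
    masses: Sequence[float] = DEFAULT_MASSES,
) -> ContrastResult:
    """Difference-of-differences score for the two learning rates.

    Per draw: ``(alpha_rew_A - alpha_rew_B) - (alpha_pun_A - alpha_pun_B)``,
    positive when condition A raises the reward rate more than the punishment
    rate.  All four aligned draw vectors must have equal length.
    """
    arrays = [np.asarray(v, dtype=float).ravel() for v in (rew_a, rew_b, pun_a, pun_b)]
    sizes = {a.size for a in arrays}
    if len(sizes) != 1:
        raise ValueError(f"mismatched draw counts: {sorted(sizes)}")
    ra, rb, pa, pb = arrays
    return _summarise((ra - rb) - (pa - pb), masses)


def condition_contrasts(posterior, masses: Sequence[float] = DEFAULT_MASSES):
    """All natural-scale condition contrasts of a fitted posterior.

    Returns a dict mapping parameter name -> :class:`ContrastResult` for
    (first condition minus second condition), plus, when both learning rates
    are present, the ``"difference_of_differences"`` entry.
    """
    c0, c1 = posterior.conditions
    out = {}
    for p in posterior.layout.params:
        out[p] = drug_contrast(
            posterior.group_mean_draws(p, c0).ravel(),
            posterior.group_mean_draws(p, c1).ravel(),
            masses,
        )
    if {"alpha_rew", "alpha_pun"} <= set(posterior.layout.params):
        out["difference_of_differences"] = difference_of_differences(
            posterior.group_mean_draws("alpha_rew", c0).ravel(),
            posterior.group_mean_draws("alpha_rew", c1).ravel(),
            posterior.group_mean_draws("alpha_pun", c0).ravel(),
            posterior.group_mean_draws("alpha_pun", c1).ravel(),
            masses,
        )
    return out
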