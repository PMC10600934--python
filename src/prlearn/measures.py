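"""Classical (model-free) behavioural measures of reversal-learning sessions.

* Correct-choice counts per phase ("correct" = the stimulus that is rich
  under the contingencies currently in force).
* Win-stay and lose-stay probabilities: the proportion of rewarded
  (respectively punished) trials with a successor on which the same choice
  was repeated.  With three options the chance stay rate is 1/3, not 1/2.
* Perseverative errors: choices of the previously rich stimulus during the
  reversal phase occurring in runs of two or more consecutive such choices;
  the first reversal trial is excluded because behaviour cannot yet have
  been shaped by the new contingencies.
* The acquisition-perseveration coupling regression: OLS of reversal-phase
  perseverative errors on acquisition correct counts, per condition and on
  within-subject (condition A minus condition B) difference scores.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import Phase, Role


def _session_frame(session: pd.DataFrame) -> pd.DataFrame:
    if isinstance(session, pd.DataFrame):
        return session.sort_values("trial").reset_index(drop=True)
    from .io import records_to_frame

    return records_to_frame(list(session))


def win_lose_stay(session) -> Tuple[float, float]:
    """Win-stay and lose-stay probabilities of one session.

    The last trial has no successor and is excluded from both denominators;
    the two denominators therefore partition the first n-1 trials.  A zero
    denominator yields ``nan`` (undefined, distinct from a zero stay rate).
    """
    df = _session_frame(session)
    choices = df["choice"].to_numpy()
    outcomes = df["outcome"].to_numpy(dtype=int)
    stay = choices[1:] == choices[:-1]
    wins = outcomes[:-1] == 1
    losses = ~wins
    win_stay = float(stay[wins].mean()) if wins.any() else float("nan")
    lose_stay = float(stay[losses].mean()) if losses.any() else float("nan")
    return win_stay, lose_stay


def _previously_rich(df: pd.DataFrame) -> str:
    """The stimulus that was rich during acquisition.

    By task construction this is the first stimulus chosen in the session;
    cross-checked against the recorded acquisition-phase role annotations
    when present.
    """
    acq = df[df["phase"] == Phase.ACQUISITION.value]
    if acq.empty:
        raise ValueError("session has no acquisition phase; cannot derive "
                         "the previously rich stimulus")
    rich_rows = acq[acq["chosen_role"] == Role.RICH.value]
    if not rich_rows.empty:
        stimuli = rich_rows["choice"].unique()
        if len(stimuli) > 1:
            raise ValueError(f"inconsistent RICH annotations: {sorted(stimuli)}")
        return str(stimuli[0])
    return str(acq.sort_values("trial")["choice"].iloc[0])


def perseverative_errors(
    session,
    previously_rich: Optional[str] = None,
    cumulative: bool = False,
) -> int:
    """Count perseverative errors in the reversal phase.

    Scans reversal-phase choices, excluding the first reversal trial, for
    choices of the previously rich (now mostly punished) stimulus.  Under the
    default run-based rule, only choices inside maximal runs of two or more
    consecutive such choices count, and every choice inside a qualifying run
    counts.  With ``cumulative=True`` the alternative reading is used: all
    such choices count provided at least two occurred anywhere in the phase.
    """
    df = _session_frame(session)
    rev = df[df["phase"] == Phase.REVERSAL.value].sort_values("trial")
    if rev.empty:
        raise ValueError("session has no reversal phase")
    if previously_rich is None:
        previously_rich = _previously_rich(df)
    hits = (rev["choice"].to_numpy()[1:] == previously_rich)  # drop 1st reversal trial
    if cumulative:
        total = int(hits.sum())
        return total if total >= 2 else 0
    count = 0
    run = 0
    for h in hits:
        if h:
            run += 1
        else:
            if run >= 2:
                count += run
            run = 0
    if run >= 2:
        count += run
    return count


def session_measures(session, cumulative: bool = False) -> Dict[str, float]:
    """All raw measures of one session as a flat dict."""
    df = _session_frame(session)
    correct = df["chosen_role"] == Role.RICH.value
    acq = df["phase"] == Phase.ACQUISITION.value
    ws, ls = win_lose_stay(df)
    return {
        "acq_correct": int((correct & acq).sum()),
        "rev_correct": int((correct & ~acq).sum()),
        "win_stay": ws,
        "lose_stay": ls,
        "perseverative_errors": perseverative_errors(df, cumulative=cumulative),
    }


def cohort_measures(data: pd.DataFrame, cumulative: bool = False) -> pd.DataFrame:
    """Tidy per-session measures: subject, condition, measure, value."""
    rows = []
    for (subject, condition), session in data.groupby(
        ["subject", "condition"], sort=True
    ):
        for measure, value in session_measures(session, cumulative).items():
            rows.append({"subject": subject, "condition": condition,
                         "measure": measure, "value": value})
    return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: regression slope undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.pvalues[1])


def coupling_regression(
    table: pd.DataFrame,
    conditions: Optional[Tuple[str, str]] = None,
) -> Dict[str, Dict[str, float]]:
    """Acquisition-perseveration coupling regressions.

    ``table`` has one row per subject x condition with columns ``subject``,
    ``condition``, ``acq_correct`` and ``perseverative_errors`` (the wide
    form of :func:`cohort_measures` output).  Returns, per condition, the OLS
    slope and p-value of perseverative errors on acquisition correct counts,
    plus the same regression on within-subject difference scores
    (first condition minus second).
    """
    if conditions is None:
        conditions = tuple(sorted(table["condition"].unique()))
    if len(conditions) != 2:
        raise ValueError(f"expected two conditions, got {conditions}")
    out: Dict[str, Dict[str, float]] = {}
    for cond in conditions:
        sub = table[table["condition"] == cond].sort_values("subject")
        if len(sub) < 3:
            raise ValueError(f"need >= 3 subjects per condition, got {len(sub)}")
        slope, p = _ols(sub["acq_correct"].to_numpy(dtype=float),
                        sub["perseverative_errors"].to_numpy(dtype=float))
        out[cond] = {"slope": slope, "p_value": p, "n": int(len(sub))}
    wide_a = table[table["condition"] == conditions[0]].set_index("subject")
    wide_b = table[table["condition"] == conditions[1]].set_index("subject")
    common = wide_a.index.intersection(wide_b.index)
    dx = (wide_a.loc[common, "acq_correct"] - wide_b.loc[common, "acq_correct"])
    dy = (wide_a.loc[common, "perseverative_errors"]
          - wide_b.loc[common, "perseverative_errors"])
    slope, p = _ols(dx.to_numpy(dtype=float), dy.to_numpy(dtype=float))
    out["difference"] = {"slope": slope, "p_value": p, "n": int(len(common))}
    return out
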