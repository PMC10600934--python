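"""Reading, writing and validating trial-level session data.

The on-disk format is a plain CSV with one row per trial and columns
``subject, condition, trial, phase, choice, outcome, chosen_role``; one file
may hold any number of subjects and conditions.  Files are written
canonically (fixed column order, UTF-8, Unix newlines, 9-significant-digit
floats) so that write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple, Union

import pandas as pd
import yaml

from .task import STIMULI, Phase, Role, TaskConfig, TrialRecord

COLUMNS = ["subject", "condition", "trial", "phase", "choice", "outcome",
           "chosen_role"]

STIMULUS_INDEX: Dict[str, int] = {s: i for i, s in enumerate(STIMULI)}

_PHASES = {p.value for p in Phase}
_ROLES = {r.value for r in Role}


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Tidy DataFrame from trial records, in canonical column order."""
    return pd.DataFrame(
        [
            {
                "subject": r.subject,
                "condition": r.condition,
                "trial": r.trial,
                "phase": Phase(r.phase).value,
                "choice": r.choice,
                "outcome": r.outcome,
                "chosen_role": Role(r.chosen_role).value,
            }
            for r in records
        ],
        columns=COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> List[TrialRecord]:
    return [
        TrialRecord(
            subject=row.subject,
            condition=row.condition,
            trial=int(row.trial),
            phase=Phase(row.phase),
            choice=row.choice,
            outcome=int(row.outcome),
            chosen_role=Role(row.chosen_role),
        )
        for row in df.itertuples(index=False)
    ]


def validate_sessions(df: pd.DataFrame) -> None:
    """Validate a tidy trial table; raises descriptive errors naming rows.

    Row numbers refer to 1-based data rows (header excluded), matching the
    on-disk CSV layout when the frame was read from a file.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    outcomes = df["outcome"]
    bad = ~outcomes.isin([0, 1])
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise ValueError(
            f"row {row}: outcome {outcomes[bad].iloc[0]!r} not in {{0, 1}}"
        )
    bad = ~df["phase"].isin(_PHASES)
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise ValueError(f"row {row}: unknown phase {df['phase'][bad].iloc[0]!r}")
    bad = ~df["choice"].isin(STIMULI)
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise ValueError(f"row {row}: unknown stimulus {df['choice'][bad].iloc[0]!r}")
    bad = ~df["chosen_role"].isin(_ROLES)
    if bad.any():
        row = int(df.index[bad][0]) + 1
        raise ValueError(f"row {row}: unknown role {df['chosen_role'][bad].iloc[0]!r}")
    for (subject, condition), g in df.groupby(["subject", "condition"], sort=False):
        trials = g.sort_values("trial")["trial"].to_numpy()
        expected = range(1, len(trials) + 1)
        if list(trials) != list(expected):
            raise ValueError(
                f"subject {subject!r}, condition {condition!r}: trial indices "
                f"are not consecutive from 1 (got {trials[:5].tolist()}...)"
            )


def read_sessions(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a session CSV."""
    df = pd.read_csv(path, dtype={"subject": str, "condition": str})
    df.index = pd.RangeIndex(len(df))
    validate_sessions(df)
    return df[COLUMNS]


def write_sessions(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a validated session table in canonical form."""
    validate_sessions(df)
    df[COLUMNS].to_csv(path, index=False, lineterminator="\n",
                       float_format="%.9g", encoding="utf-8")


def iter_sessions(
    df: pd.DataFrame,
) -> Iterator[Tuple[Tuple[str, str], pd.DataFrame]]:
    """Iterate (subject, condition) cells in sorted order, trials ascending."""
    for key, g in df.groupby(["subject", "condition"], sort=True):
        yield key, g.sort_values("trial").reset_index(drop=True)


def write_truth(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    truth.to_csv(path, index=False, lineterminator="\n", float_format="%.9g",
                 encoding="utf-8")


def read_truth(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject": str, "condition": str})


def load_task_config(path: Union[str, Path]) -> TaskConfig:
    """Load a flat YAML key-value file mirroring :class:`TaskConfig` fields."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in TaskConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown task config keys: {sorted(unknown)}")
    return TaskConfig(**raw)
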