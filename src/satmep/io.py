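"""Interchange formats: CSV tables, JSON configs, and run logs.

CSV is the interchange format throughout (there is no domain standard
for MEP tables).  Schedules serialize one row per trial with the
15-character jump string; behavior and MEP tables are plain tidy frames.
A run log is a JSON-lines file collecting, per stage, the seed, input
counts, and how many rows each exclusion rule removed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .task_model import ScheduledTrial, SessionSchedule, TokenTrial

__all__ = [
    "schedule_to_frame",
    "frame_to_schedule",
    "save_schedule",
    "load_schedule",
    "save_table",
    "load_table",
    "save_config",
    "load_config",
    "RunLog",
]

SCHEDULE_COLUMNS = ["trial", "trial_type", "correct_side", "jumps", "tms_event"]


def schedule_to_frame(schedule: SessionSchedule) -> pd.DataFrame:
    rows = [
        {
            "trial": e.index,
            "trial_type": e.trial.trial_type,
            "correct_side": e.trial.correct_side,
            "jumps": e.trial.jumps,
            "tms_event": e.tms_event,
        }
        for e in schedule
    ]
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def frame_to_schedule(df: pd.DataFrame) -> SessionSchedule:
    missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"schedule table missing column(s): {missing}")
    entries = [
        ScheduledTrial(
            int(r.trial),
            TokenTrial(r.trial_type, r.correct_side, r.jumps),
            r.tms_event,
        )
        for r in df.itertuples()
    ]
    return SessionSchedule(entries)


def save_schedule(schedule: SessionSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def load_schedule(path) -> SessionSchedule:
    return frame_to_schedule(pd.read_csv(path, dtype={"jumps": str}))


def save_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_table(path, required_columns=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise KeyError(f"{path}: missing column(s): {missing}")
    return df


def save_config(config, path) -> None:
    """Serialize a dataclass config (tuple-keyed dicts flattened) to JSON."""
    d = dataclasses.asdict(config)
    for key, value in d.items():
        if isinstance(value, dict) and any(
            isinstance(k, tuple) for k in value
        ):
            d[key] = {"|".join(map(str, k)): v for k, v in value.items()}
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def load_config(cls, path):
    with open(path) as fh:
        d = json.load(fh)
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in d.items():
        if key in fields and isinstance(value, dict) and any("|" in k for k in value):
            d[key] = {tuple(k.split("|")): v for k, v in value.items()}
    return cls(**{k: v for k, v in d.items() if k in fields})


class RunLog:
    """Append-only JSON-lines log of pipeline stages and exclusion counts."""

    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, stage: str, **fields) -> None:
        with open(self.path, "a") as fh:
            fh.write(json.dumps({"stage": stage, **fields}) + "\n")

    def entries(self) -> list[dict]:
        if not self.path.exists():
            return []
        with open(self.path) as fh:
            return [json.loads(line) for line in fh if line.strip()]
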