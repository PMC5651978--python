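"""CSV dialects for trajectory tables and exit-event lists.

The trajectory dialect matches what video-tracking exports provide: one row
per (trial, frame, agent) with positions in meters; simulator output adds
orientation, velocity and status columns.  Readers validate structure and
report the offending line number on malformed input.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ParseError

__all__ = [
    "CORE_TRACK_COLUMNS",
    "read_tracks",
    "write_tracks",
    "read_events",
    "write_events",
]

CORE_TRACK_COLUMNS = ["trial_id", "frame", "time_s", "agent_id", "x_m", "y_m"]
EVENT_COLUMNS = ["trial_id", "agent_id", "exit_time_s"]


def write_tracks(tracks: pd.DataFrame, path) -> None:
    missing = [c for c in CORE_TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table lacks columns {missing}")
    tracks.to_csv(path, index=False)


def read_tracks(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a trajectory CSV, optionally renaming external column names to the
    canonical ones via ``column_map`` (external -> canonical).

    Raises :class:`ParseError` (with a line number where applicable) for a
    missing header, missing columns, duplicate (trial, frame, agent) rows or
    non-monotone per-agent times.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: no header")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no header") from None
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CORE_TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header lacks required columns {missing}")

    dup = df.duplicated(subset=["trial_id", "frame", "agent_id"])
    if dup.any():
        line = int(df.index[dup][0]) + 2  # header is line 1
        raise ParseError(f"{path}: duplicate (trial, frame, agent) row at line {line}")

    order = df.sort_values(["trial_id", "agent_id", "frame"], kind="stable")
    dt = order.groupby(["trial_id", "agent_id"], sort=False)["time_s"].diff()
    bad = dt <= 0.0
    if bad.any():
        line = int(order.index[bad][0]) + 2
        raise ParseError(f"{path}: non-monotone time for an agent at line {line}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns {missing}")
    events.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: no header")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: no header") from None
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header lacks required columns {missing}")
    dup = df.duplicated(subset=["trial_id", "agent_id"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: duplicate exit event at line {line}")
    return df
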