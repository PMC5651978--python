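"""Evacuation measurement layer: speeds, evacuation times and dispersion.

Definitions (N agents per trial, C cases per angle, E angles):

* ``V_t``      — per-agent mean speed: the average of instantaneous speeds
  (finite differences of position over the frame interval) from the agent's
  start to its exit.
* ``V_tN``     — per-trial mean of the N per-agent means.
* ``V_total``  — per-angle mean of ``V_tN`` over the C cases.
* ``T_evc``    — per-trial total evacuation time: last exit minus first start.
* ``t_evc``    — per-trial mean individual evacuation time (exit minus start).
* ``S``        — per-trial standard deviation (population, divisor N) of the
  per-agent mean speeds about ``V_tN``; averaged over the C cases it gives the
  per-angle dispersion ``S_mice``, and the mean of ``S_mice`` over the E
  angles is the uniform dispersion ``S_uni``.

Instantaneous speeds use central differences at interior frames and one-sided
differences at the ends, since tracking exports carry positions rather than
velocities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricsResult",
    "agent_mean_speed",
    "agent_mean_speeds",
    "trial_table",
    "aggregate",
    "velocity_dispersion",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricsResult:
    """Per-agent, per-trial and per-angle evacuation metrics.

    ``agent_means`` has columns (trial_id, agent_id, v_mean_mps); ``trials``
    (trial_id, n_agents, v_tn_mps, s_v_mps, t_evc_s, T_evc_s);
    ``angles`` (angle_deg, v_total_mps, T_evc_s, t_evc_s, s_mice_mps);
    ``s_uni_mps`` is the across-angle mean of ``s_mice_mps``.
    """

    agent_means: pd.DataFrame
    trials: pd.DataFrame
    angles: pd.DataFrame
    s_uni_mps: float


def agent_mean_speed(times, xs, ys) -> float:
    """Mean instantaneous speed of one agent track.

    Central differences interiorly, one-sided at the ends; requires at least
    two samples between the agent's start and exit.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if t.size < 2:
        raise ValueError("agent mean speed needs at least two samples")
    vx = np.gradient(x, t)
    vy = np.gradient(y, t)
    return float(np.mean(np.hypot(vx, vy)))


def agent_mean_speeds(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-agent mean speeds for every (trial, agent) in a track table."""
    rows = []
    for (trial, agent), grp in tracks.groupby(["trial_id", "agent_id"], sort=True):
        g = grp.sort_values("frame", kind="stable")
        rows.append(
            (trial, agent, agent_mean_speed(g["time_s"], g["x_m"], g["y_m"]))
        )
    return pd.DataFrame(rows, columns=["trial_id", "agent_id", "v_mean_mps"])


def trial_table(
    tracks: pd.DataFrame, events: pd.DataFrame, ddof: int = 0
) -> pd.DataFrame:
    """Per-trial aggregates from tracks plus exit events.

    An agent's start is the time of its first recorded frame; its exit comes
    from the event list.  Every trial must have at least one exit event and
    at least two agents (the dispersion is undefined otherwise).  ``ddof=0``
    is the population standard deviation convention.
    """
    if len(events) == 0:
        raise ValueError("no exit events")
    means = agent_mean_speeds(tracks)
    starts = (
        tracks.groupby(["trial_id", "agent_id"])["time_s"].min().rename("start_s")
    )
    rows = []
    for trial, ev in events.groupby("trial_id", sort=True):
        if len(ev) == 0:
            raise ValueError(f"trial {trial}: no exit events")
        m = means[means.trial_id == trial]
        if len(m) < 2:
            raise ValueError(f"trial {trial}: dispersion needs >= 2 agents")
        st = starts.loc[trial]
        durations = ev.set_index("agent_id")["exit_time_s"] - st.reindex(
            ev["agent_id"]
        )
        v = m["v_mean_mps"].to_numpy()
        rows.append(
            (
                trial,
                len(m),
                float(v.mean()),
                float(v.std(ddof=ddof)),
                float(durations.mean()),
                float(ev["exit_time_s"].max() - st.min()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["trial_id", "n_agents", "v_tn_mps", "s_v_mps", "t_evc_s", "T_evc_s"],
    )


def aggregate(trials: pd.DataFrame, trial_angles: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-angle means over cases plus the uniform dispersion.

    ``trial_angles`` maps trial_id -> angle_deg.  Returns the per-angle table
    and ``S_uni`` (the arithmetic mean of ``S_mice`` over the angles).
    """
    merged = trials.merge(trial_angles[["trial_id", "angle_deg"]], on="trial_id")
    if len(merged) != len(trials):
        raise ValueError("trial_angles does not cover every trial")
    ang = (
        merged.groupby("angle_deg")
        .agg(
            v_total_mps=("v_tn_mps", "mean"),
            T_evc_s=("T_evc_s", "mean"),
            t_evc_s=("t_evc_s", "mean"),
            s_mice_mps=("s_v_mps", "mean"),
        )
        .reset_index()
        .sort_values("angle_deg", ignore_index=True)
    )
    return ang, float(ang["s_mice_mps"].mean())


def velocity_dispersion(
    agent_means: pd.DataFrame, trial_angles: pd.DataFrame, ddof: int = 0
) -> tuple[pd.Series, float]:
    """Angle-wise speed dispersion ``S_mice`` and the uniform ``S_uni``.

    Per trial the (population) standard deviation of per-agent mean speeds
    about the trial mean; averaged over the cases of each angle; ``S_uni`` is
    the mean of the angle values.
    """
    counts = agent_means.groupby("trial_id")["agent_id"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise ValueError(f"trial {bad}: dispersion needs >= 2 agents")
    per_trial = (
        agent_means.groupby("trial_id")["v_mean_mps"]
        .agg(lambda v: v.std(ddof=ddof))
        .rename("s_v_mps")
        .reset_index()
    )
    merged = per_trial.merge(trial_angles[["trial_id", "angle_deg"]], on="trial_id")
    s_mice = merged.groupby("angle_deg")["s_v_mps"].mean()
    return s_mice, float(s_mice.mean())


def compute_metrics(
    tracks: pd.DataFrame,
    events: pd.DataFrame,
    trial_angles: pd.DataFrame,
    ddof: int = 0,
) -> MetricsResult:
    """Full measurement layer on a track table + exit events + angle labels."""
    agent_means = agent_mean_speeds(tracks)
    trials = trial_table(tracks, events, ddof=ddof)
    angles, s_uni = aggregate(trials, trial_angles)
    return MetricsResult(
        agent_means=agent_means, trials=trials, angles=angles, s_uni_mps=s_uni
    )
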