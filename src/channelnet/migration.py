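"""Per-track migration statistics: distance, displacement, velocity, straightness.

Straightness is net displacement divided by cumulative path length (D/S), 1
for perfectly directed motion and 0 for a closed loop. Tracks recorded in a
periodic domain are unwrapped before computation: any consecutive step larger
than half the domain per axis is taken as a boundary crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abm import TrajectorySet


class MalformedTrackError(ValueError):
    """Track has fewer than two points or non-increasing times."""


@dataclass
class MigrationMetrics:
    agent_id: int
    total_distance: float  # S, um
    displacement: float  # D, um
    mean_velocity: float  # S / elapsed time, um per t
    straightness: float  # D / S in [0, 1]; NaN when S == 0

    def to_dict(self) -> dict:
        return {
            "agent_id": self.agent_id,
            "total_distance": self.total_distance,
            "displacement": self.displacement,
            "mean_velocity": self.mean_velocity,
            "straightness": self.straightness,
        }


def unwrap_track(xy: np.ndarray, domain_size: float) -> np.ndarray:
    """Undo periodic wrapping: steps larger than L/2 per axis are corrected."""
    xy = np.asarray(xy, dtype=float)
    steps = np.diff(xy, axis=0)
    steps -= domain_size * np.round(steps / domain_size)
    return np.vstack([xy[:1], xy[:1] + np.cumsum(steps, axis=0)])


def track_metrics(
    positions: np.ndarray,
    times: np.ndarray,
    domain_size: float | None = None,
    agent_id: int = 0,
) -> MigrationMetrics:
    """Distance S, displacement D, mean velocity S/T and straightness D/S.

    Parameters
    ----------
    positions : (n, 2) array of um coordinates, n >= 2.
    times : strictly increasing time stamps.
    domain_size : if given, the track is periodically unwrapped first.
    """
    xy = np.asarray(positions, dtype=float)
    t = np.asarray(times, dtype=float)
    if xy.ndim != 2 or len(xy) < 2:
        raise MalformedTrackError("track needs at least two points")
    if len(t) != len(xy) or np.any(np.diff(t) <= 0):
        raise MalformedTrackError("times must be strictly increasing, one per point")
    if domain_size is not None:
        xy = unwrap_track(xy, domain_size)
    steps = np.diff(xy, axis=0)
    S = float(np.hypot(steps[:, 0], steps[:, 1]).sum())
    D = float(np.hypot(*(xy[-1] - xy[0])))
    elapsed = float(t[-1] - t[0])
    straightness = D / S if S > 0 else np.nan
    return MigrationMetrics(agent_id, S, D, S / elapsed, straightness)


def cohort_metrics(
    traj: TrajectorySet, domain_size: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-agent metrics table plus mean +/- SD summary split by role.

    Returns (per_track, summary). Summary rows cover each role present and
    an "all" row; statistics are total_distance, displacement, mean_velocity
    and straightness.
    """
    if domain_size is None and traj.config is not None:
        domain_size = traj.config.domain_size
    frames = traj.frames
    if frames.empty:
        warnings.warn("empty trajectory set; returning empty tables")
        cols = ["agent_id", "total_distance", "displacement", "mean_velocity",
                "straightness", "role"]
        return pd.DataFrame(columns=cols), pd.DataFrame()
    rows = []
    for aid, sub in frames.sort_values("frame").groupby("agent_id"):
        m = track_metrics(
            sub[["x", "y"]].to_numpy(),
            sub["time"].to_numpy(),
            domain_size=domain_size,
            agent_id=int(aid),
        )
        d = m.to_dict()
        d["role"] = sub["role"].iloc[0]
        rows.append(d)
    per_track = pd.DataFrame(rows)

    stats = ["total_distance", "displacement", "mean_velocity", "straightness"]
    groups = [("all", per_track)] + [
        (role, g) for role, g in per_track.groupby("role")
    ]
    summary_rows = []
    for name, g in groups:
        row: dict = {"role": name, "n": len(g)}
        for s in stats:
            row[f"{s}_mean"] = g[s].mean()
            row[f"{s}_sd"] = g[s].std(ddof=0)
        summary_rows.append(row)
    return per_track, pd.DataFrame(summary_rows)
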