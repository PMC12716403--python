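"""Off-lattice agent-based model of collectively migrating, channel-forming cells.

Cells are disk-like agents in a square periodic domain. Each agent carries a
position ``r_i`` and a heading ``theta_i``. Pairs of agents within a cutoff
interact through a short-range exponential force: repulsive when the disks
overlap, adhesive up to the cutoff. Motion is overdamped: the position advances
along the heading at the protrusion speed plus a mobility times the net
interaction force, while the heading relaxes toward the net-force direction and
diffuses with Gaussian rotational noise. A configurable "leader" subpopulation
gets its force scale and protrusion speed multiplied by ``leader_factor``,
modelling the mechanically hyperactive cells that initiate channel extension.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

LEADER = "leader"
FOLLOWER = "follower"


class ConfigError(ValueError):
    """An invalid simulation configuration field."""


class DegenerateContactError(ValueError):
    """Two agents share exactly the same center; force direction undefined."""


class NumericalBlowupError(FloatingPointError):
    """An agent position became non-finite (time step too large)."""

    def __init__(self, agent_id: int):
        super().__init__(f"non-finite position for agent {agent_id}; reduce dt")
        self.agent_id = agent_id


@dataclass
class ModelParams:
    """Force-law, motility and noise parameters.

    Attributes
    ----------
    f_base : float
        Interaction force scale, nN. Order of the measured ~0.9 nN bridge
        tension between channels.
    alpha : float
        Exponential decay length of the interaction force, um.
    r_cut : float
        Center-to-center interaction cutoff, um. Must reach at least contact
        (``2 * radius``).
    mobility : float
        Displacement per unit force per unit time, um / (nN * t). Absorbs
        friction with the matrix.
    align_rate : float
        Rate at which the heading relaxes toward the net-force direction, 1/t.
    heading_align : float
        Rate at which the heading relaxes toward the circular-mean heading of
        neighbors within ``r_cut``, 1/t. Models the directional consensus of
        mechanically coupled cells migrating as multicellular strands; 0
        disables the term.
    mech_gain : float
        Mechanotransduction coupling, 1/nN: the effective protrusion speed is
        ``v0 * (1 + mech_gain * min(max(|F_i| - mech_thresh, 0), mech_sat))``,
        so cells under larger interaction forces migrate faster
        (force-activated motility); 0 disables the coupling.
    mech_thresh : float
        Activation threshold of the sensed force magnitude, nN: forces below
        it do not boost motility (switch-like mechanotransduction).
    mech_sat : float
        Saturation of the sensed force magnitude in the motility coupling, nN.
    noise_eta : float
        Rotational-noise amplitude, rad / sqrt(t).
    leader_factor : float
        Multiplier (>= 1) on ``f_base`` and the protrusion speed of leaders.
    dt : float
        Integration time step, t.
    """

    f_base: float = 1.0
    alpha: float = 10.0
    r_cut: float = 30.0
    mobility: float = 1.0
    align_rate: float = 1.0
    heading_align: float = 1.0
    mech_gain: float = 10.0
    mech_thresh: float = 0.4
    mech_sat: float = 2.0
    noise_eta: float = 0.3
    leader_factor: float = 2.0
    dt: float = 0.1

    def validate(self, max_radius: float | None = None) -> None:
        if self.f_base < 0:
            raise ConfigError("f_base must be >= 0")
        if self.alpha <= 0:
            raise ConfigError("alpha must be > 0")
        if self.r_cut <= 0:
            raise ConfigError("r_cut must be > 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.noise_eta < 0:
            raise ConfigError("noise_eta must be >= 0")
        if self.leader_factor < 1:
            raise ConfigError("leader_factor must be >= 1")
        if max_radius is not None and self.r_cut < 2 * max_radius:
            raise ConfigError("r_cut must reach contact (>= 2 * max radius)")


@dataclass
class AgentState:
    """One cell: position (um), heading (rad in [-pi, pi)), radius, role, speed."""

    id: int
    position: np.ndarray
    heading: float
    radius: float = 4.0
    role: str = FOLLOWER
    speed: float = 0.02

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ConfigError("radius must be > 0")
        if self.speed < 0:
            raise ConfigError("speed must be >= 0")
        if self.role not in (LEADER, FOLLOWER):
            raise ConfigError(f"role must be '{LEADER}' or '{FOLLOWER}'")

    @property
    def is_leader(self) -> bool:
        return self.role == LEADER


@dataclass
class SimConfig:
    """Full description of one simulation run (including the seed).

    Identical configs produce byte-identical trajectories.
    """

    domain_size: float = 500.0
    boundary: str = "periodic"
    n_agents: int = 200
    leader_fraction: float = 0.0
    n_steps: int = 5000
    record_every: int = 25
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)
    agent_radius: float = 4.0
    v0: float = 0.02
    cellline_label: str = ""

    def validate(self) -> None:
        if self.domain_size <= 0:
            raise ConfigError("domain_size must be > 0")
        if self.boundary != "periodic":
            raise ConfigError("boundary must be 'periodic'")
        if self.n_agents < 1:
            raise ConfigError("n_agents must be >= 1")
        if not 0 <= self.leader_fraction <= 1:
            raise ConfigError("leader_fraction must lie in [0, 1]")
        if self.n_steps < 0:
            raise ConfigError("n_steps must be >= 0")
        if self.record_every < 1:
            raise ConfigError("record_every must be >= 1")
        if self.agent_radius <= 0:
            raise ConfigError("agent_radius must be > 0")
        if self.v0 < 0:
            raise ConfigError("v0 must be >= 0")
        self.params.validate(max_radius=self.agent_radius)
        if self.params.r_cut >= self.domain_size / 2:
            raise ConfigError("r_cut must be < domain_size / 2 (minimum image)")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = asdict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        params = d.pop("params", {})
        if not isinstance(params, ModelParams):
            params = ModelParams(**params)
        return cls(params=params, **d)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


class TrajectorySet:
    """Tidy per-agent, per-frame positions plus the generating config.

    The table has columns ``agent_id, frame, time, x, y, role``; frame indices
    are consecutive and identical across agents, and frame spacing equals
    ``record_every * dt``.
    """

    COLUMNS = ["agent_id", "frame", "time", "x", "y", "role"]

    def __init__(self, frames: pd.DataFrame, config: SimConfig | None = None):
        missing = [c for c in self.COLUMNS if c not in frames.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        self.frames = frames.reset_index(drop=True)
        self.config = config

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return 0 if self.frames.empty else int(self.frames["frame"].max()) + 1

    @property
    def agent_ids(self) -> np.ndarray:
        return np.sort(self.frames["agent_id"].unique())

    def positions_at(self, frame: int) -> np.ndarray:
        sub = self.frames[self.frames["frame"] == frame].sort_values("agent_id")
        return sub[["x", "y"]].to_numpy()

    def up_to_frame(self, frame: int) -> "TrajectorySet":
        """Truncate to frames 0..frame inclusive (for time-course analysis)."""
        return TrajectorySet(
            self.frames[self.frames["frame"] <= frame].copy(), self.config
        )

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        # %.17g round-trips float64 exactly
        self.frames.to_csv(path, index=False, float_format="%.17g")
        if isinstance(path, (str, Path)) and self.config is not None:
            Path(str(path)).with_suffix(".config.json").write_text(
                json.dumps(self.config.to_dict(), indent=1)
            )

    @classmethod
    def from_csv(cls, path: str | Path, config: SimConfig | None = None) -> "TrajectorySet":
        frames = pd.read_csv(path, float_precision="round_trip")
        frames = frames.astype(
            {"agent_id": "int64", "frame": "int64", "time": "float64",
             "x": "float64", "y": "float64"}
        )
        if config is None and isinstance(path, (str, Path)):
            sidecar = Path(str(path)).with_suffix(".config.json")
            if sidecar.exists():
                config = SimConfig.from_dict(json.loads(sidecar.read_text()))
        return cls(frames, config)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, TrajectorySet) and self.frames.equals(other.frames)


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

def min_image(delta: np.ndarray, domain_size: float) -> np.ndarray:
    """Minimum-image displacement vector(s) under periodic boundaries."""
    return delta - domain_size * np.round(delta / domain_size)


def pair_force(
    state_i: AgentState,
    state_j: AgentState,
    params: ModelParams,
    domain_size: float,
) -> np.ndarray:
    """Force (nN) exerted on agent i by agent j.

    Magnitude ``F_base_eff * exp(-|g| / alpha)`` where ``g`` is the surface
    gap ``d - (R_i + R_j)`` at minimum-image center distance ``d``. The force
    points along the center line: repulsive (from j toward i) for overlapping
    disks, adhesive (toward j) out to the cutoff, zero beyond ``d > r_cut``.
    Exactly antisymmetric under exchange of i and j. If either agent is a
    leader the force scale is multiplied by ``leader_factor``.
    """
    if state_i.id == state_j.id:
        raise ValueError("pair_force requires two distinct agents")
    if domain_size <= 0:
        raise ConfigError("domain_size must be > 0")
    delta = min_image(state_i.position - state_j.position, domain_size)
    d = float(np.hypot(*delta))
    if d == 0.0:
        raise DegenerateContactError(
            f"agents {state_i.id} and {state_j.id} have coincident centers"
        )
    if d > params.r_cut:
        return np.zeros(2)
    gap = d - (state_i.radius + state_j.radius)
    f_base = params.f_base
    if state_i.is_leader or state_j.is_leader:
        f_base *= params.leader_factor
    sign = 1.0 if gap < 0 else -1.0
    mag = sign * f_base * math.exp(-abs(gap) / params.alpha)
    return (mag / d) * delta


def find_neighbors(
    states: Sequence[AgentState], r_cut: float, domain_size: float
) -> list[list[int]]:
    """Per-agent neighbor id lists at minimum-image distance <= r_cut.

    Backed by a periodic k-d tree; contractually identical to an all-pairs
    search. Requires ``r_cut < domain_size / 2`` for minimum-image validity.
    """
    if r_cut >= domain_size / 2:
        raise ConfigError("r_cut must be < domain_size / 2 for minimum image")
    ids = [s.id for s in states]
    pos = np.array([s.position for s in states], dtype=float) % domain_size
    neighbors: dict[int, list[int]] = {i: [] for i in ids}
    if len(states) > 1:
        tree = cKDTree(pos, boxsize=domain_size)
        pairs = tree.query_pairs(r_cut, output_type="ndarray")
        for a, b in pairs:
            neighbors[ids[a]].append(ids[b])
            neighbors[ids[b]].append(ids[a])
    return [sorted(neighbors[i]) for i in ids]


def net_force(
    agent: AgentState,
    states: Sequence[AgentState],
    neighbors: Sequence[int],
    params: ModelParams,
    domain_size: float,
) -> np.ndarray:
    """Vector sum of pair forces from the given neighbor ids (nN)."""
    by_id = {s.id: s for s in states}
    total = np.zeros(2)
    for j in neighbors:
        total += pair_force(agent, by_id[j], params, domain_size)
    return total


# ---------------------------------------------------------------------------
# time stepping (array engine + AgentState wrapper)
# ---------------------------------------------------------------------------

def wrap_angle(theta):
    """Map angle(s) to [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi


def _pairwise_net_forces(
    pos: np.ndarray,
    radii: np.ndarray,
    leader_mask: np.ndarray,
    heading: np.ndarray,
    params: ModelParams,
    domain_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Net interaction force and neighbor mean heading for every agent.

    Returns ``(forces, mean_heading)`` where ``mean_heading`` is the circular
    mean of neighbor headings within ``r_cut`` (NaN for agents without
    neighbors). Coincident centers are resolved by nudging the higher-id
    agent along a seeded random unit vector by 1e-6 um (logged), then
    re-evaluating.
    """
    n = len(pos)
    forces = np.zeros((n, 2))
    hsum = np.zeros((n, 2))
    if n < 2:
        return forces, np.full(n, np.nan)
    for _attempt in range(8):
        tree = cKDTree(pos % domain_size, boxsize=domain_size)
        pairs = tree.query_pairs(params.r_cut, output_type="ndarray")
        if len(pairs) == 0:
            return forces, np.full(n, np.nan)
        # fixed order for deterministic summation
        order = np.lexsort((pairs[:, 1], pairs[:, 0]))
        pairs = pairs[order]
        i, j = pairs[:, 0], pairs[:, 1]
        delta = min_image(pos[i] - pos[j], domain_size)
        d = np.hypot(delta[:, 0], delta[:, 1])
        coincident = d == 0.0
        if coincident.any():
            bad = np.unique(j[coincident])
            logger.warning(
                "resolving %d degenerate contact(s) with random nudges", len(bad)
            )
            ang = rng.uniform(-np.pi, np.pi, size=len(bad))
            pos = pos.copy()
            pos[bad] += 1e-6 * np.column_stack([np.cos(ang), np.sin(ang)])
            continue
        gap = d - (radii[i] + radii[j])
        f_base = np.where(
            leader_mask[i] | leader_mask[j],
            params.f_base * params.leader_factor,
            params.f_base,
        )
        sign = np.where(gap < 0, 1.0, -1.0)
        mag = sign * f_base * np.exp(-np.abs(gap) / params.alpha)
        fvec = (mag / d)[:, None] * delta
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)
        hvec = np.column_stack([np.cos(heading), np.sin(heading)])
        np.add.at(hsum, i, hvec[j])
        np.add.at(hsum, j, hvec[i])
        norm = np.hypot(hsum[:, 0], hsum[:, 1])
        mean_heading = np.where(
            norm > 1e-12, np.arctan2(hsum[:, 1], hsum[:, 0]), np.nan
        )
        return forces, mean_heading
    raise DegenerateContactError("could not resolve coincident centers")


def _step_arrays(
    pos: np.ndarray,
    heading: np.ndarray,
    radii: np.ndarray,
    speeds: np.ndarray,
    leader_mask: np.ndarray,
    params: ModelParams,
    domain_size: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One synchronous overdamped update; returns (new_pos, new_heading)."""
    p = params
    forces, mean_heading = _pairwise_net_forces(
        pos, radii, leader_mask, heading, p, domain_size, rng
    )
    xi = rng.standard_normal(len(pos))
    fmag = np.hypot(forces[:, 0], forces[:, 1])
    force_angle = np.arctan2(forces[:, 1], forces[:, 0])
    align = np.where(fmag > 0, wrap_angle(force_angle - heading), 0.0)
    consensus = np.where(
        np.isnan(mean_heading), 0.0, wrap_angle(np.nan_to_num(mean_heading) - heading)
    )
    new_heading = wrap_angle(
        heading
        + p.align_rate * p.dt * align
        + p.heading_align * p.dt * consensus
        + p.noise_eta * math.sqrt(p.dt) * xi
    )
    v0_eff = np.where(leader_mask, speeds * p.leader_factor, speeds)
    if p.mech_gain > 0:
        sensed = np.minimum(np.maximum(fmag - p.mech_thresh, 0.0), p.mech_sat)
        v0_eff = v0_eff * (1.0 + p.mech_gain * sensed)
    new_pos = (
        pos
        + v0_eff[:, None] * np.column_stack([np.cos(new_heading), np.sin(new_heading)]) * p.dt
        + p.mobility * forces * p.dt
    )
    if not np.isfinite(new_pos).all():
        bad = int(np.argwhere(~np.isfinite(new_pos).all(axis=1))[0, 0])
        raise NumericalBlowupError(bad)
    return new_pos % domain_size, new_heading


def step(
    states: Sequence[AgentState],
    params: ModelParams,
    rng: np.random.Generator,
    domain_size: float,
) -> list[AgentState]:
    """Advance every agent one time step (synchronous forces, id order)."""
    states = sorted(states, key=lambda s: s.id)
    pos = np.array([s.position for s in states], dtype=float)
    heading = np.array([s.heading for s in states], dtype=float)
    radii = np.array([s.radius for s in states], dtype=float)
    speeds = np.array([s.speed for s in states], dtype=float)
    leaders = np.array([s.is_leader for s in states], dtype=bool)
    new_pos, new_heading = _step_arrays(
        pos, heading, radii, speeds, leaders, params, domain_size, rng
    )
    return [
        replace(s, position=new_pos[k], heading=float(new_heading[k]))
        for k, s in enumerate(states)
    ]


def run_simulation(config: SimConfig) -> TrajectorySet:
    """Run the full model and return the recorded trajectories.

    Agents start uniformly at random with uniform random headings; leader
    roles go to the first ``floor(leader_fraction * n)`` agents of a seeded
    shuffle. Positions are recorded at frame 0 and every ``record_every``
    steps thereafter. Deterministic given the config (including seed).
    """
    config.validate()
    L = config.domain_size
    n = config.n_agents
    p = config.params
    rng = np.random.default_rng(config.seed)
    pos = rng.uniform(0.0, L, size=(n, 2))
    heading = rng.uniform(-np.pi, np.pi, size=n)
    perm = rng.permutation(n)
    n_leaders = int(math.floor(config.leader_fraction * n))
    leader_mask = np.zeros(n, dtype=bool)
    leader_mask[perm[:n_leaders]] = True
    radii = np.full(n, config.agent_radius)
    speeds = np.full(n, config.v0)
    roles = np.where(leader_mask, LEADER, FOLLOWER)

    logger.info(
        "run %s: n=%d leaders=%d steps=%d seed=%d",
        config.config_hash(), n, n_leaders, config.n_steps, config.seed,
    )

    agent_ids = np.arange(n)
    chunks = []
    frame = 0

    def record(step_idx: int) -> None:
        nonlocal frame
        t = step_idx * p.dt
        chunks.append(
            pd.DataFrame(
                {
                    "agent_id": agent_ids,
                    "frame": frame,
                    "time": t,
                    "x": pos[:, 0],
                    "y": pos[:, 1],
                    "role": roles,
                }
            )
        )
        frame += 1

    record(0)
    for k in range(1, config.n_steps + 1):
        pos, heading = _step_arrays(
            pos, heading, radii, speeds, leader_mask, p, L, rng
        )
        if k % config.record_every == 0:
            record(k)
        if k % max(1, config.n_steps // 10) == 0:
            logger.debug("step %d / %d", k, config.n_steps)
    table = pd.concat(chunks, ignore_index=True)
    return TrajectorySet(table, config)
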