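"""Synthetic masks and tracks with analytically known ground truth.

Mask fixtures are drawn as one-pixel polyline motifs and dilated by a disk,
so the skeleton recovers the intended medial curve and the junction, branch,
segment and mesh counts are known by construction. Track fixtures carry
closed-form distance/displacement/straightness truths. These stand in for
the study's confocal channel masks, which are not needed to test the
analysis stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import line as sk_line
from skimage.morphology import dilation, disk

from .abm import TrajectorySet
from .trace import OccupancyGrid, write_grid

MASK_NAMES = ("line", "plus", "H", "ring", "theta", "grid3x3", "two_components")
TRACK_KINDS = ("straight", "loop", "L_path", "lattice_walk")


@dataclass
class Fixture:
    name: str
    payload: object  # OccupancyGrid or TrajectorySet
    truth: dict = field(default_factory=dict)
    note: str = ""


def _draw_polylines(size: int, polylines) -> np.ndarray:
    img = np.zeros((size, size), dtype=bool)
    for pts in polylines:
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = sk_line(r0, c0, r1, c1)
            img[rr, cc] = True
    return img


def make_mask_fixture(
    name: str, size: int = 121, stroke_radius: int = 3, pixel_size: float = 1.0
) -> Fixture:
    """Binary mask whose skeleton has a known motif topology.

    Motifs (axis-aligned strokes, margin m): line, plus, H, ring (rectangle
    outline), theta (ring with a chord), grid3x3 (2x2 lattice of cells,
    4 meshes), two_components (two equal disjoint lines, stability 0.5).
    """
    if name not in MASK_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid names: {MASK_NAMES}")
    m = max(4 * stroke_radius, 15)
    if size <= 2 * m + 8:
        raise ValueError(f"size {size} too small for motif at margin {m}")
    lo, hi, mid = m, size - 1 - m, size // 2

    if name == "line":
        lines = [[(mid, lo), (mid, hi)]]
        truth = {
            "n_junctions": 0, "n_branches": 1, "n_segments": 0, "n_meshes": 0,
            "endpoints": 2, "edges": 1, "components": 1,
            "n_master_junctions": 0, "isolated_cycles": 0,
        }
    elif name == "plus":
        lines = [[(mid, lo), (mid, hi)], [(lo, mid), (hi, mid)]]
        truth = {
            "n_junctions": 1, "n_branches": 4, "n_segments": 0, "n_meshes": 0,
            "endpoints": 4, "n_master_junctions": 0, "isolated_cycles": 0,
        }
    elif name == "H":
        c1, c2 = lo + (hi - lo) // 4, hi - (hi - lo) // 4
        lines = [
            [(lo, c1), (hi, c1)],
            [(lo, c2), (hi, c2)],
            [(mid, c1), (mid, c2)],
        ]
        truth = {
            "n_junctions": 2, "n_branches": 4, "n_segments": 1, "n_meshes": 0,
            "endpoints": 4, "n_master_junctions": 0, "isolated_cycles": 0,
        }
    elif name == "ring":
        lines = [[(lo, lo), (lo, hi), (hi, hi), (hi, lo), (lo, lo)]]
        truth = {
            "n_junctions": 0, "n_branches": 0, "n_segments": 0, "n_meshes": 1,
            "endpoints": 0, "isolated_cycles": 1, "components": 1,
        }
    elif name == "theta":
        lines = [
            [(lo, lo), (lo, hi), (hi, hi), (hi, lo), (lo, lo)],
            [(lo, mid), (hi, mid)],
        ]
        truth = {
            "n_junctions": 2, "n_branches": 0, "n_segments": 3, "n_meshes": 2,
            "endpoints": 0, "isolated_cycles": 0,
        }
    elif name == "grid3x3":
        lines = [
            [(lo, lo), (lo, hi), (hi, hi), (hi, lo), (lo, lo)],
            [(lo, mid), (hi, mid)],
            [(mid, lo), (mid, hi)],
        ]
        truth = {
            "n_junctions": 5, "n_branches": 0, "n_segments": 8, "n_meshes": 4,
            "endpoints": 0, "isolated_cycles": 0,
        }
    else:  # two_components
        r1 = mid - (hi - lo) // 4
        r2 = mid + (hi - lo) // 4
        lines = [[(r1, lo), (r1, hi)], [(r2, lo), (r2, hi)]]
        truth = {
            "n_junctions": 0, "n_branches": 2, "n_segments": 0, "n_meshes": 0,
            "endpoints": 4, "components": 2, "stability": 0.5,
        }

    img = _draw_polylines(size, lines)
    img = dilation(img, disk(stroke_radius))
    grid = OccupancyGrid(img, pixel_size, size * pixel_size)
    return Fixture(name, grid, truth, note="synthetic motif mask")


def _tracks_to_set(points: np.ndarray, dt: float = 1.0) -> TrajectorySet:
    n = len(points)
    return TrajectorySet(
        pd.DataFrame(
            {
                "agent_id": 0,
                "frame": np.arange(n),
                "time": np.arange(n) * dt,
                "x": points[:, 0],
                "y": points[:, 1],
                "role": "follower",
            }
        )
    )


def make_track_fixture(kind: str, **params) -> Fixture:
    """Single-agent track with closed-form S, D and straightness truth.

    straight: n points spaced ``step`` along +x. loop: square perimeter of
    given side back to start. L_path: legs of 3 then 4 units (3-4-5
    triangle, straightness 5/7). lattice_walk: seeded unit-step walk on the
    integer lattice (S = number of steps; D from the constructed points).
    """
    if kind not in TRACK_KINDS:
        raise ValueError(f"unknown track kind {kind!r}; valid: {TRACK_KINDS}")
    if kind == "straight":
        n = int(params.get("n", 10))
        step = float(params.get("step", 2.0))
        pts = np.column_stack([np.arange(n) * step, np.zeros(n)])
        S = (n - 1) * step
        truth = {"S": S, "D": S, "straightness": 1.0}
    elif kind == "loop":
        side = float(params.get("side", 5.0))
        pts = np.array(
            [[0, 0], [side, 0], [side, side], [0, side], [0, 0]], dtype=float
        )
        truth = {"S": 4 * side, "D": 0.0, "straightness": 0.0}
    elif kind == "L_path":
        a = float(params.get("a", 3.0))
        b = float(params.get("b", 4.0))
        pts = np.array([[0, 0], [a, 0], [a, b]], dtype=float)
        c = float(np.hypot(a, b))
        truth = {"S": a + b, "D": c, "straightness": c / (a + b)}
    else:  # lattice_walk
        n = int(params.get("n", 50))
        seed = int(params.get("seed", 0))
        rng = np.random.default_rng(seed)
        steps = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=float)
        walk = steps[rng.integers(0, 4, size=n)]
        pts = np.vstack([[0.0, 0.0], np.cumsum(walk, axis=0)])
        D = float(np.hypot(*pts[-1]))
        truth = {"S": float(n), "D": D,
                 "straightness": D / n if n else np.nan}
    # offset away from the origin so tracks are generic
    pts = pts + np.asarray(params.get("offset", (0.0, 0.0)), dtype=float)
    return Fixture(kind, _tracks_to_set(pts), truth, note="synthetic track")


def write_fixture(fixture: Fixture, path: str | Path) -> None:
    """Write a mask fixture (TIFF + truth JSON) or track fixture (CSV + JSON)."""
    path = Path(path)
    if isinstance(fixture.payload, OccupancyGrid):
        write_grid(fixture.payload, path)
    else:
        fixture.payload.to_csv(path)
    path.with_suffix(".truth.json").write_text(json.dumps(fixture.truth, indent=1))
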