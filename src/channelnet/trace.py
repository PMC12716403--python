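"""Trajectory accumulation into binary microchannel occupancy maps.

Channels are carved irreversibly as cells move, so the union of all swept
disks over time is the channel map. Consecutive recorded positions of the
same agent are joined by a capsule (a line segment dilated by the channel
radius); capsules that cross the periodic boundary are stamped on both sides.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .abm import TrajectorySet, min_image

logger = logging.getLogger(__name__)


@dataclass
class OccupancyGrid:
    """Binary channel map on a pixel grid with a physical pixel size (um)."""

    pixels: np.ndarray  # bool, shape (ny, nx); row = y, col = x
    pixel_size: float
    domain_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2

    def copy(self) -> "OccupancyGrid":
        return OccupancyGrid(self.pixels.copy(), self.pixel_size, self.domain_size)


def grid_shape(domain_size: float, pixel_size: float) -> tuple[int, int]:
    n = int(math.ceil(domain_size / pixel_size))
    return (n, n)


def rasterize_trajectories(
    traj: TrajectorySet,
    channel_radius: float | None = None,
    pixel_size: float = 2.0,
    max_frame: int | None = None,
    domain_size: float | None = None,
) -> OccupancyGrid:
    """Stamp accumulated trajectories into a binary occupancy grid.

    A pixel is set when its center lies within ``channel_radius`` of any
    recorded position or of the segment joining consecutive positions of the
    same agent (periodically unwrapped). Segments are densely sampled at
    spacing <= min(pixel_size, channel_radius)/2 and each sample stamps an
    exact pixel-center-in-disk test, so the capsule is recovered to well below
    one pixel.

    Parameters
    ----------
    channel_radius : float, optional
        Stamp radius in um; defaults to the simulated agent radius.
    pixel_size : float
        Pixel edge in um; must satisfy ``pixel_size <= channel_radius / 2``.
    max_frame : int, optional
        Only stamp frames 0..max_frame (time-course checkpoints).
    """
    cfg = traj.config
    if channel_radius is None:
        if cfg is None:
            raise ValueError("channel_radius required when trajectory has no config")
        channel_radius = cfg.agent_radius
    if domain_size is not None:
        L = float(domain_size)
    elif cfg is not None:
        L = cfg.domain_size
    else:
        raise ValueError("domain_size required when trajectory has no config")
    if pixel_size > channel_radius / 2:
        raise ValueError("pixel_size must be <= channel_radius / 2")

    shape = grid_shape(L, pixel_size)
    grid = np.zeros(shape, dtype=bool)
    frames = traj.frames
    if max_frame is not None:
        frames = frames[frames["frame"] <= max_frame]
    if frames.empty:
        warnings.warn("empty trajectory table; returning all-zero grid")
        return OccupancyGrid(grid, pixel_size, L)

    frames = frames.sort_values(["agent_id", "frame"])
    xy = frames[["x", "y"]].to_numpy(dtype=float)
    same_agent = frames["agent_id"].to_numpy()[1:] == frames["agent_id"].to_numpy()[:-1]

    # segment sample points (capsules), plus every recorded point itself
    p0 = xy[:-1][same_agent]
    delta = min_image(xy[1:][same_agent] - p0, L)  # periodic unwrap
    seg_len = np.hypot(delta[:, 0], delta[:, 1])
    spacing = min(pixel_size, channel_radius) / 2.0
    pts = [xy]
    if len(p0):
        counts = np.maximum(np.ceil(seg_len / spacing).astype(int), 1) + 1
        total = int(counts.sum())
        seg_idx = np.repeat(np.arange(len(p0)), counts)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        local = np.arange(total) - starts[seg_idx]
        tfrac = local / (counts[seg_idx] - 1)
        pts.append(p0[seg_idx] + tfrac[:, None] * delta[seg_idx])
    points = np.concatenate(pts, axis=0) % L

    _stamp_disks(grid, points, channel_radius, pixel_size, L)
    return OccupancyGrid(grid, pixel_size, L)


def _stamp_disks(
    grid: np.ndarray,
    points: np.ndarray,
    radius: float,
    pixel_size: float,
    domain_size: float,
) -> None:
    """Set every pixel whose center is within ``radius`` of any point (periodic)."""
    ny, nx = grid.shape
    # integer offsets wide enough to cover the disk from any in-pixel position
    k = int(math.ceil(radius / pixel_size)) + 1
    px = np.floor(points[:, 0] / pixel_size).astype(np.int64)
    py = np.floor(points[:, 1] / pixel_size).astype(np.int64)
    r2 = radius**2
    for dy in range(-k, k + 1):
        for dx in range(-k, k + 1):
            # quick reject: nearest approach of this offset's pixel centers
            if (max(abs(dx) - 1, 0) ** 2 + max(abs(dy) - 1, 0) ** 2) * pixel_size**2 > r2:
                continue
            cx = (px + dx + 0.5) * pixel_size
            cy = (py + dy + 0.5) * pixel_size
            ex = min_image(cx - points[:, 0], domain_size)
            ey = min_image(cy - points[:, 1], domain_size)
            hit = ex**2 + ey**2 <= r2
            if hit.any():
                rows = (py[hit] + dy) % ny
                cols = (px[hit] + dx) % nx
                grid[rows, cols] = True


# ---------------------------------------------------------------------------
# grid I/O: binary TIFF (0/255) + sidecar JSON metadata; PNG accepted on read
# ---------------------------------------------------------------------------

def _sidecar_path(path: str | Path) -> Path:
    return Path(str(path)).with_suffix(".meta.json")


def write_grid(grid: OccupancyGrid, path: str | Path) -> None:
    """Write the mask as a single-page 0/255 TIFF plus a JSON sidecar."""
    path = Path(path)
    img = (grid.pixels.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    _sidecar_path(path).write_text(
        json.dumps(
            {"pixel_size_um": grid.pixel_size, "domain_size_um": grid.domain_size}
        )
    )


def read_grid(path: str | Path, pixel_size: float | None = None) -> OccupancyGrid:
    """Read a binary mask (TIFF or PNG); pixel size from sidecar unless given."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(path)
        else:
            img = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask image at {path}: {exc}") from exc
    if img.ndim == 3:  # RGB(A) PNG
        img = img[..., 0]
    pixels = img > 0
    domain_size = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
        domain_size = meta.get("domain_size_um")
    if pixel_size is None:
        raise ValueError(f"no pixel size: pass pixel_size or provide {sidecar.name}")
    if domain_size is None:
        domain_size = pixels.shape[1] * pixel_size
    return OccupancyGrid(pixels, float(pixel_size), float(domain_size))
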