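"""Ground classification and height normalization.

Ground points are found with a cloth-simulation filter (CSF): the cloud is
inverted in z and a grid of cloth particles is dropped onto it under
gravity; internal springs keep the cloth stiff (more smoothing passes =
more rigid), particles freeze where they touch the inverted surface, and
points within ``class_threshold`` of the settled cloth are labeled ground.
Heights are then normalized by subtracting an inverse-distance-weighted
estimate of the ground surface from the k nearest ground points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import InsufficientInputError, MissingGroundError, StateError
from .io_formats import PointClass, PointCloud

logger = logging.getLogger(__name__)

_RIGIDNESS_PASSES = {"low": 1, "medium": 2, "high": 3}
# Normalized gravity: displacement per step is _GRAVITY * time_step^2 (~8 cm
# at the stock 0.65 time step).  Small steps let the spring constraints keep
# the cloth taut over canopy gaps instead of punching through them.
_GRAVITY = 0.2


@dataclass
class GroundParams:
    """Cloth-simulation parameters (defaults follow common SfM practice)."""

    class_threshold: float = 0.20   # m: point-to-cloth distance for "ground"
    cloth_resolution: float = 0.20  # m: particle grid spacing
    rigidness: str = "medium"       # low / medium / high
    iterations: int = 500
    time_step: float = 0.65

    def __post_init__(self) -> None:
        if self.class_threshold <= 0 or self.cloth_resolution <= 0:
            raise ValueError("class_threshold and cloth_resolution must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.time_step < 1:
            raise ValueError("time_step must lie in (0, 1)")
        if self.rigidness not in _RIGIDNESS_PASSES:
            raise ValueError(f"rigidness must be one of {sorted(_RIGIDNESS_PASSES)}")


@dataclass
class NormalizeParams:
    k_neighbors: int = 10
    idw_power: float = 2.0
    max_radius: float = 0.50  # m

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.idw_power <= 0 or self.max_radius <= 0:
            raise ValueError("idw_power and max_radius must be > 0")


def _simulate_cloth(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, params: GroundParams
) -> tuple[np.ndarray, float, float]:
    """Drop a cloth onto the inverted surface ``w``; return settled heights.

    Returns (cloth grid, x0, y0) where the grid node (i, j) sits at
    (x0 + j*res, y0 + i*res).
    """
    res = params.cloth_resolution
    x0 = x.min() - res
    y0 = y.min() - res
    nx = int(np.ceil((x.max() + res - x0) / res)) + 1
    ny = int(np.ceil((y.max() + res - y0) / res)) + 1

    # height control values: highest inverted point near each node
    jj = np.clip(np.round((x - x0) / res).astype(np.int64), 0, nx - 1)
    ii = np.clip(np.round((y - y0) / res).astype(np.int64), 0, ny - 1)
    hcv = np.full((ny, nx), -np.inf)
    np.maximum.at(hcv, (ii, jj), w)
    empty = ~np.isfinite(hcv)
    if empty.any():
        filled_idx = np.argwhere(~empty)
        tree = cKDTree(filled_idx)
        _, nearest = tree.query(np.argwhere(empty), k=1)
        hcv[empty] = hcv[tuple(filled_idx[nearest].T)]

    passes = _RIGIDNESS_PASSES[params.rigidness]
    fall = _GRAVITY * params.time_step**2

    pos = np.full((ny, nx), w.max() + 2.0)
    prev = pos.copy()
    movable = np.ones((ny, nx), bool)

    def _clamp() -> None:
        hit = movable & (pos <= hcv)
        pos[hit] = hcv[hit]
        movable[hit] = False

    for _ in range(params.iterations):
        if not movable.any():
            break
        # Verlet gravity step for particles still in flight
        new = 2.0 * pos - prev - fall
        prev = np.where(movable, pos, prev)
        pos = np.where(movable, new, pos)
        _clamp()
        # internal spring constraints: pull toward the 4-neighbor mean
        for _ in range(passes):
            padded = np.pad(pos, 1, mode="edge")
            neigh = (
                padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
            ) / 4.0
            pos = np.where(movable, pos + 0.5 * (neigh - pos), pos)
            prev = np.where(movable, pos, prev)  # springs dissipate momentum
            _clamp()

    # any particle still aloft settles onto its control surface
    pos = np.where(movable, np.maximum(pos, hcv), pos)
    return pos, x0, y0


def _bilinear(grid: np.ndarray, x0: float, y0: float, res: float, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    gy = (y - y0) / res
    gx = (x - x0) / res
    i0 = np.clip(np.floor(gy).astype(np.int64), 0, grid.shape[0] - 2)
    j0 = np.clip(np.floor(gx).astype(np.int64), 0, grid.shape[1] - 2)
    fy = np.clip(gy - i0, 0.0, 1.0)
    fx = np.clip(gx - j0, 0.0, 1.0)
    return (
        grid[i0, j0] * (1 - fy) * (1 - fx)
        + grid[i0 + 1, j0] * fy * (1 - fx)
        + grid[i0, j0 + 1] * (1 - fy) * fx
        + grid[i0 + 1, j0 + 1] * fy * fx
    )


def classify_ground(cloud: PointCloud, params: GroundParams | None = None) -> PointCloud:
    """Label ground points via cloth simulation; other points become unclassified."""
    params = params or GroundParams()
    if cloud.normalized:
        raise StateError("classify_ground expects an un-normalized cloud")
    if len(cloud) < 3:
        raise InsufficientInputError("need at least 3 points to classify ground")

    w = -cloud.z  # invert: ground becomes the upper envelope
    cloth, x0, y0 = _simulate_cloth(cloud.x, cloud.y, w, params)
    surf = _bilinear(cloth, x0, y0, params.cloth_resolution, cloud.x, cloud.y)
    is_ground = np.abs(surf - w) <= params.class_threshold

    out = cloud.copy()
    out.point_class = np.where(
        is_ground, int(PointClass.GROUND), int(PointClass.UNCLASSIFIED)
    ).astype(np.uint8)
    logger.info("classify_ground: %d / %d points ground", int(is_ground.sum()), len(cloud))
    return out


def normalize_heights(cloud: PointCloud, params: NormalizeParams | None = None) -> PointCloud:
    """Replace z with height above the IDW-interpolated ground surface.

    A point coinciding exactly with a ground point takes that ground
    elevation (so ground points normalize to exactly 0).  Points with no
    ground neighbor inside ``max_radius`` fall back to the single nearest
    ground point, with a warning.
    """
    params = params or NormalizeParams()
    gmask = cloud.is_ground
    n_ground = int(gmask.sum())
    if n_ground == 0:
        raise MissingGroundError("no ground-classified points; run classify_ground first")
    k = min(params.k_neighbors, n_ground)
    if k < params.k_neighbors:
        logger.warning("only %d ground points; using k=%d", n_ground, k)

    gx, gy, gz = cloud.x[gmask], cloud.y[gmask], cloud.z[gmask]
    tree = cKDTree(np.column_stack([gx, gy]))
    dist, idx = tree.query(np.column_stack([cloud.x, cloud.y]), k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]

    zn = gz[idx]
    in_radius = dist <= params.max_radius
    exact = dist[:, 0] == 0.0

    with np.errstate(divide="ignore", over="ignore"):
        weight = np.where(in_radius, 1.0 / np.maximum(dist, 1e-300) ** params.idw_power, 0.0)
    no_neighbor = ~in_radius.any(axis=1)
    if no_neighbor.any():
        logger.warning(
            "%d points had no ground neighbor within %.2f m; using nearest ground point",
            int(no_neighbor.sum()),
            params.max_radius,
        )
        weight[no_neighbor, 0] = 1.0

    wsum = weight.sum(axis=1)
    with np.errstate(invalid="ignore"):  # exact hits produce inf/inf, fixed below
        ghat = (weight * zn).sum(axis=1) / wsum
    ghat[exact] = zn[exact, 0]

    out = cloud.copy()
    out.z = cloud.z - ghat
    out.normalized = True
    return out
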