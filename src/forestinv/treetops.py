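"""Individual tree detection: variable-window local maxima on the CHM.

A pixel is a tree top when it is at least as high as every pixel whose
center lies within a search radius that scales linearly with the pixel's
own height (radius = height x window_factor, floored at one cell).  The
linear scaling reflects the crown-width/height allometry of open-grown
conifers: taller trees get wider exclusion windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chm import HeightRaster
from .io_formats import BREAST_HEIGHT_M

__all__ = ["TreeTop", "DetectParams", "variable_window_radius", "detect_treetops"]


@dataclass(frozen=True)
class TreeTop:
    tree_id: int
    x: float
    y: float
    height: float


@dataclass
class DetectParams:
    window_factor: float = 0.1       # window radius per meter of height
    min_height: float = BREAST_HEIGHT_M  # m; trees at or below are ignored

    def __post_init__(self) -> None:
        if self.window_factor <= 0:
            raise ValueError("window_factor must be > 0")
        if self.min_height < 0:
            raise ValueError("min_height must be >= 0")


def variable_window_radius(
    pixel_height: float, window_factor: float = 0.1, min_radius: float = 0.0
) -> float:
    """Search radius in meters for a local-maximum pixel of given height.

    ``min_radius`` (typically one CHM cell) floors the radius so short
    trees still have a defined window.
    """
    if pixel_height < 0:
        raise ValueError("pixel_height must be >= 0")
    return max(pixel_height * window_factor, min_radius)


def detect_treetops(chm: HeightRaster, params: DetectParams | None = None) -> list[TreeTop]:
    """Find tree tops as variable-window local maxima of the CHM.

    A candidate must be >= every non-nodata pixel in its circular window
    and strictly higher than at least one of them (so constant fields
    yield nothing); on an equal-height plateau only the first pixel in
    row-major order is kept.  Returned coordinates are pixel centers; ids
    follow row-major scan order.
    """
    params = params or DetectParams()
    vals = chm.values
    ny, nx = vals.shape
    data = chm.mask
    cand = data & (vals > params.min_height)
    if not cand.any():
        return []

    cell = chm.cell_size
    # Cheap prefilter: the window always contains the 4-neighbors (radius
    # is floored at one cell), so a top must dominate them.
    up = np.full_like(vals, -np.inf)
    masked = np.where(data, vals, -np.inf)
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.full_like(vals, -np.inf)
        src = masked[
            max(di, 0) : ny + min(di, 0) or None, max(dj, 0) : nx + min(dj, 0) or None
        ]
        shifted[
            max(-di, 0) : ny + min(-di, 0) or None, max(-dj, 0) : nx + min(-dj, 0) or None
        ] = src
        np.maximum(up, shifted, out=up)
    cand &= vals >= up

    ci, cj = np.nonzero(cand)
    heights = vals[ci, cj]
    rmax_cells = int(np.ceil(max(heights.max() * params.window_factor / cell, 1.0)))
    off = np.arange(-rmax_cells, rmax_cells + 1)
    d2 = off[None, :] ** 2 + off[:, None] ** 2  # squared distance in cells

    tops: list[TreeTop] = []
    tree_id = 0
    for i, j, h in zip(ci.tolist(), cj.tolist(), heights.tolist()):
        r_cells = variable_window_radius(h, params.window_factor, cell) / cell
        rc = int(np.floor(r_cells + 1e-9))
        i0, i1 = max(i - rc, 0), min(i + rc, ny - 1)
        j0, j1 = max(j - rc, 0), min(j + rc, nx - 1)
        win = vals[i0 : i1 + 1, j0 : j1 + 1]
        wmask = data[i0 : i1 + 1, j0 : j1 + 1]
        dsub = d2[
            rmax_cells - (i - i0) : rmax_cells + (i1 - i) + 1,
            rmax_cells - (j - j0) : rmax_cells + (j1 - j) + 1,
        ]
        inwin = wmask & (dsub <= r_cells * r_cells + 1e-9)
        neigh = win[inwin]
        if np.any(neigh > h):
            continue
        if neigh.size > 1 and not np.any(neigh < h):
            continue  # flat field: every in-window pixel equals the candidate
        if np.any(neigh == h):
            # plateau: keep only the first pixel in row-major order
            wi, wj = np.nonzero(inwin & (win == h))
            flat = (wi + i0) * nx + (wj + j0)
            if flat.min() < i * nx + j:
                continue
        tree_id += 1
        x, y = chm.cell_center(i, j)
        tops.append(TreeTop(tree_id, float(x), float(y), float(h)))
    return tops
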