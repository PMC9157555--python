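"""Stem mapping and DBH extraction from the normalized cloud.

Five steps mirror standard TLS inventory practice: (1) slice the cloud to
the stem zone, (2) map candidate stems with a Hough circle search on the
breast-height band, (3) attribute nearby points to each candidate tree,
(4) classify stem points by per-segment circle fits that reject outliers,
(5) fit the breast-height circle with RANSAC + algebraic least squares to
report DBH.

The Hough accumulator and the DBH raster are anchored to the data's own
bounding box, so every operation here is exactly invariant under rigid
xy-translation of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ParameterError
from .io_formats import PointClass, PointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "StemParams",
    "StemRecord",
    "slice_cloud",
    "map_stems_hough",
    "assign_tree_points",
    "classify_stem_points",
    "fit_dbh",
]


@dataclass(frozen=True)
class StemRecord:
    """An extracted stem: breast-height circle center and diameter."""

    stem_id: int
    x: float
    y: float
    dbh: float        # cm
    n_inliers: int
    rmse: float       # cm, radial residual of the final circle fit


@dataclass
class StemParams:
    """Stem-extraction parameters (lengths in meters)."""

    slice_zmin: float = 0.1
    slice_zmax: float = 4.0
    map_zlo: float = 1.32
    map_zhi: float = 1.42
    map_max_diameter: float = 1.0
    map_min_density: float = 0.001   # fractional Hough vote density
    crop_radius: float = 0.5
    stem_max_diameter: float = 1.5
    stem_min_density: float = 0.1    # fractional Hough vote density
    segment_height: float = 0.5
    dbh_center: float = 1.37
    dbh_thickness: float = 0.1
    # discretization / robustness settings
    hough_cell: float = 0.025        # accumulator cell and radius step
    dbh_cell: float = 0.01           # raster cell for the RANSAC circle fit
    inlier_tolerance: float = 0.025  # radial distance to keep a stem point
    ransac_iterations: int = 500
    ransac_tolerance: float = 0.015  # m, on the 1 cm raster

    def __post_init__(self) -> None:
        if not self.slice_zmin < self.map_zlo < self.map_zhi < self.slice_zmax:
            raise ParameterError("need slice_zmin < map_zlo < map_zhi < slice_zmax")
        if self.dbh_thickness <= 0:
            raise ParameterError("dbh_thickness must be > 0")
        if min(self.map_max_diameter, self.stem_max_diameter) <= 0:
            raise ParameterError("stem diameters must be > 0")


def slice_cloud(cloud: PointCloud, zmin: float, zmax: float) -> PointCloud:
    """Keep points with zmin <= z <= zmax (the stem zone of a normalized cloud)."""
    if zmin >= zmax:
        raise ParameterError(f"zmin ({zmin}) must be < zmax ({zmax})")
    return cloud.select((cloud.z >= zmin) & (cloud.z <= zmax))


# ---------------------------------------------------------------------------
# Hough circle search


def _circle_offsets(radius_cells: float) -> np.ndarray:
    """Unique integer cell offsets approximating a circle of given radius."""
    n = max(int(np.ceil(2 * np.pi * radius_cells * 2)), 8)
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    pts = np.stack(
        [np.round(radius_cells * np.cos(ang)), np.round(radius_cells * np.sin(ang))], axis=1
    ).astype(np.int64)
    return np.unique(pts, axis=0)


def hough_circles(
    x: np.ndarray,
    y: np.ndarray,
    max_diameter: float,
    min_density: float,
    merge_distance: float,
    cell: float = 0.025,
) -> list[tuple[float, float, float, float]]:
    """2-D Hough circle search over an occupancy grid.

    Points are binned to ``cell``-sized occupancy cells; every candidate
    radius (multiples of ``cell`` up to ``max_diameter/2``) votes at the
    circle of centers around each occupied cell.  A peak's score is its
    vote count divided by the circle circumference in cells, so a fully
    sampled circle scores near 1 regardless of size.  Peaks below
    ``min_density`` are dropped and peaks closer than ``merge_distance``
    merge to the strongest.

    Returns (cx, cy, radius, density) tuples sorted by descending density.
    """
    if x.size == 0:
        return []
    r_max = max_diameter / 2.0
    pad = int(np.ceil(r_max / cell)) + 1
    x0 = x.min() - pad * cell
    y0 = y.min() - pad * cell
    nx = int(np.ceil((x.max() - x0) / cell)) + pad + 2
    ny = int(np.ceil((y.max() - y0) / cell)) + pad + 2

    occ = np.unique(
        np.stack(
            [((y - y0) / cell).astype(np.int64), ((x - x0) / cell).astype(np.int64)], axis=1
        ),
        axis=0,
    )

    radii = np.arange(cell, r_max + cell / 2, cell)
    best_density = np.zeros((ny, nx))
    best_radius = np.zeros((ny, nx))
    acc = np.zeros((ny, nx), np.int32)
    for r in radii:
        offs = _circle_offsets(r / cell)
        acc[:] = 0
        ci = occ[:, 0][:, None] + offs[:, 0][None, :]
        cj = occ[:, 1][:, None] + offs[:, 1][None, :]
        ok = (ci >= 0) & (ci < ny) & (cj >= 0) & (cj < nx)
        np.add.at(acc, (ci[ok], cj[ok]), 1)
        density = acc / len(offs)
        better = density > best_density
        best_density[better] = density[better]
        best_radius[better] = r

    ii, jj = np.nonzero(best_density >= min_density)
    if ii.size == 0:
        return []
    dens = best_density[ii, jj]
    order = np.argsort(-dens, kind="stable")
    cx = x0 + (jj + 0.5) * cell
    cy = y0 + (ii + 0.5) * cell

    peaks: list[tuple[float, float, float, float]] = []
    taken_x: list[float] = []
    taken_y: list[float] = []
    for k in order:
        px, py = cx[k], cy[k]
        if taken_x:
            d2 = (np.array(taken_x) - px) ** 2 + (np.array(taken_y) - py) ** 2
            if (d2 < merge_distance**2).any():
                continue
        peaks.append((float(px), float(py), float(best_radius[ii[k], jj[k]]), float(dens[k])))
        taken_x.append(px)
        taken_y.append(py)
    return peaks


def map_stems_hough(
    slab: PointCloud, params: StemParams | None = None
) -> list[tuple[float, float, float]]:
    """Find candidate stem centers on the breast-height band.

    Crops the stem-zone slab to [map_zlo, map_zhi] and runs the Hough
    circle search; returns (x, y, radius) per candidate.
    """
    params = params or StemParams()
    band = slice_cloud(slab, params.map_zlo, params.map_zhi)
    if len(band) == 0:
        logger.warning("map_stems_hough: no points in the breast-height band")
        return []
    peaks = hough_circles(
        band.x,
        band.y,
        params.map_max_diameter,
        params.map_min_density,
        merge_distance=params.map_max_diameter,
        cell=params.hough_cell,
    )
    return [(px, py, r) for px, py, r, _ in peaks]


def assign_tree_points(
    slab: PointCloud, centers: list[tuple[float, float] | tuple[float, float, float]]
) -> PointCloud:
    """Give each point within ``crop_radius`` of a candidate center its tree id.

    Points within range of several centers go to the nearest; tree ids are
    1-based indices into ``centers``.
    """
    out = slab.copy()
    if not centers:
        return out
    xy = np.array([[c[0], c[1]] for c in centers])
    tree = cKDTree(xy)
    dist, idx = tree.query(np.column_stack([slab.x, slab.y]), k=1)
    within = dist <= StemParams().crop_radius
    out.tree_id = np.where(within, idx + 1, 0).astype(np.int32)
    return out


def _kasa_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle fit; returns (cx, cy, r)."""
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    return float(cx), float(cy), float(np.sqrt(max(r2, 0.0)))


def classify_stem_points(labeled: PointCloud, params: StemParams | None = None) -> PointCloud:
    """Classify stem points per tree by segment-wise circle fits.

    Each tree's points are cut into ``segment_height`` vertical segments;
    a Hough circle (refined by algebraic least squares) is fit per
    segment and points farther than ``inlier_tolerance`` from the fitted
    ring are rejected.  Survivors get ``point_class = STEM``.  A tree
    where no segment yields a circle is dropped from the stem set.
    """
    params = params or StemParams()
    out = labeled.copy()
    ids = np.unique(labeled.tree_id)
    ids = ids[ids > 0]
    zlo, zhi = params.slice_zmin, params.slice_zmax
    edges = np.arange(zlo, zhi + params.segment_height, params.segment_height)
    for tid in ids:
        tmask = labeled.tree_id == tid
        kept_any = False
        for s0, s1 in zip(edges[:-1], edges[1:]):
            seg = tmask & (labeled.z >= s0) & (labeled.z < s1)
            n_seg = int(seg.sum())
            if n_seg < 3:
                continue
            peaks = hough_circles(
                labeled.x[seg],
                labeled.y[seg],
                params.stem_max_diameter,
                params.stem_min_density,
                merge_distance=params.stem_max_diameter,
                cell=params.hough_cell,
            )
            if not peaks:
                continue
            cx, cy, r, _ = peaks[0]
            dx = labeled.x[seg] - cx
            dy = labeled.y[seg] - cy
            radial = np.abs(np.hypot(dx, dy) - r)
            rough = radial <= 2 * params.inlier_tolerance
            if rough.sum() >= 3:
                cx, cy, r = _kasa_fit(labeled.x[seg][rough], labeled.y[seg][rough])
                radial = np.abs(np.hypot(labeled.x[seg] - cx, labeled.y[seg] - cy) - r)
            inl = radial <= params.inlier_tolerance
            if inl.sum() >= 3:
                seg_idx = np.nonzero(seg)[0][inl]
                out.point_class[seg_idx] = int(PointClass.STEM)
                kept_any = True
        if not kept_any:
            logger.info("tree %d: no segment produced a circle; dropped from stem set", tid)
    return out


def _circle_from_3(p: np.ndarray) -> tuple[float, float, float] | None:
    (x1, y1), (x2, y2), (x3, y3) = p
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    if abs(d) < 1e-12:
        return None
    s1 = x1**2 + y1**2
    s2 = x2**2 + y2**2
    s3 = x3**2 + y3**2
    cx = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    cy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    return cx, cy, float(np.hypot(x1 - cx, y1 - cy))


def fit_dbh(
    stem_points: PointCloud, params: StemParams | None = None, seed: int = 0
) -> list[StemRecord]:
    """Fit the breast-height circle per tree and report DBH in cm.

    Takes the stem-classified points in the ``dbh_thickness`` band around
    ``dbh_center`` (1.37 m), flattens them, rasterizes occupied cells at
    ``dbh_cell`` (1 cm), and fits a circle by RANSAC (3-cell minimal
    samples, consensus refit by algebraic least squares).  Trees with
    fewer than 3 occupied cells, or whose fitted diameter exceeds
    ``map_max_diameter``, are omitted.
    """
    params = params or StemParams()
    rng = np.random.default_rng(seed)
    half = params.dbh_thickness / 2.0
    band = (
        (stem_points.point_class == PointClass.STEM)
        & (stem_points.z >= params.dbh_center - half)
        & (stem_points.z <= params.dbh_center + half)
    )
    records: list[StemRecord] = []
    for tid in np.unique(stem_points.tree_id[band & (stem_points.tree_id > 0)]):
        sel = band & (stem_points.tree_id == tid)
        x = stem_points.x[sel]
        y = stem_points.y[sel]
        # rasterize the flattened slice: occupied 1 cm cells become fit samples
        cell = params.dbh_cell
        x0, y0 = x.min(), y.min()
        occ = np.unique(
            np.stack(
                [((x - x0) / cell).astype(np.int64), ((y - y0) / cell).astype(np.int64)],
                axis=1,
            ),
            axis=0,
        )
        if len(occ) < 3:
            logger.info("tree %d: <3 occupied cells at breast height; no DBH", tid)
            continue
        cx_cells = (occ[:, 0] + 0.5) * cell + x0
        cy_cells = (occ[:, 1] + 0.5) * cell + y0
        pts = np.column_stack([cx_cells, cy_cells])

        best_count = 0
        best_rmse = np.inf
        best_inliers: np.ndarray | None = None
        n = len(pts)
        for _ in range(params.ransac_iterations):
            tri = pts[rng.choice(n, size=3, replace=False)]
            fit = _circle_from_3(tri)
            if fit is None:
                continue
            ccx, ccy, cr = fit
            if 2 * cr > params.map_max_diameter * 2:  # wildly large sample circle
                continue
            resid = np.abs(np.hypot(pts[:, 0] - ccx, pts[:, 1] - ccy) - cr)
            inl = resid <= params.ransac_tolerance
            count = int(inl.sum())
            rmse = float(np.sqrt(np.mean(resid[inl] ** 2))) if count else np.inf
            if count > best_count or (count == best_count and rmse < best_rmse):
                best_count = count
                best_rmse = rmse
                best_inliers = inl
        if best_inliers is None or best_inliers.sum() < 3:
            logger.info("tree %d: RANSAC found no consensus circle; no DBH", tid)
            continue
        fx, fy, fr = _kasa_fit(pts[best_inliers, 0], pts[best_inliers, 1])
        dbh_cm = 2.0 * fr * 100.0
        if not 0.0 < dbh_cm <= params.map_max_diameter * 100.0:
            logger.info("tree %d: fitted diameter %.1f cm rejected", tid, dbh_cm)
            continue
        resid = np.hypot(pts[best_inliers, 0] - fx, pts[best_inliers, 1] - fy) - fr
        rmse_cm = float(np.sqrt(np.mean(resid**2)) * 100.0)
        records.append(
            StemRecord(int(tid), fx, fy, dbh_cm, int(best_inliers.sum()), rmse_cm)
        )
    return records
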