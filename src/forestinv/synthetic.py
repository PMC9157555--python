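"""Labeled synthetic stands for testing every pipeline stage end to end.

The generator emulates the open-canopy conifer regime the method targets:
a ground surface, trees with bare cylindrical stems below 30% of their
height and narrow conical crowns above, sampled as surface-biased point
clouds of SfM-like density, plus a regional inventory whose height-DBH
pairs follow a power allometry with additive Gaussian noise.  Every
output carries ground-truth labels (per-tree attributes, per-point class
and tree id), and everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import RegionalInventory
from .io_formats import PointCloud

__all__ = [
    "StandConfig",
    "GroundTruth",
    "generate_stand",
    "sample_stand_cloud",
    "generate_regional_inventory",
]

# true per-point class codes
TRUE_GROUND = 2
TRUE_STEM = 4
TRUE_CROWN = 5


@dataclass
class StandConfig:
    """Conditions of a simulated stand.

    Defaults describe a 0.25 ha open ponderosa-like stand sampled at
    roughly SfM density (~1000 pts/m2 of ground plus crown and stem
    surface points).
    """

    seed: int = 0
    extent: tuple[float, float] = (50.0, 50.0)   # m x m
    n_trees: int = 50
    min_spacing: float = 3.0                     # m between stem centers
    height_range: tuple[float, float] = (5.0, 20.0)  # m
    allometry_a: float = 2.5                     # cm * m^-b
    allometry_b: float = 0.9
    allometry_sigma: float = 1.0                 # cm, additive DBH noise
    stem_points_per_m: float = 600.0             # points per m of stem height
    crown_point_density: float = 300.0           # pts per m3 of crown volume
    ground_density: float = 1000.0               # pts per m2
    terrain: str = "flat"                        # flat / slope / rolling
    occlusion: bool = False                      # keep only a 180 deg stem arc

    def __post_init__(self) -> None:
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be > 0")
        if min(self.stem_points_per_m, self.crown_point_density, self.ground_density) <= 0:
            raise ValueError("densities must be > 0")
        lo, hi = self.height_range
        if not (1.37 < lo <= hi <= 40.0):
            raise ValueError("height_range must lie within (1.37, 40]")
        if self.terrain not in ("flat", "slope", "rolling"):
            raise ValueError("terrain must be flat, slope, or rolling")


@dataclass
class GroundTruth:
    """Per-tree truth plus (after sampling) per-point truth labels."""

    trees: pd.DataFrame                      # tree_id, x, y, height_m, dbh_cm
    point_class: np.ndarray = field(default=None)    # type: ignore[assignment]
    point_tree_id: np.ndarray = field(default=None)  # type: ignore[assignment]


def terrain_elevation(x: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    """Ground elevation (m) of the three built-in terrain shapes."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if kind == "flat":
        return np.full_like(x, 100.0)
    if kind == "slope":
        return 100.0 + 0.15 * x
    return 100.0 + 1.5 * np.sin(x / 8.0) * np.cos(y / 10.0)  # rolling


def crown_radius(height: np.ndarray) -> np.ndarray:
    """Crown radius (m): 10% of height, kept within [0.4, 2.0] m.

    Narrow cones mimic shade-intolerant conifers in open stands, where
    crowns do not interlock at typical 3 m stem spacings.
    """
    return np.clip(0.1 * np.asarray(height, float), 0.4, 2.0)


def generate_stand(config: StandConfig) -> GroundTruth:
    """Place trees by Poisson-disk dart throwing and draw their attributes.

    Heights are uniform over ``height_range``; DBH follows the configured
    power allometry with N(0, sigma) additive noise (floored at 1 cm).
    """
    rng = np.random.default_rng(config.seed)
    ex, ey = config.extent
    margin = min(config.min_spacing, min(ex, ey) / 4.0)
    xs: list[float] = []
    ys: list[float] = []
    attempts = 0
    max_attempts = max(20000, config.n_trees * 2000)
    while len(xs) < config.n_trees:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_trees} trees at {config.min_spacing} m "
                f"spacing in a {ex} x {ey} m extent"
            )
        px = rng.uniform(margin, ex - margin)
        py = rng.uniform(margin, ey - margin)
        if xs:
            d2 = (np.array(xs) - px) ** 2 + (np.array(ys) - py) ** 2
            if d2.min() < config.min_spacing**2:
                continue
        xs.append(px)
        ys.append(py)

    h = rng.uniform(*config.height_range, size=config.n_trees)
    dbh = config.allometry_a * h**config.allometry_b + rng.normal(
        0.0, config.allometry_sigma, size=config.n_trees
    )
    dbh = np.maximum(dbh, 1.0)
    trees = pd.DataFrame(
        {
            "tree_id": np.arange(1, config.n_trees + 1),
            "x": xs,
            "y": ys,
            "height_m": h,
            "dbh_cm": dbh,
        }
    )
    return GroundTruth(trees)


def _sample_cone(
    rng: np.random.Generator,
    n: int,
    base_z: float,
    apex_z: float,
    base_radius: float,
    surface_fraction: float = 0.7,
) -> np.ndarray:
    """Sample points of a crown cone: mostly on the lateral surface (what
    photogrammetry reconstructs), the rest scattered in the interior."""
    length = apex_z - base_z
    n_surf = int(round(n * surface_fraction))
    out = np.empty((n, 3))
    # lateral surface: area density along the axis is proportional to radius
    t = 1.0 - np.sqrt(rng.uniform(size=n_surf))
    r = base_radius * (1.0 - t)
    ang = rng.uniform(0, 2 * np.pi, size=n_surf)
    out[:n_surf, 0] = r * np.cos(ang)
    out[:n_surf, 1] = r * np.sin(ang)
    out[:n_surf, 2] = base_z + t * length
    # interior: volume density proportional to radius^2
    m = n - n_surf
    t = 1.0 - np.cbrt(rng.uniform(size=m))
    r = base_radius * (1.0 - t) * np.sqrt(rng.uniform(size=m))
    ang = rng.uniform(0, 2 * np.pi, size=m)
    out[n_surf:, 0] = r * np.cos(ang)
    out[n_surf:, 1] = r * np.sin(ang)
    out[n_surf:, 2] = base_z + t * length
    return out


def sample_stand_cloud(truth: GroundTruth, config: StandConfig) -> PointCloud:
    """Sample the stand into an (un-normalized) labeled point cloud.

    Ground points are uniform over the extent at ``ground_density``; stem
    points sit on cylinder surfaces of radius DBH/2 from the ground up to
    30% of tree height; crown points fill a cone from there to the apex,
    with one guaranteed point at each apex so the CHM always sees the true
    height.  In ``occlusion`` mode stems keep only a 180 degree arc.
    True labels are stored on ``truth`` (point_class, point_tree_id).
    """
    rng = np.random.default_rng(config.seed + 101)
    ex, ey = config.extent

    chunks: list[np.ndarray] = []
    classes: list[np.ndarray] = []
    tids: list[np.ndarray] = []

    n_ground = int(round(config.ground_density * ex * ey))
    gx = rng.uniform(0, ex, n_ground)
    gy = rng.uniform(0, ey, n_ground)
    gz = terrain_elevation(gx, gy, config.terrain)
    chunks.append(np.column_stack([gx, gy, gz]))
    classes.append(np.full(n_ground, TRUE_GROUND, np.uint8))
    tids.append(np.zeros(n_ground, np.int32))

    for row in truth.trees.itertuples():
        base = float(terrain_elevation(np.array([row.x]), np.array([row.y]), config.terrain)[0])
        stem_top = 0.3 * row.height_m
        stem_r = row.dbh_cm / 200.0
        n_stem = max(int(round(config.stem_points_per_m * stem_top)), 10)
        if config.occlusion:
            ang = rng.uniform(0, np.pi, n_stem)
        else:
            ang = rng.uniform(0, 2 * np.pi, n_stem)
        sz = rng.uniform(0, stem_top, n_stem)
        sx = row.x + stem_r * np.cos(ang)
        sy = row.y + stem_r * np.sin(ang)
        chunks.append(np.column_stack([sx, sy, base + sz]))
        classes.append(np.full(n_stem, TRUE_STEM, np.uint8))
        tids.append(np.full(n_stem, row.tree_id, np.int32))

        cr = float(crown_radius(row.height_m))
        length = row.height_m - stem_top
        volume = np.pi * cr**2 * length / 3.0
        n_crown = max(int(round(config.crown_point_density * volume)), 20)
        crown = _sample_cone(rng, n_crown, base + stem_top, base + row.height_m, cr)
        crown[:, 0] += row.x
        crown[:, 1] += row.y
        crown = np.vstack([crown, [row.x, row.y, base + row.height_m]])  # apex
        chunks.append(crown)
        classes.append(np.full(len(crown), TRUE_CROWN, np.uint8))
        tids.append(np.full(len(crown), row.tree_id, np.int32))

    pts = np.vstack(chunks)
    truth.point_class = np.concatenate(classes)
    truth.point_tree_id = np.concatenate(tids)
    return PointCloud(pts[:, 0], pts[:, 1], pts[:, 2])


def generate_regional_inventory(
    config: StandConfig,
    n_plots: int,
    site_index: float = 20.0,
    dominant_species: str = "PIPO",
    pass_fraction: float = 0.6,
    trees_per_plot: int = 30,
    residual_sigma: float = 3.0,
) -> RegionalInventory:
    """Regional plot network whose height-DBH pairs share the stand allometry.

    A configurable fraction of plots is constructed to survive the
    site-comparability filter (site index within +/-2 m, dominant-species
    basal-area share > 0.70); the rest are pushed clearly outside one of
    the two bounds.  Heights span 2-28 m; DBH noise sd is
    ``residual_sigma`` cm (floored at 0.5 cm after noise).
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    rng = np.random.default_rng(config.seed + 202)
    n_pass = int(round(pass_fraction * n_plots))

    plot_rows = []
    tree_rows = []
    for pid in range(1, n_plots + 1):
        if pid <= n_pass:
            si = site_index + rng.uniform(-1.8, 1.8)
            share = rng.uniform(0.72, 0.95)
        elif rng.uniform() < 0.5:
            si = site_index + rng.choice([-1, 1]) * rng.uniform(2.2, 5.0)
            share = rng.uniform(0.72, 0.95)
        else:
            si = site_index + rng.uniform(-1.8, 1.8)
            share = rng.uniform(0.30, 0.68)
        plot_rows.append((pid, si, dominant_species, share))
        plot_rows.append((pid, si, "OTHER", 1.0 - share))
        h = rng.uniform(2.0, 28.0, trees_per_plot)
        d = config.allometry_a * h**config.allometry_b + rng.normal(
            0.0, residual_sigma, trees_per_plot
        )
        d = np.maximum(d, 0.5)
        for hh, dd in zip(h, d):
            tree_rows.append((pid, dominant_species, hh, dd))

    plots = pd.DataFrame(plot_rows, columns=["plot_id", "site_index_m", "species", "ba_share"])
    trees = pd.DataFrame(tree_rows, columns=["plot_id", "species", "height_m", "dbh_cm"])
    return RegionalInventory(plots, trees)
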