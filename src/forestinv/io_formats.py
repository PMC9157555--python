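"""Core geometry carrier and the standard formats the pipeline reads/writes.

The :class:`PointCloud` is the universal container passed between stages:
plain numpy columns for coordinates plus per-point class labels and tree
ids.  Coordinates are projected meters throughout; no geographic CRS math
is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from . import _las
from .errors import EmptyInputError, FormatError

__all__ = [
    "PointClass",
    "PointCloud",
    "TreeList",
    "read_point_cloud",
    "write_point_cloud",
    "write_tree_list",
    "read_tree_list",
]


class PointClass(IntEnum):
    """Per-point semantic label; values track ASPRS where one exists."""

    UNCLASSIFIED = 1
    GROUND = 2
    STEM = 4      # stored as ASPRS medium vegetation on export
    NOISE = 7


@dataclass
class PointCloud:
    """Columns of point coordinates with class labels and optional tree ids.

    Parameters
    ----------
    x, y : ndarray
        Easting / northing in meters (projected CRS).
    z : ndarray
        Elevation in meters, or height above ground once ``normalized``.
    point_class : ndarray of uint8
        :class:`PointClass` codes, one per point.
    tree_id : ndarray of int32
        Positive tree id per point, 0 where unassigned.
    normalized : bool
        True once z is height above ground.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    point_class: np.ndarray = field(default=None)  # type: ignore[assignment]
    tree_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        n = self.x.size
        if not (self.y.size == n and self.z.size == n):
            raise ValueError("x, y, z must have equal length")
        for arr in (self.x, self.y, self.z):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")
        if self.point_class is None:
            self.point_class = np.full(n, int(PointClass.UNCLASSIFIED), np.uint8)
        else:
            self.point_class = np.asarray(self.point_class, np.uint8)
        if self.tree_id is None:
            self.tree_id = np.zeros(n, np.int32)
        else:
            self.tree_id = np.asarray(self.tree_id, np.int32)
        if self.point_class.size != n or self.tree_id.size != n:
            raise ValueError("label arrays must match coordinate length")

    def __len__(self) -> int:
        return int(self.x.size)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or index array, keeping labels and state."""
        return PointCloud(
            self.x[mask],
            self.y[mask],
            self.z[mask],
            self.point_class[mask],
            self.tree_id[mask],
            self.normalized,
        )

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.x.copy(),
            self.y.copy(),
            self.z.copy(),
            self.point_class.copy(),
            self.tree_id.copy(),
            self.normalized,
        )

    @property
    def is_ground(self) -> np.ndarray:
        return self.point_class == PointClass.GROUND


#: Minimum tree height retained anywhere in the pipeline: breast height, m.
BREAST_HEIGHT_M = 1.37


@dataclass
class TreeList:
    """Final per-tree table: location, height and (eventually) DBH.

    Backed by a DataFrame with columns ``tree_id, x, y, height_m, dbh_cm,
    dbh_source``; ``dbh_source`` is "extracted" for circle-fit diameters and
    "modeled" for allometrically filled ones.
    """

    frame: pd.DataFrame

    COLUMNS = ("tree_id", "x", "y", "height_m", "dbh_cm", "dbh_source")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TreeList missing columns: {missing}")
        if len(df):
            if not (df["height_m"] > BREAST_HEIGHT_M).all():
                raise ValueError("every tree must be taller than 1.37 m")
            has_dbh = df["dbh_cm"].notna()
            if not (df.loc[has_dbh, "dbh_cm"] > 0).all():
                raise ValueError("dbh must be positive where present")
            if (has_dbh != df["dbh_source"].notna()).any():
                raise ValueError("dbh_source must be set iff dbh is set")
        self.frame = df.loc[:, list(self.COLUMNS)].sort_values("tree_id").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


def read_point_cloud(path: str | Path) -> PointCloud:
    """Read a point cloud from LAS (or XYZ-CSV fallback) into a PointCloud.

    LAS classification 2 maps to ground; everything else is unclassified.
    The returned cloud is not height-normalized.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".laz":
        raise FormatError("LAZ (compressed) input is not supported; decompress to LAS")
    if suffix == ".las":
        try:
            x, y, z, cls = _las.read_las(path)
        except _las.LasFormatError as exc:
            if "empty" in str(exc):
                raise EmptyInputError(str(exc)) from exc
            raise FormatError(str(exc)) from exc
        point_class = np.where(cls == 2, int(PointClass.GROUND), int(PointClass.UNCLASSIFIED))
        return PointCloud(x, y, z, point_class.astype(np.uint8))
    # XYZ-CSV fallback: columns x,y,z[,classification]
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - any parse failure is a format error
        raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if not {"x", "y", "z"} <= set(cols):
        raise FormatError(f"{path}: XYZ CSV needs x,y,z columns")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: empty point cloud")
    if "classification" in cols:
        cls = df[cols["classification"]].to_numpy()
        point_class = np.where(cls == 2, int(PointClass.GROUND), int(PointClass.UNCLASSIFIED))
    else:
        point_class = np.full(len(df), int(PointClass.UNCLASSIFIED))
    return PointCloud(
        df[cols["x"]].to_numpy(float),
        df[cols["y"]].to_numpy(float),
        df[cols["z"]].to_numpy(float),
        point_class.astype(np.uint8),
    )


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Write a PointCloud to LAS 1.2 (class labels exported as ASPRS codes)."""
    asprs = np.array(cloud.point_class, np.uint8)
    _las.write_las(path, cloud.x, cloud.y, cloud.z, asprs)


def write_tree_list(trees: TreeList, path: str | Path) -> None:
    """Write the tree list to CSV, rows ordered by tree_id."""
    df = trees.frame.copy()
    df = df.sort_values("tree_id")
    df.to_csv(path, index=False, float_format="%.4f")


def read_tree_list(path: str | Path) -> TreeList:
    df = pd.read_csv(path)
    return TreeList(df)
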