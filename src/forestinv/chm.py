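"""Canopy height model: point-to-raster with the highest point per pixel."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import StateError
from .io_formats import PointCloud

DEFAULT_CELL_SIZE = 0.10  # m
NODATA = -9999.0


@dataclass
class HeightRaster:
    """Gridded canopy heights.

    ``values[i, j]`` is the cell with lower-left corner at
    ``(origin_x + j*cell_size, origin_y + i*cell_size)``; row 0 is the
    southernmost row.  Empty cells hold ``nodata``.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = NODATA

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds data."""
        return self.values != self.nodata

    def cell_center(self, i: np.ndarray, j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin_x + (np.asarray(j) + 0.5) * self.cell_size
        y = self.origin_y + (np.asarray(i) + 0.5) * self.cell_size
        return x, y


def rasterize_chm(cloud: PointCloud, cell_size: float = DEFAULT_CELL_SIZE) -> HeightRaster:
    """Grid the normalized cloud: each cell takes the max z of its points.

    Cells are half-open intervals ``[x0 + j*s, x0 + (j+1)*s)``; points on
    the outer max edge fall into the last cell.
    """
    if not cloud.normalized:
        raise StateError("rasterize_chm expects a height-normalized cloud")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if len(cloud) == 0:
        return HeightRaster(0.0, 0.0, cell_size, np.full((1, 1), NODATA))

    x0 = float(cloud.x.min())
    y0 = float(cloud.y.min())
    nx = max(1, int(np.floor((cloud.x.max() - x0) / cell_size)) + 1)
    ny = max(1, int(np.floor((cloud.y.max() - y0) / cell_size)) + 1)

    j = np.minimum((np.floor((cloud.x - x0) / cell_size)).astype(np.int64), nx - 1)
    i = np.minimum((np.floor((cloud.y - y0) / cell_size)).astype(np.int64), ny - 1)

    values = np.full((ny, nx), NODATA)
    np.maximum.at(values, (i, j), cloud.z)
    return HeightRaster(x0, y0, cell_size, values)


def write_chm_geotiff(raster: HeightRaster, path: str | Path) -> None:
    """Write the CHM as a GeoTIFF (north-up, GDAL nodata tag set)."""
    import tifffile

    ny = raster.shape[0]
    data = np.flipud(raster.values).astype(np.float32)  # row 0 = northern edge
    top = raster.origin_y + ny * raster.cell_size
    extratags = [
        # ModelPixelScaleTag
        (33550, "d", 3, (raster.cell_size, raster.cell_size, 0.0)),
        # ModelTiepointTag: raster (0,0) -> (origin_x, top)
        (33922, "d", 6, (0.0, 0.0, 0.0, raster.origin_x, top, 0.0)),
        # GDAL_NODATA (ASCII)
        (42113, "s", 0, str(raster.nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_chm_geotiff(path: str | Path) -> HeightRaster:
    """Read a CHM written by :func:`write_chm_geotiff`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        tags = {t.code: t.value for t in page.tags.values()}
    scale = tags.get(33550, (DEFAULT_CELL_SIZE,))
    cell = float(scale[0])
    tie = tags.get(33922, (0.0, 0.0, 0.0, 0.0, data.shape[0] * cell, 0.0))
    origin_x = float(tie[3])
    top = float(tie[4])
    nodata = float(tags.get(42113, NODATA))
    values = np.flipud(data)
    return HeightRaster(origin_x, top - data.shape[0] * cell, cell, values, nodata)
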