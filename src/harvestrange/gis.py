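"""Planar-grid and vector-I/O helpers shared across the pipeline.

All coordinates are planar meters in a single projected CRS; no geographic
(lon/lat) support. Rasters are boolean class grids or float distance grids on
a regular grid whose row index increases with y (row 0 is the southernmost
row); exported ESRI ASCII grids are flipped to the conventional
north-up row order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid: cell ``(i, j)`` has its center at
    ``(x0 + (j + 0.5) * cell, y0 + (i + 0.5) * cell)``."""

    x0: float
    y0: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and one column")

    @classmethod
    def from_bounds(
        cls, bounds: tuple[float, float, float, float], cell: float, pad: float = 0.0
    ) -> "GridSpec":
        """Smallest grid of ``cell``-sized cells covering ``bounds`` plus ``pad``."""
        if cell <= 0:
            raise ValueError(f"cell size must be positive, got {cell}")
        xmin, ymin, xmax, ymax = bounds
        xmin -= pad
        ymin -= pad
        xmax += pad
        ymax += pad
        ncols = max(1, int(np.ceil((xmax - xmin) / cell)))
        nrows = max(1, int(np.ceil((ymax - ymin) / cell)))
        return cls(x0=xmin, y0=ymin, cell=cell, nrows=nrows, ncols=ncols)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` center-coordinate arrays of shape ``(nrows, ncols)``."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)


def rasterize(geometry: BaseGeometry, grid: GridSpec) -> np.ndarray:
    """Boolean class raster: a cell is in-class iff its center lies inside
    ``geometry`` (cell-center inclusion rule)."""
    out = np.zeros(grid.shape, dtype=bool)
    if geometry is None or geometry.is_empty:
        return out
    xs = grid.x0 + (np.arange(grid.ncols) + 0.5) * grid.cell
    ys = grid.y0 + (np.arange(grid.nrows) + 0.5) * grid.cell
    # test each polygonal part only against the cells in its own bounding
    # box: harvest blocks are small relative to study-area grids
    for part in polygons_of(geometry):
        xmin, ymin, xmax, ymax = part.bounds
        j0, j1 = np.searchsorted(xs, [xmin, xmax])
        i0, i1 = np.searchsorted(ys, [ymin, ymax])
        if i1 <= i0 or j1 <= j0:
            continue
        shapely.prepare(part)
        xw, yw = np.meshgrid(xs[j0:j1], ys[i0:i1])
        hit = shapely.contains_xy(part, xw.ravel(), yw.ravel())
        out[i0:i1, j0:j1] |= hit.reshape(i1 - i0, j1 - j0)
    return out


def polygons_of(geometry: BaseGeometry) -> list:
    """Flatten any geometry into its polygonal parts."""
    if geometry.is_empty:
        return []
    if geometry.geom_type == "Polygon":
        return [geometry]
    if geometry.geom_type in ("MultiPolygon", "GeometryCollection"):
        parts = []
        for g in geometry.geoms:
            parts.extend(polygons_of(g))
        return parts
    return []


def clean_polygons(geoms: Iterable[BaseGeometry]) -> BaseGeometry:
    """Union an iterable of polygons after validity repair."""
    fixed = []
    for g in geoms:
        if g is None or g.is_empty:
            continue
        if not g.is_valid:
            g = shapely.make_valid(g)
        fixed.extend(polygons_of(g))
    if not fixed:
        return shapely.Polygon()
    return shapely.unary_union(fixed)


# ---------------------------------------------------------------------------
# GeoJSON I/O (plain-text vector format; one FeatureCollection per file)
# ---------------------------------------------------------------------------

def write_geojson(path: str | Path, geometries: Sequence[BaseGeometry],
                  properties: Sequence[dict] | None = None) -> None:
    feats = []
    for i, geom in enumerate(geometries):
        props = dict(properties[i]) if properties is not None else {}
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(geom)})
    doc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def read_geojson(path: str | Path) -> tuple[list[BaseGeometry], list[dict]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    geoms, props = [], []
    for feat in doc["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec,
                     nodata: float = -9999.0) -> None:
    """Export a raster as an ESRI ASCII grid (plain text, north-up rows)."""
    header = (
        f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
        f"xllcorner {grid.x0}\nyllcorner {grid.y0}\n"
        f"cellsize {grid.cell}\nNODATA_value {nodata}\n"
    )
    body = np.flipud(np.asarray(values, dtype=float))
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")
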