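"""Harvest-landscape layers and class-level pattern metrics.

Annual harvest-block polygon layers (calendar years of cutting) are
aggregated into 5-year sliding windows that mirror 5-year forest-management
operating plans: the window labelled 1995 is the union of the 1991-1995
annual layers. From a rasterized window we compute

* total class area (km^2),
* mean patch size (ha) under 8-neighbour patch connectivity, and
* the class-level Clumpiness Index (CLUMPY) from like-adjacency
  proportions, in [-1, 1] with -1 maximally disaggregated and +1 maximally
  aggregated,

plus Euclidean distance-to-harvest rasters (center-to-center, meters) used
by the proximity index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .gis import GridSpec, clean_polygons, rasterize, read_geojson

log = logging.getLogger(__name__)

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class HarvestLayer:
    """All blocks cut in one calendar year, as a (multi)polygon in planar
    meters; invalid input geometry is repaired on construction."""

    year: int
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            self.geometry = clean_polygons([self.geometry])

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6


@dataclass(frozen=True)
class AggregatedHarvest:
    label_year: int
    window: tuple[int, int]
    geometry: BaseGeometry
    truncated: bool  # True when the series starts inside the window

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6


@dataclass(frozen=True)
class ClassMetrics:
    total_area_km2: float
    n_patches: int
    mean_patch_size_ha: float  # NaN when no patches
    clumpy: float  # NaN when undefined


def read_harvest_layers(path: str | Path, year_field: str = "year") -> list[HarvestLayer]:
    """Read annual harvest layers from one GeoJSON file whose features carry
    a calendar-year attribute."""
    geoms, props = read_geojson(path)
    by_year: dict[int, list[BaseGeometry]] = {}
    for geom, prop in zip(geoms, props):
        if year_field not in prop:
            raise KeyError(f"feature missing year field {year_field!r} in {path}")
        by_year.setdefault(int(prop[year_field]), []).append(geom)
    return [HarvestLayer(year=y, geometry=clean_polygons(gs))
            for y, gs in sorted(by_year.items())]


def aggregate_sliding(
    layers: Sequence[HarvestLayer], label_year: int, window: int = 5
) -> AggregatedHarvest:
    """Union the annual layers for ``label_year - window + 1 .. label_year``.

    Missing years inside the window are treated as empty (and logged); a
    label year outside the annual series raises ``ValueError``.
    """
    if not layers:
        raise ValueError("no harvest layers supplied")
    years = {layer.year: layer for layer in layers}
    lo, hi = min(years), max(years)
    if not (lo <= label_year <= hi):
        raise ValueError(f"label year {label_year} outside harvest series {lo}-{hi}")
    start = label_year - window + 1
    truncated = start < lo
    members = []
    for y in range(max(start, lo), label_year + 1):
        if y in years:
            members.append(years[y].geometry)
        else:
            log.info("window %d: year %d missing, treated as empty", label_year, y)
    geometry = clean_polygons(members)
    return AggregatedHarvest(
        label_year=label_year, window=(start, label_year),
        geometry=geometry, truncated=truncated,
    )


def distance_raster(class_raster: np.ndarray, cell: float) -> np.ndarray:
    """Exact Euclidean distance (meters, cell center to cell center) from
    every cell to the nearest in-class cell; 0 on class cells."""
    mask = np.asarray(class_raster, dtype=bool)
    if not mask.any():
        raise ValueError("distance raster undefined: no harvest cells")
    return ndimage.distance_transform_edt(~mask, sampling=cell)


def _min_perimeter(n_cells: int) -> int:
    """Minimum cell-face perimeter of a patch of ``n_cells`` grid cells
    (attained by the most square-like arrangement)."""
    m = int(math.floor(math.sqrt(n_cells)))
    if m * m == n_cells:
        return 4 * m
    if n_cells <= m * (m + 1):
        return 4 * m + 2
    return 4 * m + 4


def clumpiness(class_raster: np.ndarray) -> float:
    """Class-level Clumpiness Index from rook like-adjacency proportions.

    With P the class proportion of the landscape and G the like-adjacency
    proportion corrected for the minimum attainable patch perimeter
    (landscape-border faces excluded from the adjacency tally):

        CLUMPY = (G - P) / P        if G < P and P < 0.5
                 (G - P) / (1 - P)  otherwise

    Returns NaN for an empty or full landscape where the index is undefined.
    """
    mask = np.asarray(class_raster, dtype=bool)
    n_class = int(mask.sum())
    n_total = mask.size
    if n_class == 0 or n_class == n_total:
        return float("nan")
    p = n_class / n_total

    like = 0
    total = 0
    # ordered (double-count) adjacencies from class cells, within-grid only
    for a, b in ((mask[:, :-1], mask[:, 1:]), (mask[:-1, :], mask[1:, :])):
        like += int(np.count_nonzero(a & b))
        total += int(np.count_nonzero(a)) + int(np.count_nonzero(b))
    g_ii = 2 * like          # each like adjacency counted from both sides
    edges = total            # each class cell contributes its in-grid faces
    denom = edges - _min_perimeter(n_class)
    if denom <= 0:
        g = g_ii / edges if edges > 0 else 0.0
    else:
        g = g_ii / denom
    if g < p and p < 0.5:
        value = (g - p) / p
    else:
        value = (g - p) / (1.0 - p)
    return float(np.clip(value, -1.0, 1.0))


def class_metrics(class_raster: np.ndarray, cell: float) -> ClassMetrics:
    """Patch count, mean patch size and CLUMPY for one class raster.

    Patches use 8-neighbour connectivity. With no class cells the area
    metrics are zero and mean patch size / CLUMPY are reported missing.
    """
    mask = np.asarray(class_raster, dtype=bool)
    n_class = int(mask.sum())
    total_area_km2 = n_class * cell * cell / 1e6
    if n_class == 0:
        return ClassMetrics(0.0, 0, float("nan"), float("nan"))
    _, n_patches = ndimage.label(mask, structure=EIGHT_CONN)
    mean_patch_ha = (n_class * cell * cell / 1e4) / n_patches
    return ClassMetrics(total_area_km2, n_patches, mean_patch_ha, clumpiness(mask))


def harvest_trend(
    layers: Sequence[HarvestLayer],
    label_years: Sequence[int],
    cell: float = 25.0,
    clip: BaseGeometry | None = None,
    window: int = 5,
) -> pd.DataFrame:
    """Sliding-window class metrics per label year, on one common grid.

    ``clip`` restricts the landscape to a study-area polygon (the grid and
    the landscape proportion P are then defined by the clip polygon's
    extent). Returns one row per label year with total area (km^2), patch
    count, mean patch size (ha), CLUMPY and a truncated-window flag.
    """
    if len(label_years) < 2:
        raise ValueError("need at least two label years for a trend")
    extent = clip if clip is not None else shapely.unary_union(
        [shapely.box(*layer.geometry.bounds) for layer in layers
         if not layer.geometry.is_empty]
    )
    grid = GridSpec.from_bounds(extent.bounds, cell=cell, pad=cell)
    rows = []
    for label_year in sorted(label_years):
        agg = aggregate_sliding(layers, label_year, window=window)
        geom = agg.geometry if clip is None else agg.geometry.intersection(clip)
        metrics = class_metrics(rasterize(geom, grid), cell)
        rows.append(
            {
                "label_year": label_year,
                "window_start": agg.window[0],
                "truncated": agg.truncated,
                "total_area_km2": metrics.total_area_km2,
                "n_patches": metrics.n_patches,
                "mean_patch_size_ha": metrics.mean_patch_size_ha,
                "clumpy": metrics.clumpy,
            }
        )
    return pd.DataFrame(rows)


def percent_change(area_from: float, area_to: float) -> float:
    """Percent change between two window totals, positive for a decline:
    ``100 * (A_from - A_to) / A_from``."""
    if area_from == 0:
        raise ValueError("percent change undefined from a zero baseline")
    return 100.0 * (area_from - area_to) / area_from


def sliding_window_totals(annual_areas: pd.Series, window: int = 5) -> pd.Series:
    """5-year sliding totals from an annual area table (year -> area).

    This is the tabular analogue of :func:`aggregate_sliding` for datasets
    that record only per-year harvested areas (no polygons); overlap between
    years cannot be deduplicated, so window totals are sums.
    """
    s = annual_areas.sort_index()
    years = np.arange(s.index.min() + window - 1, s.index.max() + 1)
    out = {}
    for label in years:
        member = s.loc[(s.index >= label - window + 1) & (s.index <= label)]
        out[int(label)] = float(member.sum())
    return pd.Series(out, name=s.name)
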