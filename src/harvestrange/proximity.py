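"""Observed/expected proximity-to-harvest index for summer locations.

For each summer fix the observed quantity is the Euclidean distance to the
nearest harvest block cut within the preceding decade (0 inside a block;
point-to-polygon, vector-based). The expectation is the mean of a 25 m
distance-to-harvest raster over a reference range:

* population scale — the 100% MCP of all locations in the fix's
  region-period class, buffered outward by 7.5 km;
* annual scale — the animal's 90% kernel range for that biological year.

The index is observed / expected per fix: values above 1 mean the animal
sat farther from recent harvests than the average location available to it
at that scale; under uniform space use within the range the index averages
to 1.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .gis import GridSpec, clean_polygons, rasterize
from .home_range import mcp
from .landscape import HarvestLayer, distance_raster

log = logging.getLogger(__name__)

POPULATION_BUFFER_M = 7500.0
AGE_WINDOW_YEARS = 10
DISTANCE_CELL_M = 25.0


def population_range(points, buffer_m: float = POPULATION_BUFFER_M) -> BaseGeometry:
    """100% MCP of a region-period class's locations, buffered outward."""
    hull = mcp(points).polygon
    return hull.buffer(buffer_m) if buffer_m else hull


def eligible_harvest(
    layers: Sequence[HarvestLayer], year: int, age_window: int = AGE_WINDOW_YEARS
) -> BaseGeometry:
    """Union of blocks cut within ``(year - age_window, year]``."""
    members = [l.geometry for l in layers if year - age_window < l.year <= year]
    return clean_polygons(members)


def expected_distance(
    range_polygon: BaseGeometry, dist: np.ndarray, grid: GridSpec
) -> float:
    """Mean distance-raster value over cells whose centers fall in the range."""
    mask = rasterize(range_polygon, grid)
    if not mask.any():
        raise ValueError("range polygon contains no raster cell centers")
    return float(dist[mask].mean())


def observed_distance(
    x: float, y: float, harvest: BaseGeometry
) -> float | None:
    """Vector distance from a fix to the nearest eligible block edge
    (0 inside); ``None`` when no eligible harvest exists."""
    if harvest is None or harvest.is_empty:
        return None
    return float(shapely.Point(x, y).distance(harvest))


def _subgrid_mask(grid: GridSpec, polygon: BaseGeometry):
    """Cell-center containment mask of ``polygon`` on the subwindow of
    ``grid`` covering its bounds; returns ((i0, i1, j0, j1), mask) or
    ``None`` when no cell center falls inside."""
    xmin, ymin, xmax, ymax = polygon.bounds
    j0 = max(0, int((xmin - grid.x0) / grid.cell) - 1)
    i0 = max(0, int((ymin - grid.y0) / grid.cell) - 1)
    j1 = min(grid.ncols, int(np.ceil((xmax - grid.x0) / grid.cell)) + 1)
    i1 = min(grid.nrows, int(np.ceil((ymax - grid.y0) / grid.cell)) + 1)
    if i1 <= i0 or j1 <= j0:
        return None
    sub = GridSpec(x0=grid.x0 + j0 * grid.cell, y0=grid.y0 + i0 * grid.cell,
                   cell=grid.cell, nrows=i1 - i0, ncols=j1 - j0)
    mask = rasterize(polygon, sub)
    if not mask.any():
        return None
    return (i0, i1, j0, j1), mask


def proximity_index(
    fixes: pd.DataFrame,
    layers: Sequence[HarvestLayer],
    scale: str,
    ranges: Mapping,
    cell: float = DISTANCE_CELL_M,
    age_window: int = AGE_WINDOW_YEARS,
) -> pd.DataFrame:
    """Per-fix proximity records for one scale.

    ``fixes`` must be summer fixes carrying ``animal_id``, ``t``, ``x``,
    ``y``, ``biological_year`` and (population scale) a ``class`` column
    naming the region-period class. ``ranges`` maps the scale's key —
    the class name, or ``(animal_id, biological_year)`` for the annual
    scale — to a range polygon. Fixes with no eligible harvest, outside
    their range's raster, or with no range are skipped and logged.

    One distance field per fix year is built on a grid spanning every
    range polygon plus the year's eligible harvest, so expected distances
    see harvest beyond the range edge, exactly as the per-fix observed
    distances do. Returns one row per eligible fix with observed and
    expected distance (meters) and their ratio.
    """
    if scale not in ("population", "annual"):
        raise ValueError(f"scale must be 'population' or 'annual', got {scale!r}")
    need = {"animal_id", "x", "y", "biological_year"}
    if missing := need - set(fixes.columns):
        raise KeyError(f"fixes missing columns: {sorted(missing)}")

    fixes = fixes.copy()
    if scale == "population":
        fixes["__key"] = fixes["class"]
    else:
        fixes["__key"] = list(zip(fixes["animal_id"],
                                  fixes["biological_year"].astype(int)))
    known = fixes["__key"].isin(set(ranges))
    skipped = {"no_range": int((~known).sum()), "no_harvest": 0,
               "outside_raster": 0}
    fixes = fixes.loc[known]

    records = []
    if not fixes.empty:
        used = sorted(set(fixes["__key"]), key=str)
        bounds = np.array([ranges[k].bounds for k in used])
        years = sorted(set(fixes["biological_year"].astype(int)))
        all_harvest = {y: eligible_harvest(layers, y, age_window) for y in years}
        hb = [g.bounds for g in all_harvest.values() if not g.is_empty]
        total = (
            min([bounds[:, 0].min()] + [b[0] for b in hb]),
            min([bounds[:, 1].min()] + [b[1] for b in hb]),
            max([bounds[:, 2].max()] + [b[2] for b in hb]),
            max([bounds[:, 3].max()] + [b[3] for b in hb]),
        )
        grid = GridSpec.from_bounds(total, cell=cell, pad=cell)
        # range-polygon masks are year-independent: rasterize each once
        masks = {k: _subgrid_mask(grid, ranges[k]) for k in used}
        for year, sub in fixes.groupby(fixes["biological_year"].astype(int)):
            harvest = all_harvest[int(year)]
            if harvest.is_empty:
                skipped["no_harvest"] += len(sub)
                continue
            dist = distance_raster(rasterize(harvest, grid), cell)
            expected = {}
            for k in set(sub["__key"]):
                window = masks[k]
                if window is None:
                    expected[k] = None
                else:
                    (i0, i1, j0, j1), mask = window
                    expected[k] = float(dist[i0:i1, j0:j1][mask].mean())
            blocks = shapely.STRtree(
                [harvest] if harvest.geom_type == "Polygon"
                else list(harvest.geoms))
            pts = shapely.points(sub["x"].to_numpy(dtype=float),
                                 sub["y"].to_numpy(dtype=float))
            idx = blocks.nearest(pts)
            observed = shapely.distance(pts, np.asarray(blocks.geometries)[idx])
            for (key, obs), (_, row) in zip(
                zip(sub["__key"], observed), sub.iterrows()
            ):
                exp = expected[key]
                if exp is None or exp <= 0:
                    skipped["outside_raster"] += 1
                    continue
                records.append({
                    "animal_id": row["animal_id"],
                    "biological_year": int(year),
                    "t": row.get("t"),
                    "class": row.get("class"),
                    "scale": scale,
                    "observed_d": float(obs),
                    "expected_d": exp,
                    "index": float(obs) / exp,
                })
    if any(skipped.values()):
        log.info("proximity_index (%s scale): skipped fixes %s", scale, skipped)
    return pd.DataFrame(
        records,
        columns=["animal_id", "biological_year", "t", "class", "scale",
                 "observed_d", "expected_d", "index"],
    )


def summarize_index(records: pd.DataFrame, by: str = "class",
                    ratio_of_means: bool = False) -> pd.DataFrame:
    """Class mean +/- SE of the proximity index (or ratio of means)."""
    if records.empty:
        return pd.DataFrame(columns=[by, "mean_index", "se_index", "n"])
    def _one(g: pd.DataFrame) -> pd.Series:
        if ratio_of_means:
            m = g["observed_d"].mean() / g["expected_d"].mean()
        else:
            m = g["index"].mean()
        se = g["index"].std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else np.nan
        return pd.Series({"mean_index": m, "se_index": se, "n": len(g)})
    out = records.groupby(by, dropna=False).apply(_one, include_groups=False)
    return out.reset_index()
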