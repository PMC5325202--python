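"""Harvest-exposure covariates attached to each behavioural response row.

Four covariates describe how much recent cutting (blocks under 15 years of
age relative to the row's biological year) surrounds an observation:

* ``CutinHR``     — percent of the animal's 90% kernel range in harvest;
* ``CutHRBuffer`` — percent of the buffer ring around the kernel range in
  harvest; ring width is the square root of the regional mean annual 100%
  MCP area (defaults 21 km west, 37 km east);
* ``CutBuffer``   — percent harvest within the 7.5 km buffer around the
  harvest block nearest to a fix (per fix; proximity responses);
* ``CutPoint``    — mean percent harvest within a regional disc around each
  fidelity fix; disc radius is sqrt(mean MCP area / pi)
  (defaults 12 km west, 21 km east).

All percentages are in [0, 100] and are invariant under rigid translation
of the scene.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .landscape import HarvestLayer
from .gis import clean_polygons, polygons_of

log = logging.getLogger(__name__)

#: ring width around the kernel range, meters, per region (sqrt of the
#: regional mean annual 100% MCP area)
HR_BUFFER_M = {"west": 21_000.0, "east": 37_000.0}
#: per-fix disc radius, meters, per region (sqrt(mean MCP area / pi))
POINT_DISC_M = {"west": 12_000.0, "east": 21_000.0}
CUT_AGE_YEARS = 15
CUTBUFFER_M = 7500.0


def recent_harvest(layers: Sequence[HarvestLayer], biological_year: int,
                   age_years: int = CUT_AGE_YEARS) -> BaseGeometry:
    """Union of blocks cut within the ``age_years`` calendar years up to and
    including ``biological_year``."""
    members = [l.geometry for l in layers
               if biological_year - age_years < l.year <= biological_year]
    return clean_polygons(members)


def pct_harvest_in(polygon: BaseGeometry, harvest: BaseGeometry) -> float:
    """Percent of ``polygon`` covered by ``harvest``."""
    if polygon is None or polygon.is_empty or polygon.area == 0:
        raise ValueError("percent cover undefined for an empty polygon")
    if harvest is None or harvest.is_empty:
        return 0.0
    return 100.0 * polygon.intersection(harvest).area / polygon.area


def hr_buffer_ring(range_polygon: BaseGeometry, region: str,
                   buffer_m: Mapping[str, float] | None = None,
                   mean_mcp_km2: float | None = None) -> BaseGeometry:
    """Buffer ring around a kernel range: (range ⊕ d) minus the range.

    ``d`` is the regional default unless ``mean_mcp_km2`` is given, in which
    case it is recomputed as sqrt of that area.
    """
    if mean_mcp_km2 is not None:
        d = math.sqrt(mean_mcp_km2) * 1000.0
    else:
        d = (buffer_m or HR_BUFFER_M)[region]
    return range_polygon.buffer(d).difference(range_polygon)


def point_disc_radius(mean_mcp_km2: float) -> float:
    """Disc radius (km) whose circle has the mean 100% MCP area."""
    if mean_mcp_km2 <= 0:
        raise ValueError("mean MCP area must be positive")
    return math.sqrt(mean_mcp_km2 / math.pi)


def cut_buffer(x: float, y: float, harvest: BaseGeometry,
               buffer_m: float = CUTBUFFER_M) -> float | None:
    """Percent harvest within the buffer around the block nearest a fix.

    Returns ``None`` (missing) when no eligible harvest exists in the scene.
    """
    blocks = polygons_of(harvest) if harvest is not None else []
    if not blocks:
        return None
    pt = shapely.Point(x, y)
    nearest = min(blocks, key=pt.distance)
    zone = nearest.buffer(buffer_m)
    return pct_harvest_in(zone, harvest)


def cut_point(fixes_xy: np.ndarray, harvest: BaseGeometry,
              radius_m: float) -> float | None:
    """Mean percent harvest within the per-fix disc, over the given fixes."""
    if len(fixes_xy) == 0:
        return None
    blocks = polygons_of(harvest) if harvest is not None else []
    tree = shapely.STRtree(blocks) if blocks else None
    vals = []
    for x, y in np.asarray(fixes_xy, dtype=float):
        disc = shapely.Point(x, y).buffer(radius_m, quad_segs=32)
        if tree is None:
            vals.append(0.0)
            continue
        near = tree.query(disc)  # blocks are disjoint after union
        cut = sum(blocks[i].intersection(disc).area for i in near)
        vals.append(100.0 * cut / disc.area)
    return float(np.mean(vals))


class CutBufferCalculator:
    """Per-fix CutBuffer with caching by nearest-block identity.

    The covariate depends only on which block is nearest and on the year's
    eligible-harvest union, so values are computed once per (year, block)
    and looked up via an STRtree nearest-neighbour query.
    """

    def __init__(self, layers: Sequence[HarvestLayer],
                 age_years: int = CUT_AGE_YEARS, buffer_m: float = CUTBUFFER_M):
        self.layers = list(layers)
        self.age_years = age_years
        self.buffer_m = buffer_m
        self._scenes: dict[int, tuple] = {}
        self._cache: dict[tuple[int, int], float] = {}

    def _scene(self, year: int):
        if year not in self._scenes:
            harvest = recent_harvest(self.layers, year, self.age_years)
            blocks = polygons_of(harvest)
            tree = shapely.STRtree(blocks) if blocks else None
            self._scenes[year] = (harvest, blocks, tree)
        return self._scenes[year]

    def __call__(self, x: float, y: float, biological_year: int) -> float | None:
        harvest, blocks, tree = self._scene(int(biological_year))
        if tree is None:
            return None
        idx = int(tree.nearest(shapely.Point(x, y)))
        key = (int(biological_year), idx)
        if key not in self._cache:
            zone = blocks[idx].buffer(self.buffer_m)
            self._cache[key] = pct_harvest_in(zone, harvest)
        return self._cache[key]


def covariates_for_range(
    range_polygon: BaseGeometry,
    region: str,
    biological_year: int,
    layers: Sequence[HarvestLayer],
    age_years: int = CUT_AGE_YEARS,
    buffer_m: Mapping[str, float] | None = None,
) -> dict:
    """CutinHR and CutHRBuffer for one animal-year kernel range."""
    harvest = recent_harvest(layers, biological_year, age_years)
    ring = hr_buffer_ring(range_polygon, region, buffer_m=buffer_m)
    return {
        "CutinHR": pct_harvest_in(range_polygon, harvest),
        "CutHRBuffer": pct_harvest_in(ring, harvest),
    }


def covariates_for_fix(
    x: float, y: float, biological_year: int,
    layers: Sequence[HarvestLayer],
    age_years: int = CUT_AGE_YEARS,
    buffer_m: float = CUTBUFFER_M,
) -> dict:
    """CutBuffer for one proximity fix (missing when no recent harvest)."""
    harvest = recent_harvest(layers, biological_year, age_years)
    return {"CutBuffer": cut_buffer(x, y, harvest, buffer_m)}


def cutpoint_for_animal(
    fixes: pd.DataFrame, region: str,
    layers: Sequence[HarvestLayer],
    radius_m: Mapping[str, float] | None = None,
    age_years: int = CUT_AGE_YEARS,
) -> float | None:
    """CutPoint for one animal: mean per-fix disc percentage over its
    fidelity fixes (grouped by biological year for harvest aging)."""
    radius = (radius_m or POINT_DISC_M)[region]
    vals = []
    for year, sub in fixes.groupby("biological_year"):
        harvest = recent_harvest(layers, int(year), age_years)
        v = cut_point(sub[["x", "y"]].to_numpy(dtype=float), harvest, radius)
        if v is not None:
            vals.extend([v] * len(sub))
    return float(np.mean(vals)) if vals else None
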