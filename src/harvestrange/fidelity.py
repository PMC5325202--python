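"""Summer site-fidelity index against an all-pairs null expectation.

Locations recorded on the same calendar day in consecutive-year summers
(e.g. July 1st of year t and year t+1) are paired and the distance between
each pair measured; an animal's paired mean pools those distances over all
its consecutive-year pairs. The null expectation for a region-period class
is the mean distance between all possible pairs of summer locations pooled
over the class's collared animals, computed per summer year and then
averaged across years. The fidelity index is

    index = null_mean / paired_mean

so values above 1 indicate returning closer to previously used locations
than expected under no fidelity, and values below 1 indicate moving farther
than expected.

Only animal-summers with at least 10 locations spread across every month of
the summer window (May through mid-September) enter the index. For days
with several fixes the representative fix is the one nearest local noon
(deterministic, and robust to the ARGOS-daily vs GPS-subdaily schedules).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

MIN_SUMMER_POINTS = 10
SUMMER_MONTHS = (5, 6, 7, 8, 9)


def summer_fixes(fixes: pd.DataFrame) -> pd.DataFrame:
    """Subset to summer-season fixes (requires a ``season`` column)."""
    return fixes.loc[fixes["season"] == "Summer"].copy()


def eligibility(
    summer: pd.DataFrame,
    min_points: int = MIN_SUMMER_POINTS,
    months: Iterable[int] = SUMMER_MONTHS,
) -> bool:
    """One animal-summer qualifies iff it has >= ``min_points`` fixes and at
    least one fix in every month of the summer window."""
    if len(summer) < min_points:
        return False
    present = set(pd.DatetimeIndex(summer["t"]).month)
    return all(m in present for m in months)


def representative_daily(summer: pd.DataFrame) -> pd.DataFrame:
    """One fix per day-of-year: the fix nearest 12:00 local time."""
    t = pd.DatetimeIndex(summer["t"])
    df = summer.assign(
        _doy=t.dayofyear,
        _noon_off=np.abs(
            (t - t.normalize()) / pd.Timedelta(hours=1) - 12.0
        ),
    )
    df = df.sort_values(["_doy", "_noon_off"], kind="mergesort")
    out = df.drop_duplicates("_doy", keep="first")
    return out.drop(columns=["_noon_off"]).rename(columns={"_doy": "doy"})


def paired_distances(track: pd.DataFrame) -> pd.DataFrame:
    """Same-day consecutive-year summer distances for one animal.

    ``track`` must carry ``t``, ``x``, ``y``, ``season``,
    ``biological_year``. Returns one row per matched day with the year pair
    and distance (meters), pooled over all consecutive-year pairs. Summers
    failing the eligibility rule are excluded.
    """
    summers = {
        int(year): representative_daily(sub)
        for year, sub in summer_fixes(track).groupby("biological_year")
        if eligibility(sub)
    }
    rows = []
    for year in sorted(summers):
        if year + 1 not in summers:
            continue
        a = summers[year].set_index("doy")
        b = summers[year + 1].set_index("doy")
        common = a.index.intersection(b.index)
        for doy in common:
            d = float(np.hypot(a.loc[doy, "x"] - b.loc[doy, "x"],
                               a.loc[doy, "y"] - b.loc[doy, "y"]))
            rows.append({"year": year, "next_year": year + 1,
                         "doy": int(doy), "distance_m": d})
    return pd.DataFrame(rows, columns=["year", "next_year", "doy", "distance_m"])


def _mean_pairwise(points: np.ndarray, max_exact: int = 6000,
                   rng: np.random.Generator | None = None) -> float:
    """Mean distance over all unordered point pairs; exact up to
    ``max_exact`` points, subsampled (logged) beyond that."""
    n = len(points)
    if n > max_exact:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(n, size=max_exact, replace=False)
        log.info("null distance: subsampled %d of %d fixes", max_exact, n)
        points = points[idx]
    return float(pdist(points).mean())


def null_distance(class_fixes: pd.DataFrame, max_exact: int = 6000) -> float:
    """Class-level null: per summer year the mean over all possible pairs of
    locations pooled across animals, then the mean of those per-year values.

    The pooling order is fixed — per-year means first, then across years —
    so years with different fix counts weigh equally.
    """
    summer = summer_fixes(class_fixes)
    per_year = []
    for year, sub in summer.groupby("biological_year"):
        if len(sub) < 2:
            log.info("null distance: year %s has <2 fixes, skipped", year)
            continue
        pts = sub[["x", "y"]].to_numpy(dtype=float)
        per_year.append(_mean_pairwise(pts, max_exact))
    if not per_year:
        raise ValueError("null distance undefined: no summer year with >= 2 fixes")
    return float(np.mean(per_year))


def fidelity_index(
    tracks: pd.DataFrame,
    class_label: str | None = None,
    min_points: int = MIN_SUMMER_POINTS,
    max_exact: int = 6000,
) -> pd.DataFrame:
    """Per-animal fidelity records for one region-period class.

    Returns one row per animal with >= 1 matched day: pooled paired mean,
    the class null mean, their ratio (null / paired), and the pair count.
    Animals whose paired mean is zero (identical coordinates) are flagged
    with a missing index and excluded from class summaries downstream.
    """
    null_mean = null_distance(tracks, max_exact=max_exact)
    rows = []
    for animal, track in tracks.groupby("animal_id", sort=False):
        pairs = paired_distances(track)
        if pairs.empty:
            log.info("fidelity: animal %s has no matchable days, excluded", animal)
            continue
        paired_mean = float(pairs["distance_m"].mean())
        index = null_mean / paired_mean if paired_mean > 0 else np.nan
        if paired_mean == 0:
            log.warning("fidelity: animal %s paired mean is 0; index undefined", animal)
        rows.append(
            {
                "animal_id": animal,
                "class": class_label,
                "paired_mean_m": paired_mean,
                "null_mean_m": null_mean,
                "index": index,
                "n_pairs": len(pairs),
            }
        )
    return pd.DataFrame(
        rows, columns=["animal_id", "class", "paired_mean_m", "null_mean_m",
                       "index", "n_pairs"],
    )
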