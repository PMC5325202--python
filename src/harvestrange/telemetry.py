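"""Telemetry ingestion, quality filtering, and season / biological-year labels.

Fixes live in a pandas DataFrame with the columns

    animal_id, t, x, y, collar, loc_class, region, period

``collar`` is ``"ARGOS"`` or ``"GPS"``; ``loc_class`` is one of
``3, 2, 1, 0, A, B, Z`` (as strings) for ARGOS fixes and missing for GPS.
Coordinates are planar meters. ARGOS screening keeps location classes 3/2/1
and drops fixes whose implied straight-line speed to both temporal
neighbours exceeds a maximum plausible travel rate.

The biological year runs May 1 - April 30, anchored to the onset of calving;
seasons are Winter (Nov 16 - Feb 15), Spring (Feb 16 - Apr 30),
Summer (May 1 - Sep 15) and Fall (Sep 16 - Nov 15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")
#: classes retained by the quality screen (3 best, then 2, 1, 0, A, B, Z)
GOOD_CLASSES = frozenset({"3", "2", "1"})

COLUMNS = ["animal_id", "t", "x", "y", "collar", "loc_class", "region", "period"]


@dataclass(frozen=True)
class SeasonCalendar:
    """Season boundaries as (month, day) start dates; seasons partition the
    year with no gap or overlap. The biological year starts with Summer."""

    summer_start: tuple[int, int] = (5, 1)
    fall_start: tuple[int, int] = (9, 16)
    winter_start: tuple[int, int] = (11, 16)
    spring_start: tuple[int, int] = (2, 16)

    @property
    def starts(self) -> list[tuple[tuple[int, int], str]]:
        return sorted(
            [
                (self.spring_start, "Spring"),
                (self.summer_start, "Summer"),
                (self.fall_start, "Fall"),
                (self.winter_start, "Winter"),
            ]
        )

    def season_of(self, month: int, day: int) -> str:
        md = (month, day)
        starts = self.starts
        # before the first boundary of the calendar year -> season wrapping
        # over New Year (the one starting at the latest boundary)
        current = starts[-1][1]
        for start, name in starts:
            if md >= start:
                current = name
        return current

    def biological_year(self, ts: pd.Timestamp) -> int:
        start = self.summer_start
        return ts.year if (ts.month, ts.day) >= start else ts.year - 1


DEFAULT_CALENDAR = SeasonCalendar()


def read_telemetry(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited-text telemetry table into the canonical fix frame.

    ``column_map`` maps canonical names (``animal_id, t, x, y, collar`` and
    optionally ``loc_class, region, period``) to the file's column names.
    Rows with an unparseable timestamp or non-finite coordinates are rejected
    with a warning; a missing required column is a fatal configuration error.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, sep=sep)
    required = ["animal_id", "t", "x", "y", "collar"]
    optional = ["loc_class", "region", "period"]
    rename = {}
    for canon in required + optional:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in required:
            raise KeyError(
                f"required telemetry column {canon!r} (mapped to {src!r}) "
                f"not found in {path}"
            )
    df = raw.rename(columns=rename)
    for canon in optional:
        if canon not in df.columns:
            df[canon] = pd.NA

    n_raw = len(df)
    df["t"] = pd.to_datetime(df["t"], errors="coerce", format="ISO8601")
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    ok = df["t"].notna() & np.isfinite(df["x"]) & np.isfinite(df["y"])
    n_rejected = int((~ok).sum())
    if n_rejected:
        log.warning("%s: rejected %d of %d rows (bad timestamp or coordinates)",
                    path, n_rejected, n_raw)
    df = df.loc[ok].copy()

    df["collar"] = df["collar"].astype(str).str.upper()
    bad_collar = ~df["collar"].isin(["ARGOS", "GPS"])
    if bad_collar.any():
        raise ValueError(f"unknown collar types: {sorted(df.loc[bad_collar, 'collar'].unique())}")

    # GPS fixes carry no ARGOS location class; drop any stray value.
    df["loc_class"] = df["loc_class"].astype("object")
    stray = (df["collar"] == "GPS") & df["loc_class"].notna()
    if stray.any():
        log.warning("%s: ignoring loc_class on %d GPS rows", path, int(stray.sum()))
        df.loc[stray, "loc_class"] = pd.NA
    is_argos = df["collar"] == "ARGOS"

    def _norm_lc(v):  # "3", 3, 3.0 all mean class 3
        s = str(v).strip().upper()
        try:
            return str(int(float(s)))
        except ValueError:
            return s

    df.loc[is_argos, "loc_class"] = df.loc[is_argos, "loc_class"].map(_norm_lc)
    bad_lc = is_argos & ~df["loc_class"].isin(ARGOS_CLASSES)
    if bad_lc.any():
        raise ValueError(
            f"ARGOS rows with missing/unknown location class: {int(bad_lc.sum())}"
        )

    log.info("%s: parsed %d fixes (%d rows rejected)", path, len(df), n_rejected)
    df = df.sort_values(["animal_id", "t"], kind="mergesort").reset_index(drop=True)
    return df[[c for c in COLUMNS if c in df.columns]]


def _speed_flags(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                 max_speed_m_day: float) -> np.ndarray:
    """True where an interior fix is aberrant: its implied speed to both
    temporal neighbours exceeds ``max_speed_m_day``."""
    n = len(t)
    if n < 2:
        return np.zeros(n, dtype=bool)
    days = (t[1:] - t[:-1]) / np.timedelta64(1, "D")
    dist = np.hypot(x[1:] - x[:-1], y[1:] - y[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = np.where(days > 0, dist / days, np.inf)
    fast_prev = np.concatenate([[False], speed > max_speed_m_day])
    fast_next = np.concatenate([speed > max_speed_m_day, [False]])
    has_prev = np.arange(n) > 0
    has_next = np.arange(n) < n - 1
    # only interior fixes can be judged against both neighbours; track
    # endpoints are kept (a single fast segment does not identify which
    # of its two fixes is aberrant)
    return has_prev & has_next & fast_prev & fast_next


def filter_argos(fixes: pd.DataFrame, max_speed_km_day: float = 50.0) -> pd.DataFrame:
    """Quality-screen ARGOS fixes; GPS fixes pass untouched.

    Keeps ARGOS location classes 3/2/1 only, then iteratively removes fixes
    whose straight-line speed to both temporal neighbours (one neighbour at a
    track end) exceeds ``max_speed_km_day``. Iterating to a fixed point makes
    the screen idempotent even for runs of consecutive outliers.
    """
    if fixes.empty:
        return fixes.copy()
    is_argos = fixes["collar"] == "ARGOS"
    keep_class = ~is_argos | fixes["loc_class"].isin(GOOD_CLASSES)
    df = fixes.loc[keep_class].copy()
    max_speed = max_speed_km_day * 1000.0

    gps = df.loc[df["collar"] != "ARGOS"]
    argos = df.loc[df["collar"] == "ARGOS"]
    kept_parts = [gps]
    n_removed = 0
    for _, track in argos.groupby("animal_id", sort=False):
        track = track.sort_values("t", kind="mergesort")
        while len(track) > 1:
            bad = _speed_flags(
                track["t"].to_numpy(), track["x"].to_numpy(dtype=float),
                track["y"].to_numpy(dtype=float), max_speed,
            )
            if not bad.any():
                break
            n_removed += int(bad.sum())
            track = track.loc[~bad]
        kept_parts.append(track)
    if n_removed:
        log.info("speed filter removed %d aberrant ARGOS fixes", n_removed)
    out = pd.concat(kept_parts).sort_values(["animal_id", "t"], kind="mergesort")
    return out.reset_index(drop=True)


def assign_season(
    fixes: pd.DataFrame, cal: SeasonCalendar = DEFAULT_CALENDAR
) -> pd.DataFrame:
    """Add ``season`` and ``biological_year`` columns (vectorised)."""
    df = fixes.copy()
    t = pd.DatetimeIndex(df["t"])
    md = list(zip(t.month, t.day))
    df["season"] = [cal.season_of(m, d) for m, d in md]
    start = cal.summer_start
    df["biological_year"] = np.where(
        [pair >= start for pair in md], t.year, t.year - 1
    )
    return df


def assign_period(
    fixes: pd.DataFrame,
    early_years: tuple[int, int] = (1995, 2001),
    late_years: tuple[int, int] = (2009, 2013),
) -> pd.DataFrame:
    """Label management period (early/late) from the fix's calendar year.

    Fixes outside both windows keep a missing period and are excluded from
    period-stratified analyses.
    """
    df = fixes.copy()
    year = pd.DatetimeIndex(df["t"]).year
    period = np.full(len(df), None, dtype=object)
    period[(year >= early_years[0]) & (year <= early_years[1])] = "early"
    period[(year >= late_years[0]) & (year <= late_years[1])] = "late"
    df["period"] = period
    return df
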