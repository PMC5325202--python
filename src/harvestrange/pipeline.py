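"""End-to-end orchestration: telemetry -> landscape -> ranges -> indices
-> covariates -> models, with file-based stage composition.

Every stage writes plain-text artifacts (CSV, GeoJSON) into the run
directory and can reload them, so the CLI subcommands compose to the same
result as a single ``all`` run. Output CSVs carry a provenance header
comment (package version, config hash, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__
from . import covariates as cov
from . import fidelity as fid
from . import home_range as hr
from . import landscape as ls
from . import models as mdl
from . import proximity as prox
from . import telemetry as tel
from .gis import read_geojson, write_geojson

log = logging.getLogger(__name__)

CLASSES = ("west_early", "east_early", "west_late", "east_late")


@dataclass
class RunConfig:
    """Declarative run configuration; defaults follow the study protocol
    (25 m cells, 7.5 km population buffer, 65-location/1000-draw bootstrap,
    >=50-location annual ranges, >=10-location summer eligibility, delta
    AICc < 2 averaging)."""

    telemetry_path: str = "telemetry.csv"
    harvest_paths: dict[str, str] = field(default_factory=dict)  # region -> file
    regions_path: Optional[str] = None
    outdir: str = "run"
    seed: int = 0

    early_years: tuple[int, int] = (1995, 2001)
    late_years: tuple[int, int] = (2009, 2013)
    max_speed_km_day: float = 50.0

    metrics_cell_m: float = 25.0
    distance_cell_m: float = 25.0
    label_years: Optional[list[int]] = None

    kde_grid_size: int = 200
    min_kde_locations: int = 50
    bootstrap_m: int = 65
    bootstrap_iters: int = 1000

    population_buffer_m: float = 7500.0
    proximity_age_window: int = 10
    cut_age_years: int = 15
    hr_buffer_m: dict[str, float] = field(
        default_factory=lambda: dict(cov.HR_BUFFER_M))
    point_disc_m: dict[str, float] = field(
        default_factory=lambda: dict(cov.POINT_DISC_M))

    sqrt_transform: dict[str, bool] = field(default_factory=lambda: {
        "home_range_area": True, "proximity_population": False,
        "proximity_annual": False, "fidelity": True,
    })
    averaging_threshold: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config fields: {sorted(unknown)}")
        for key in ("early_years", "late_years"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output directory does not
        affect results and is excluded)."""
        doc = dataclasses.asdict(self)
        doc.pop("outdir")
        doc = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:12]


class Pipeline:
    """Stage runner; holds in-memory state and mirrors it to disk."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.fixes: pd.DataFrame | None = None
        self.layers: dict[str, list[ls.HarvestLayer]] | None = None
        self.ranges: pd.DataFrame | None = None
        self.range_polys: dict[tuple, shapely.Geometry] | None = None

    # -- provenance-aware CSV I/O ---------------------------------------

    def _write_csv(self, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        header = (f"# harvestrange {__version__} config={self.cfg.config_hash()} "
                  f"seed={self.cfg.seed}\n")
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        return path

    def _read_csv(self, name: str, **kw) -> pd.DataFrame:
        return pd.read_csv(self.outdir / name, comment="#", **kw)

    # -- stages ---------------------------------------------------------

    def stage_telemetry(self) -> pd.DataFrame:
        df = tel.read_telemetry(self.cfg.telemetry_path)
        df = tel.filter_argos(df, max_speed_km_day=self.cfg.max_speed_km_day)
        df = tel.assign_season(df)
        df = tel.assign_period(df, self.cfg.early_years, self.cfg.late_years)
        df = df.loc[df["period"].notna() & df["region"].notna()].copy()
        df["class"] = df["region"].astype(str) + "_" + df["period"].astype(str)
        self.fixes = df
        out = df.copy()
        out["t"] = pd.DatetimeIndex(out["t"]).strftime("%Y-%m-%dT%H:%M:%S")
        self._write_csv(out, "fixes.csv")
        return df

    def _load_fixes(self) -> pd.DataFrame:
        if self.fixes is None:
            df = self._read_csv("fixes.csv")
            df["t"] = pd.to_datetime(df["t"])
            self.fixes = df
        return self.fixes

    def _load_layers(self) -> dict[str, list[ls.HarvestLayer]]:
        if self.layers is None:
            self.layers = {
                region: ls.read_harvest_layers(path)
                for region, path in self.cfg.harvest_paths.items()
            }
        return self.layers

    def stage_landscape(self) -> pd.DataFrame:
        layers = self._load_layers()
        frames = []
        for region, lyrs in sorted(layers.items()):
            years = sorted({l.year for l in lyrs})
            label_years = self.cfg.label_years or [
                y for y in years if y >= min(years) + 4
            ]
            trend = ls.harvest_trend(lyrs, label_years,
                                     cell=self.cfg.metrics_cell_m)
            trend.insert(0, "region", region)
            frames.append(trend)
        out = pd.concat(frames, ignore_index=True)
        self._write_csv(out, "harvest_trend.csv")
        return out

    def stage_ranges(self) -> pd.DataFrame:
        fixes = self._load_fixes()
        rows, geoms, props = [], [], []
        self.range_polys = {}
        rng = np.random.default_rng(self.cfg.seed)
        for (animal, year), sub in fixes.groupby(["animal_id", "biological_year"]):
            pts = sub[["x", "y"]].to_numpy(dtype=float)
            if len(pts) < self.cfg.min_kde_locations:
                continue
            klass = sub["class"].iloc[0]
            period = sub["period"].iloc[0]
            mcp_est = hr.mcp(pts)
            kde_est = hr.kde_range(
                pts, grid_size=self.cfg.kde_grid_size,
                min_locations=self.cfg.min_kde_locations,
            )
            if period == "late" and len(pts) >= self.cfg.bootstrap_m:
                boot = hr.bootstrap_range(
                    pts, m=self.cfg.bootstrap_m, iters=self.cfg.bootstrap_iters,
                    seed=np.random.default_rng(rng.integers(2**31)),
                )
                area, method = boot.area_km2, boot.method
                area_sd = boot.area_sd_km2
            else:
                area, method = kde_est.area_km2, kde_est.method
                area_sd = np.nan
            rows.append({
                "animal_id": animal, "biological_year": int(year),
                "class": klass, "region": sub["region"].iloc[0],
                "period": period, "method": method,
                "area_km2": area, "area_sd_km2": area_sd,
                "kde90_area_km2": kde_est.area_km2,
                "mcp_area_km2": mcp_est.area_km2,
                "n_locations": len(pts), "h_m": kde_est.h,
            })
            key = (animal, int(year))
            self.range_polys[key] = kde_est.polygon
            geoms.append(kde_est.polygon)
            props.append({"animal_id": animal, "biological_year": int(year)})
        if not rows:
            raise RuntimeError("no animal-year met the minimum-location rule")
        out = pd.DataFrame(rows)
        self.ranges = out
        self._write_csv(out, "ranges.csv")
        write_geojson(self.outdir / "range_polygons.geojson", geoms, props)
        return out

    def _load_ranges(self) -> pd.DataFrame:
        if self.ranges is None:
            self.ranges = self._read_csv("ranges.csv")
        if self.range_polys is None:
            geoms, props = read_geojson(self.outdir / "range_polygons.geojson")
            self.range_polys = {
                (p["animal_id"], int(p["biological_year"])): g
                for g, p in zip(geoms, props)
            }
        return self.ranges

    def _summer_fixes(self) -> pd.DataFrame:
        fixes = self._load_fixes()
        return fixes.loc[fixes["season"] == "Summer"].copy()

    def stage_proximity(self) -> dict[str, pd.DataFrame]:
        summer = self._summer_fixes()
        layers = self._load_layers()
        self._load_ranges()
        results = {}
        for scale in ("population", "annual"):
            frames = []
            for region, lyrs in sorted(layers.items()):
                sub = summer.loc[summer["region"] == region]
                if sub.empty:
                    continue
                if scale == "population":
                    ranges = {
                        klass: prox.population_range(
                            g[["x", "y"]].to_numpy(dtype=float),
                            self.cfg.population_buffer_m,
                        )
                        for klass, g in sub.groupby("class") if len(g) >= 3
                    }
                else:
                    ranges = {
                        key: poly for key, poly in self.range_polys.items()
                        if key[0] in set(sub["animal_id"])
                    }
                frames.append(prox.proximity_index(
                    sub, lyrs, scale, ranges,
                    cell=self.cfg.distance_cell_m,
                    age_window=self.cfg.proximity_age_window,
                ))
            records = pd.concat(frames, ignore_index=True)
            out = records.copy()
            if "t" in out.columns:
                out["t"] = pd.DatetimeIndex(out["t"]).strftime("%Y-%m-%dT%H:%M:%S")
            self._write_csv(out, f"proximity_{scale}.csv")
            self._write_csv(prox.summarize_index(records),
                            f"proximity_{scale}_summary.csv")
            results[scale] = records
        return results

    def stage_fidelity(self) -> pd.DataFrame:
        fixes = self._load_fixes()
        frames = []
        for klass, sub in fixes.groupby("class"):
            try:
                frames.append(fid.fidelity_index(sub, class_label=klass))
            except ValueError as err:
                log.warning("fidelity for class %s skipped: %s", klass, err)
        out = pd.concat(frames, ignore_index=True)
        self._write_csv(out, "fidelity.csv")
        return out

    # -- covariates and model rows --------------------------------------

    def stage_covariates(self) -> dict[str, pd.DataFrame]:
        layers = self._load_layers()
        ranges = self._load_ranges()

        range_cov = []
        for _, row in ranges.iterrows():
            poly = self.range_polys.get((row["animal_id"], int(row["biological_year"])))
            if poly is None or poly.is_empty:
                continue
            c = cov.covariates_for_range(
                poly, row["region"], int(row["biological_year"]),
                layers[row["region"]], age_years=self.cfg.cut_age_years,
                buffer_m=self.cfg.hr_buffer_m,
            )
            range_cov.append({
                "animal_id": row["animal_id"],
                "biological_year": int(row["biological_year"]),
                **c,
            })
        range_cov = pd.DataFrame(range_cov)

        hr_rows = ranges.merge(range_cov, on=["animal_id", "biological_year"])
        hr_rows = hr_rows.rename(columns={"area_km2": "response",
                                          "class": "Group"})
        hr_rows = hr_rows[["animal_id", "biological_year", "Group", "response",
                           "CutinHR", "CutHRBuffer"]]
        self._write_csv(hr_rows, "model_rows_home_range_area.csv")

        outputs = {"home_range_area": hr_rows}
        calculators = {
            region: cov.CutBufferCalculator(
                lyrs, age_years=self.cfg.cut_age_years)
            for region, lyrs in layers.items()
        }
        for scale in ("population", "annual"):
            recs = self._read_csv(f"proximity_{scale}.csv")
            recs["t"] = pd.to_datetime(recs["t"])
            fixes = self._summer_fixes()
            merged = recs.merge(
                fixes[["animal_id", "t", "x", "y", "region"]],
                on=["animal_id", "t"], how="left",
            )
            if merged["class"].isna().all():
                merged["class"] = (
                    merged["region"] + "_" +
                    merged["animal_id"].map(
                        fixes.drop_duplicates("animal_id")
                        .set_index("animal_id")["period"])
                )
            merged["CutBuffer"] = [
                calculators[r](x, y, by) if isinstance(r, str) else np.nan
                for r, x, y, by in zip(merged["region"], merged["x"],
                                       merged["y"], merged["biological_year"])
            ]
            merged = merged.merge(range_cov, on=["animal_id", "biological_year"],
                                  how="left")
            rows = merged.rename(columns={"index": "response", "class": "Group"})
            rows = rows[["animal_id", "biological_year", "Group", "response",
                         "CutinHR", "CutHRBuffer", "CutBuffer"]]
            name = f"proximity_{scale}"
            self._write_csv(rows, f"model_rows_{name}.csv")
            outputs[name] = rows

        fixes = self._load_fixes()
        fid_tab = self._read_csv("fidelity.csv")
        cut_points = []
        for _, row in fid_tab.iterrows():
            animal = row["animal_id"]
            sub = fixes.loc[(fixes["animal_id"] == animal)
                            & (fixes["season"] == "Summer")]
            eligible = [
                fid.representative_daily(s)
                for _, s in sub.groupby("biological_year") if fid.eligibility(s)
            ]
            region = sub["region"].iloc[0]
            value = None
            if eligible:
                value = cov.cutpoint_for_animal(
                    pd.concat(eligible), region, layers[region],
                    radius_m=self.cfg.point_disc_m,
                    age_years=self.cfg.cut_age_years,
                )
            cut_points.append(value)
        fid_rows = fid_tab.rename(columns={"index": "response",
                                           "class": "Group"})
        fid_rows["CutPoint"] = cut_points
        fid_rows = fid_rows[["animal_id", "Group", "response", "CutPoint"]]
        self._write_csv(fid_rows, "model_rows_fidelity.csv")
        outputs["fidelity"] = fid_rows
        return outputs

    # -- models ----------------------------------------------------------

    def stage_models(self) -> dict[str, mdl.SelectionResults]:
        results = {}
        for response in ("home_range_area", "proximity_population",
                         "proximity_annual", "fidelity"):
            rows = self._read_csv(f"model_rows_{response}.csv")
            rows = rows.loc[rows["response"].notna()]
            cs = mdl.CandidateSet.for_response(
                response, sqrt_transform=self.cfg.sqrt_transform.get(response, False))
            try:
                res = cs.fit(rows)
            except Exception as err:
                log.warning("model selection for %s failed: %s", response, err)
                continue
            results[response] = res
            self._write_csv(res.table, f"model_selection_{response}.csv")
            avg = res.average_top(self.cfg.averaging_threshold)
            self._write_csv(
                avg.params.rename("estimate").rename_axis("term").reset_index(),
                f"model_average_{response}.csv")
            self._write_csv(
                avg.importance.rename("importance").rename_axis("variable")
                .reset_index(),
                f"model_importance_{response}.csv")
            if "Group" in res.best.formula:
                try:
                    con = mdl.contrasts_frame(res.group_contrasts())
                    self._write_csv(con, f"group_contrasts_{response}.csv")
                except ValueError as err:
                    log.info("contrasts for %s: %s", response, err)
        return results

    def run(self) -> Path:
        """Execute every stage in dependency order."""
        self.stage_telemetry()
        self.stage_landscape()
        self.stage_ranges()
        self.stage_proximity()
        self.stage_fidelity()
        self.stage_covariates()
        self.stage_models()
        return self.outdir
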