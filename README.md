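# harvestrange

Caribou spatial behaviour against changing forest-harvest landscapes.

Boreal woodland caribou (*Rangifer tarandus caribou*) avoid recently cut
forest and return to the same summering areas year after year. When
forest management changes how much is cut and how the cutblocks are
arranged, do caribou range sizes, their proximity to harvests, and their
summer site fidelity change with it? `harvestrange` implements the full
analysis chain needed to ask that question from telemetry and annual
harvest-block layers, for movement ecologists and wildlife managers
working with ARGOS/GPS collar data and vector GIS harvest records:

1. **Telemetry screening** — ARGOS location-class filtering (keep
   classes 3/2/1), a neighbour-speed outlier screen, and season /
   biological-year labelling (biological year = May 1 – Apr 30; Summer =
   May 1 – Sep 15).
2. **Harvest-landscape metrics** — annual block layers aggregated into
   5-year sliding windows, rasterized, and summarised as total area
   (km²), mean patch size (ha, 8-neighbour patches) and the class-level
   Clumpiness Index

   CLUMPY = (G − P)/P  if G < P and P < 0.5, else (G − P)/(1 − P),

   with P the class proportion and G the border-corrected like-adjacency
   fraction; plus exact Euclidean distance-to-harvest rasters.
3. **Home ranges** — 100% MCP; 90% fixed-kernel ranges with the
   reference bandwidth h_ref = σ·n^(−1/6) (≥50 locations per
   animal-year); and the 65-location / 1000-iteration subsampling
   bootstrap that makes dense GPS years comparable with sparse ARGOS
   years.
4. **Proximity index** — per summer fix, observed distance to the
   nearest harvest cut within the past decade over the expected (mean
   distance-raster value across a reference range: the class 100% MCP +
   7.5 km buffer, or the animal-year's 90% kernel range). Index > 1 =
   farther from harvest than expected.
5. **Fidelity index** — same-day consecutive-year summer distances
   (paired mean) against the class all-pairs null; index = null/paired,
   > 1 = fidelity.
6. **Covariates and models** — the four harvest-exposure covariates
   (CutinHR, CutHRBuffer, CutBuffer, CutPoint; harvest <15 years old),
   then per-response candidate sets of linear mixed models (random
   intercept per animal, ML) ranked by AICc, ΔAICc<2 model averaging
   with Akaike weights, and single-step-adjusted pairwise group
   contrasts.
7. **Synthetic studies** — a seeded generator (biased correlated random
   walk with per-year seasonal centers, harvest avoidance, ARGOS/GPS
   observation error; clustered harvest-block process with declining
   annual targets) so the whole pipeline runs and is testable without
   field data.

All geometry is planar meters (shapely); rasters are numpy grids
(scipy); models are statsmodels. Vector I/O is GeoJSON, tables are CSV.

## Worked example

Fit the home-range-area candidate set to synthetic model rows (200 rows,
40 animals, data generated from `Group + 1.5·CutinHR` plus per-animal
intercepts):

```python
import numpy as np, pandas as pd
from harvestrange.models import CandidateSet

rng = np.random.default_rng(7)
GROUPS = ["west_early", "east_early", "west_late", "east_late"]
rows = []
for a in range(40):
    g = GROUPS[a % 4]; u = rng.normal(0, 2.0)
    for _ in range(5):
        cut = rng.uniform(0, 20)
        mu = [0.0, 10.0, 3.0, 12.0][GROUPS.index(g)] + 1.5 * cut + u
        rows.append({"animal_id": f"a{a}", "Group": g, "CutinHR": cut,
                     "CutHRBuffer": rng.uniform(0, 20),
                     "CutBuffer": rng.uniform(0, 30),
                     "response": 50.0 + mu + rng.normal(0, 4.0)})
res = CandidateSet.for_response("home_range_area").fit(pd.DataFrame(rows))
print(res.summary())
```

prints

```
Model selection: home_range_area [LMM (random intercept per individual, ML)], n = 200
                        model  df   loglik     aicc  delta_aicc  weight
              Group + CutinHR   7 -574.732 1164.047       0.000   0.708
Group + CutinHR + CutHRBuffer   8 -574.530 1165.815       1.768   0.292
                        Group   6 -724.445 1461.325     297.278   0.000
          Group + CutHRBuffer   7 -724.445 1463.473     299.426   0.000
                            1   3 -738.027 1482.176     318.130   0.000
```

The generating structure (`Group + CutinHR`) ranks first; the spurious
extra term survives within ΔAICc < 2, so `res.average_top()` averages
the two (CutinHR coefficient 1.483, true value 1.5; importance 1.00 for
Group and CutinHR, 0.29 for CutHRBuffer), and `res.group_contrasts()`
recovers the simulated group differences with simultaneous 95% CIs, e.g.
`west_early - east_early: est=-9.47, p_adj<0.0001, CI=(-12.65, -6.29)`
against a true difference of −10.

To run the whole pipeline on a synthetic study from the shell:

```bash
harvestrange simulate --outdir data/ --seed 1 --n-per-class 3
cat > run.yaml <<YAML
telemetry_path: data/telemetry.csv
harvest_paths: {west: data/harvest_west.geojson, east: data/harvest_east.geojson}
outdir: out
seed: 1
early_years: [1997, 1999]
late_years: [2009, 2011]
metrics_cell_m: 150.0
distance_cell_m: 150.0
YAML
harvestrange all --config run.yaml
```

`out/` then holds screened fixes, harvest-trend metrics, per-animal-year
ranges and polygons, per-fix proximity records with class summaries,
per-animal fidelity records, model-row tables, AICc selection tables,
averaged coefficients and contrasts — each CSV with a provenance header
(package version, config hash, seed). Subcommands (`telemetry`,
`landscape`, `ranges`, `proximity`, `fidelity`, `covariates`, `models`)
compose to the same result as `all`.

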