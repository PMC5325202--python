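"""Summer fidelity index: pairing, eligibility, null, and calibration."""

import numpy as np
import pandas as pd
import pytest

from harvestrange.fidelity import (
    eligibility, fidelity_index, null_distance, paired_distances,
    representative_daily,
)
from conftest import summer_track


def spread_track(animal, year, center, seed=0):
    """Eligible summer: one fix per day May 1 - Sep 15 around a center."""
    return summer_track(animal, year, center, n=138, seed=seed)


class TestEligibility:
    def test_needs_every_month_represented(self):
        df = spread_track("a", 1999, (0, 0))
        missing_july = df[pd.DatetimeIndex(df["t"]).month != 7]
        assert eligibility(df)
        assert not eligibility(missing_july)

    def test_two_per_month_passes_minimum(self):
        rows = []
        for month in (5, 6, 7, 8, 9):
            for day in (2, 10):
                rows.append(pd.Timestamp(1999, month, day, 12))
        df = summer_track("a", 1999, (0, 0), n=1).iloc[:0]
        df = pd.concat([df, pd.DataFrame({
            "animal_id": "a", "t": rows, "x": 0.0, "y": 0.0,
            "season": "Summer", "biological_year": 1999})])
        assert eligibility(df)

    def test_nine_fixes_below_minimum(self):
        rows = [pd.Timestamp(1999, m, d, 12)
                for m, d in [(5, 1), (5, 20), (6, 5), (6, 25), (7, 10),
                             (8, 1), (8, 20), (9, 5), (9, 10)]]
        df = pd.DataFrame({"animal_id": "a", "t": rows, "x": 0.0, "y": 0.0,
                           "season": "Summer", "biological_year": 1999})
        assert not eligibility(df)


class TestPairedDistances:
    def test_identical_tracks_zero_distance(self):
        t1 = spread_track("a", 1998, (0, 0), seed=4)
        t2 = t1.copy()
        t2["t"] = t2["t"] + pd.DateOffset(years=1)
        t2["biological_year"] = 1999
        pairs = paired_distances(pd.concat([t1, t2]))
        assert len(pairs) > 100
        assert np.allclose(pairs["distance_m"], 0.0)

    def test_rigid_shift_gives_constant_distance(self):
        t1 = spread_track("a", 1998, (0, 0), seed=4)
        t2 = t1.copy()
        t2["t"] = t2["t"] + pd.DateOffset(years=1)
        t2["biological_year"] = 1999
        t2["x"] += 5000.0
        pairs = paired_distances(pd.concat([t1, t2]))
        assert np.allclose(pairs["distance_m"], 5000.0)

    def test_nonconsecutive_years_not_paired(self):
        t1 = spread_track("a", 1998, (0, 0))
        t3 = spread_track("a", 2000, (0, 0))
        assert paired_distances(pd.concat([t1, t3])).empty

    def test_multifix_days_use_fix_nearest_noon(self):
        rows = []
        for hour, x in [(2, 111.0), (11, 222.0), (23, 333.0)]:
            rows.append({"animal_id": "a",
                         "t": pd.Timestamp(1999, 7, 1, hour),
                         "x": x, "y": 0.0, "season": "Summer",
                         "biological_year": 1999})
        rep = representative_daily(pd.DataFrame(rows))
        assert len(rep) == 1
        assert rep["x"].iloc[0] == 222.0  # 11:00 beats 02:00 and 23:00

    def test_brute_force_day_matching(self, rng):
        """Pairs equal an O(days^2)-free brute-force match on raw tracks."""
        t1 = spread_track("a", 1998, (0, 0), seed=9)
        t2 = spread_track("a", 1999, (3000, 4000), seed=10)
        both = pd.concat([t1, t2])
        pairs = paired_distances(both)
        # oracle: loop days explicitly
        d1 = {t.dayofyear: (x, y) for t, x, y in
              zip(pd.DatetimeIndex(t1["t"]), t1["x"], t1["y"])}
        d2 = {t.dayofyear: (x, y) for t, x, y in
              zip(pd.DatetimeIndex(t2["t"]), t2["x"], t2["y"])}
        expect = {doy: np.hypot(d1[doy][0] - d2[doy][0],
                                d1[doy][1] - d2[doy][1])
                  for doy in sorted(set(d1) & set(d2))}
        got = dict(zip(pairs["doy"], pairs["distance_m"]))
        assert got.keys() == expect.keys()
        for doy in expect:
            assert got[doy] == pytest.approx(expect[doy])


class TestNullDistance:
    def test_two_fixes_one_km(self):
        df = pd.DataFrame({
            "animal_id": ["a", "b"],
            "t": [pd.Timestamp(1999, 7, 1, 12)] * 2,
            "x": [0.0, 1000.0], "y": 0.0,
            "season": "Summer", "biological_year": 1999,
        })
        assert null_distance(df) == pytest.approx(1000.0)

    def test_three_collinear_fixes(self):
        df = pd.DataFrame({
            "animal_id": ["a", "b", "c"],
            "t": [pd.Timestamp(1999, 7, 1, 12)] * 3,
            "x": [0.0, 1000.0, 2000.0], "y": 0.0,
            "season": "Summer", "biological_year": 1999,
        })
        assert null_distance(df) == pytest.approx(4000.0 / 3.0)

    def test_matches_bruteforce_all_pairs(self, rng):
        pts = rng.uniform(0, 10_000, (200, 2))
        df = pd.DataFrame({
            "animal_id": "a",
            "t": pd.date_range("1999-07-01", periods=200, freq="min"),
            "x": pts[:, 0], "y": pts[:, 1],
            "season": "Summer", "biological_year": 1999,
        })
        brute = np.mean([np.hypot(*(pts[i] - pts[j]))
                         for i in range(200) for j in range(i + 1, 200)])
        assert null_distance(df) == pytest.approx(brute, rel=1e-12)

    def test_per_year_pooling_order(self):
        """Per-year means are computed first, then averaged across years."""
        y1 = pd.DataFrame({
            "animal_id": ["a", "b"], "t": [pd.Timestamp(1999, 7, 1, 12)] * 2,
            "x": [0.0, 1000.0], "y": 0.0, "season": "Summer",
            "biological_year": 1999})
        y2 = pd.DataFrame({
            "animal_id": ["a", "b", "c", "d"],
            "t": [pd.Timestamp(2000, 7, 1, 12)] * 4,
            "x": [0.0, 3000.0, 0.0, 3000.0], "y": [0.0, 0.0, 4.0, 4.0],
            "season": "Summer", "biological_year": 2000})
        got = null_distance(pd.concat([y1, y2]))
        year2 = np.mean([3000.0, 4.0, np.hypot(3000, 4), np.hypot(3000, 4),
                         4.0, 3000.0])
        assert got == pytest.approx((1000.0 + year2) / 2, rel=1e-9)


class TestFidelityIndex:
    def test_animal_matching_null_scores_one(self):
        # two animals forming the null; target animal's paired distances are
        # made to equal the class null exactly via a rigid shift
        a1 = spread_track("a", 1998, (0, 0), seed=1)
        a2 = a1.copy()
        a2["t"] = a2["t"] + pd.DateOffset(years=1)
        a2["biological_year"] = 1999
        tracks = pd.concat([a1, a2], ignore_index=True)
        null = null_distance(tracks)
        shifted = a2.copy()
        shifted["x"] += null  # paired mean becomes exactly the null mean
        out = fidelity_index(pd.concat([a1, shifted], ignore_index=True))
        # recompute against the modified pool's own null
        expect = out["null_mean_m"].iloc[0] / out["paired_mean_m"].iloc[0]
        assert out["index"].iloc[0] == pytest.approx(expect)
        assert out["paired_mean_m"].iloc[0] == pytest.approx(null, rel=1e-6)

    def test_attraction_to_persistent_center_raises_index(self, rng):
        """Strong site fidelity vs. center-hopping null: index >> 1."""
        tracks = []
        centers = rng.uniform(0, 60_000, (8, 2))
        for i, c in enumerate(centers):
            for year in (1998, 1999):
                tracks.append(spread_track(f"f{i}", year, c,
                                           seed=100 + 2 * i + (year - 1998)))
        faithful = pd.concat(tracks, ignore_index=True)
        out = fidelity_index(faithful)
        assert out["index"].mean() > 5.0

    def test_no_fidelity_mechanism_scores_near_one(self):
        """Unbiased-walk summers (no attraction, independent year starts):
        the class mean index calibrates to 1."""

        def walk_track(animal, year, r, n=138, sigma=8000.0, L=60_000.0):
            start = r.uniform(0, L, 2)
            xy = start + np.cumsum(r.normal(0, sigma, (n, 2)), axis=0)
            t = [pd.Timestamp(year, 5, 1, 12) + pd.Timedelta(days=i)
                 for i in range(n)]
            return pd.DataFrame({"animal_id": animal, "t": t,
                                 "x": xy[:, 0], "y": xy[:, 1],
                                 "season": "Summer", "biological_year": year})

        means = []
        for rep in range(20):
            r = np.random.default_rng(rep)
            tracks = [walk_track(f"n{i}", year, r)
                      for i in range(12) for year in range(1996, 2001)]
            out = fidelity_index(pd.concat(tracks, ignore_index=True))
            means.append(out["index"].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.1)

    def test_scale_equivariance(self, rng):
        tracks = []
        for i in range(4):
            c = rng.uniform(0, 30_000, 2)
            for year in (1998, 1999):
                tracks.append(spread_track(f"s{i}", year, c, seed=7 * i + year))
        df = pd.concat(tracks, ignore_index=True)
        out1 = fidelity_index(df)
        df2 = df.copy()
        df2[["x", "y"]] *= 3.7
        out2 = fidelity_index(df2)
        np.testing.assert_allclose(out1["index"], out2["index"], rtol=1e-9)

    def test_monotone_in_fidelity_strength(self, rng):
        """Mean index increases strictly across center-persistence levels."""
        from scipy.stats import spearmanr
        strengths = [0.0, 0.5, 1.0]  # persistence of the summer center
        level_means = []
        for s in strengths:
            vals = []
            for rep in range(20):
                r = np.random.default_rng(10_000 + rep)
                tracks = []
                for i in range(6):
                    base = r.uniform(0, 60_000, 2)
                    for yi, year in enumerate((1998, 1999)):
                        fresh = r.uniform(0, 60_000, 2)
                        c = base if yi == 0 else s * base + (1 - s) * fresh
                        tracks.append(spread_track(
                            f"m{i}", year, c,
                            seed=r.integers(2**31)))
                out = fidelity_index(pd.concat(tracks, ignore_index=True))
                vals.append(out["index"].mean())
            level_means.append(np.mean(vals))
        assert level_means[0] < level_means[1] < level_means[2]
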