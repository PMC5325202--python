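"""AICc selection, Akaike weights, model averaging, and group contrasts."""

import numpy as np
import pandas as pd
import pytest

from harvestrange.models import (
    CandidateSet, aicc, akaike_weights, DEFAULT_CANDIDATES,
)

GROUPS = ["west_early", "east_early", "west_late", "east_late"]


def simulate_rows(rng, n_animals=40, years=5, beta_cutinhr=2.0,
                  group_effects=(0.0, 10.0, 3.0, 12.0), sd_animal=2.0,
                  sd_resid=3.0):
    """Rows from: response ~ Group + beta*CutinHR + animal intercept + noise."""
    rows = []
    for a in range(n_animals):
        g = GROUPS[a % 4]
        u = rng.normal(0, sd_animal)
        for _ in range(years):
            cut = rng.uniform(0, 20)
            mu = group_effects[GROUPS.index(g)] + beta_cutinhr * cut + u
            rows.append({
                "animal_id": f"a{a}", "Group": g, "CutinHR": cut,
                "CutHRBuffer": rng.uniform(0, 20),
                "CutBuffer": rng.uniform(0, 30),
                "response": 50.0 + mu + rng.normal(0, sd_resid),
            })
    return pd.DataFrame(rows)


class TestAICc:
    def test_formula_limit(self):
        # k=2, loglik=0: AICc -> 4 as n grows
        assert aicc(0.0, 2, 10**9) == pytest.approx(4.0, abs=1e-6)

    def test_small_sample_penalty_exact(self):
        k, n, ll = 5, 30, -12.5
        assert aicc(ll, k, n) == pytest.approx(
            -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1))

    def test_undefined_when_n_too_small(self):
        assert np.isnan(aicc(0.0, 5, 6))

    def test_two_model_weights_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        expect = np.array([1.0, np.exp(-1.0)])
        expect = expect / expect.sum()
        np.testing.assert_allclose(w, expect, atol=1e-12)
        assert w[0] == pytest.approx(0.731, abs=1e-3)
        assert w[1] == pytest.approx(0.269, abs=1e-3)

    def test_single_model_weight_one(self):
        assert akaike_weights([42.0])[0] == pytest.approx(1.0)

    def test_weights_sum_to_one_and_shift_invariant(self, rng):
        a = rng.uniform(100, 200, 8)
        w1 = akaike_weights(a)
        w2 = akaike_weights(a + 57.0)
        assert w1.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestCandidateFitting:
    def test_default_sets_include_null(self):
        for resp, cands in DEFAULT_CANDIDATES.items():
            assert "1" in cands

    def test_fit_ranks_by_aicc_and_weights_sum_to_one(self, rng):
        rows = simulate_rows(rng)
        res = CandidateSet.for_response("home_range_area").fit(rows)
        tab = res.table
        assert (tab["aicc"].diff().dropna() >= 0).all()
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert tab["delta_aicc"].iloc[0] == 0.0

    def test_aicc_exceeds_aic_by_exact_correction(self, rng):
        rows = simulate_rows(rng, n_animals=24, years=3)
        res = CandidateSet.for_response("home_range_area").fit(rows)
        for f in res.fits:
            aic = -2 * f.loglik + 2 * f.k
            assert f.aicc - aic == pytest.approx(
                2 * f.k * (f.k + 1) / (f.n - f.k - 1), rel=1e-9)

    def test_generating_model_recovers_sign(self, rng):
        rows = simulate_rows(rng, beta_cutinhr=2.0)
        res = CandidateSet.for_response("home_range_area").fit(rows)
        best = res.best
        assert "CutinHR" in best.formula
        assert best.params["CutinHR"] > 0

    def test_duplicated_rows_same_coefficients(self, rng):
        rows = simulate_rows(rng, n_animals=20, years=3)
        cs = CandidateSet(response="toy", candidates=["Group + CutinHR"],
                          groups="animal_id")
        res1 = cs.fit(rows)
        res2 = cs.fit(pd.concat([rows, rows], ignore_index=True))
        p1 = res1.best.params
        p2 = res2.best.params
        assert res2.n == 2 * res1.n
        # ML point estimates are invariant to duplication up to optimizer
        # tolerance
        np.testing.assert_allclose(p1, p2[p1.index], rtol=0.02, atol=0.05)

    def test_fidelity_uses_ols_single_row_per_animal(self, rng):
        rows = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(40)],
            "Group": [GROUPS[i % 4] for i in range(40)],
            "CutPoint": rng.uniform(0, 10, 40),
            "response": rng.uniform(0.5, 5, 40),
        })
        cs = CandidateSet.for_response("fidelity")
        assert cs.groups is None
        res = cs.fit(rows)
        assert len(res.fits) == 3

    def test_sqrt_transform_requires_nonnegative(self, rng):
        rows = simulate_rows(rng, n_animals=12, years=2)
        rows.loc[0, "response"] = -5.0
        cs = CandidateSet.for_response("home_range_area", sqrt_transform=True)
        with pytest.raises(ValueError, match="nonneg"):
            cs.fit(rows)


class TestModelAveraging:
    def test_single_top_model_returns_its_coefficients(self, rng):
        rows = simulate_rows(rng, beta_cutinhr=5.0)  # strong effect: one top
        res = CandidateSet.for_response("home_range_area").fit(rows)
        if len([f for f in res.fits if f.delta_aicc < 2]) == 1:
            avg = res.average_top()
            np.testing.assert_allclose(
                avg.params[res.best.params.index], res.best.params)

    def test_importance_is_weight_sum_and_hits_one(self, rng):
        rows = simulate_rows(rng, beta_cutinhr=5.0)
        res = CandidateSet.for_response("home_range_area").fit(rows)
        avg = res.average_top()
        # Group appears in every non-null candidate; with a strong signal the
        # null gets ~0 weight so importance ~ 1
        assert avg.importance["Group"] == pytest.approx(1.0, abs=1e-3)
        for v, imp in avg.importance.items():
            manual = sum(f.weight for f in res.fits
                         if v in f.formula.replace(" ", "").split("+"))
            assert imp == pytest.approx(manual, abs=1e-12)

    def test_two_model_toy_average_matches_hand_computation(self):
        """Conditional averaging equals the hand-computed weighted mean."""
        from harvestrange.models import ModelFit, SelectionResults
        p1 = pd.Series({"Intercept": 1.0, "CutinHR": 2.0})
        p2 = pd.Series({"Intercept": 3.0})
        mk = lambda f, p, ll, k: ModelFit(
            formula=f, k=k, loglik=ll, n=100, aicc=aicc(ll, k, 100),
            params=p, bse=p * 0 + 1.0,
            cov_params=pd.DataFrame(np.eye(len(p)), index=p.index,
                                    columns=p.index), converged=True)
        f1 = mk("CutinHR", p1, -10.0, 3)
        f2 = mk("1", p2, -10.5, 2)
        rows = pd.DataFrame({"Group": ["a", "b"] * 5})
        res = SelectionResults(
            CandidateSet(response="toy", candidates=["CutinHR", "1"],
                         groups=None),
            [f1, f2], n=100, rows=rows)
        w = np.array([f.weight for f in res.fits])
        avg = res.average_top(threshold=10.0)
        expect_int = (w[0] * res.fits[0].params["Intercept"]
                      + w[1] * res.fits[1].params["Intercept"]) / w.sum()
        assert avg.params["Intercept"] == pytest.approx(expect_int)
        # CutinHR appears only in one model: conditional average is its value
        assert avg.params["CutinHR"] == pytest.approx(2.0)


class TestGroupContrasts:
    def test_identical_groups_ci_covers_zero(self, rng):
        """Calibration: with no true group differences the simultaneous CI
        covers 0 for every contrast in >=94% of replicates."""
        cover = 0
        trials = 60
        for rep in range(trials):
            r = np.random.default_rng(rep)
            rows = simulate_rows(r, n_animals=32, years=3,
                                 group_effects=(0, 0, 0, 0), beta_cutinhr=0.0)
            cs = CandidateSet(response="toy", candidates=["Group"],
                              groups="animal_id")
            res = cs.fit(rows)
            cons = res.group_contrasts()
            if all(c.ci_lower <= 0 <= c.ci_upper for c in cons):
                cover += 1
        assert cover / trials >= 0.86  # ~94% nominal, binomial noise at n=60

    def test_large_true_difference_detected(self, rng):
        rows = simulate_rows(rng, n_animals=40, years=4,
                             group_effects=(0.0, 40.0, 0.0, 40.0),
                             beta_cutinhr=0.0)
        cs = CandidateSet(response="toy", candidates=["Group"],
                          groups="animal_id")
        res = cs.fit(rows)
        cons = {c.label: c for c in res.group_contrasts()}
        c = cons["west_early - east_early"]
        assert c.p_adjusted < 0.01
        assert c.estimate == pytest.approx(-40.0, abs=8.0)

    def test_single_group_is_error(self, rng):
        rows = simulate_rows(rng, n_animals=8, years=3)
        rows["Group"] = "west_early"
        cs = CandidateSet(response="toy", candidates=["1"], groups="animal_id")
        res = cs.fit(rows)
        with pytest.raises(ValueError):
            res.group_contrasts(fit=res.best)

    def test_contrasts_require_group_in_model(self, rng):
        rows = simulate_rows(rng, n_animals=12, years=2)
        cs = CandidateSet(response="toy", candidates=["1"], groups="animal_id")
        res = cs.fit(rows)
        with pytest.raises(ValueError, match="Group"):
            res.group_contrasts()


def test_generating_model_wins_aicc_most_of_the_time():
    """Parameter recovery: data generated from Group + CutinHR (with animal
    intercepts) put that model first by AICc in >= 80% of replicates."""
    wins = 0
    reps = 50
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        rows = simulate_rows(rng, n_animals=40, years=5, beta_cutinhr=1.0,
                             sd_animal=2.0, sd_resid=4.0)  # n = 200
        res = CandidateSet.for_response("home_range_area").fit(rows)
        if res.best.formula.replace(" ", "") == "Group+CutinHR":
            wins += 1
    assert wins / reps >= 0.8
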