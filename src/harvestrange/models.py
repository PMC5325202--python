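"""Candidate-set mixed-model selection for the behavioural responses.

Each behavioural metric (annual home-range area, population- and
annual-scale proximity index, summer fidelity index) is modelled over a
small candidate set of fixed-effect structures built from the region-period
``Group`` factor and the harvest covariates (``CutinHR``, ``CutHRBuffer``,
``CutBuffer``, ``CutPoint``), always including a Null (intercept-only)
model. Responses observed repeatedly per animal are fitted as linear mixed
models with a random intercept per individual (maximum likelihood, so that
AICc is comparable across fixed-effect structures); fidelity, one value per
animal, is fitted by ordinary least squares. Candidates are ranked by

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1)

models within ``delta < 2`` of the best are model-averaged with
renormalised Akaike weights, and when the best model retains ``Group`` all
pairwise group contrasts are tested with single-step (max-|t|,
multivariate-normal) adjusted p-values and simultaneous confidence
intervals.

Usage follows the construct-fit-results pattern::

    cs = CandidateSet.for_response("fidelity")
    res = cs.fit(rows)          # -> SelectionResults
    print(res.summary())
    avg = res.average_top()     # averaged coefficients + importances
    con = res.group_contrasts() # Tukey-style all-pairs comparisons
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

ALL_COVARIATES = ("CutinHR", "CutHRBuffer", "CutBuffer", "CutPoint")

#: fixed-effect candidate structures per response, reconstructed from the
#: study's reported top-model tables; "1" is the Null model
DEFAULT_CANDIDATES: dict[str, list[str]] = {
    "home_range_area": [
        "1", "Group", "Group + CutinHR", "Group + CutHRBuffer",
        "Group + CutinHR + CutHRBuffer",
    ],
    "proximity_population": [
        "1", "Group", "Group + CutinHR", "Group + CutinHR + CutHRBuffer",
        "Group + CutinHR + CutBuffer",
    ],
    "proximity_annual": [
        "1", "Group", "Group + CutinHR", "Group + CutBuffer",
        "Group + CutBuffer + CutinHR",
    ],
    "fidelity": ["1", "Group", "Group + CutPoint"],
}
#: responses with one row per animal-year use a per-animal random intercept
MIXED_RESPONSES = {"home_range_area", "proximity_population", "proximity_annual"}


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        return float("nan")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Model weights from AICc values: w_i ∝ exp(-Δ_i / 2)."""
    a = np.asarray(aicc_values, dtype=float)
    a = np.where(np.isfinite(a), a, np.inf)  # undefined AICc gets zero weight
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def _terms(formula_rhs: str) -> list[str]:
    return [t.strip() for t in formula_rhs.split("+") if t.strip() not in ("", "1")]


@dataclass
class ModelFit:
    formula: str                 # fixed-effects RHS
    k: int                       # parameter count incl. variance components
    loglik: float
    n: int
    aicc: float
    params: pd.Series            # fixed-effect estimates
    bse: pd.Series
    cov_params: pd.DataFrame     # fixed-effect covariance
    converged: bool
    delta_aicc: float = np.nan
    weight: float = np.nan

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse,
             "upper": self.params + z * self.bse}
        )


@dataclass
class CandidateSet:
    """A response, its candidate fixed-effect structures, and the random
    structure used for every candidate."""

    response: str
    candidates: list[str]
    groups: Optional[str] = "animal_id"  # random-intercept grouping; None = OLS
    sqrt_transform: bool = False

    @classmethod
    def for_response(cls, response: str, sqrt_transform: bool = False,
                     extra_candidates: Sequence[str] = ()) -> "CandidateSet":
        if response not in DEFAULT_CANDIDATES:
            raise KeyError(
                f"unknown response {response!r}; expected one of "
                f"{sorted(DEFAULT_CANDIDATES)}"
            )
        cands = list(DEFAULT_CANDIDATES[response]) + list(extra_candidates)
        groups = "animal_id" if response in MIXED_RESPONSES else None
        return cls(response=response, candidates=cands, groups=groups,
                   sqrt_transform=sqrt_transform)

    # -- fitting ---------------------------------------------------------

    def fit(self, data: pd.DataFrame, response_col: str = "response") -> "SelectionResults":
        """Fit every candidate by ML on a common complete-case row set."""
        needed = {response_col, "Group"} | {
            t for c in self.candidates for t in _terms(c) if t != "Group"
        }
        if self.groups:
            needed.add(self.groups)
        if missing := needed - set(data.columns):
            raise KeyError(f"model rows missing columns: {sorted(missing)}")
        rows = data.dropna(subset=sorted(needed)).copy()
        dropped = len(data) - len(rows)
        if dropped:
            log.info("%s: dropped %d incomplete rows (set-wide)", self.response, dropped)
        y = rows[response_col].astype(float)
        if self.sqrt_transform:
            if (y < 0).any():
                raise ValueError("square-root transform requires nonnegative response")
            rows["_y"] = np.sqrt(y)
        else:
            rows["_y"] = y
        n = len(rows)

        fits = []
        for rhs in self.candidates:
            formula = f"_y ~ {rhs}"
            try:
                fit = self._fit_one(formula, rows)
            except Exception as err:  # non-convergence or singular fit
                log.warning("%s: candidate %r failed (%s); excluded",
                            self.response, rhs, err)
                continue
            fit.formula = rhs
            fits.append(fit)
        if not fits:
            raise RuntimeError(f"{self.response}: no candidate model converged")
        return SelectionResults(candidate_set=self, fits=fits, n=n, rows=rows)

    def _fit_one(self, formula: str, rows: pd.DataFrame) -> ModelFit:
        n = len(rows)
        if self.groups is None:
            res = smf.ols(formula, data=rows).fit()
            k = int(res.df_model) + 1 + 1  # slopes + intercept + residual var
            cov = res.cov_params()
            converged = True
        else:
            res, boundary = None, False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=rows, groups=rows[self.groups])
                for optimizer in ("bfgs", "lbfgs", "cg"):
                    try:
                        cand = model.fit(reml=False, method=optimizer)
                    except np.linalg.LinAlgError:
                        boundary = True  # singular Hessian at boundary iterate
                        continue
                    if not np.isfinite(cand.llf) or \
                            float(cand.cov_re.iloc[0, 0]) <= \
                            1e-8 * float(cand.scale):
                        boundary = True
                        continue
                    if bool(cand.converged):
                        res = cand
                        break
            if res is None:
                if not boundary:
                    raise RuntimeError("mixed model did not converge")
                # random-intercept variance collapsed to 0, where the ML
                # likelihood and the fixed effects equal OLS exactly
                ols = smf.ols(formula, data=rows).fit()
                k = int(ols.df_model) + 1 + 2  # re variance counted at boundary
                return ModelFit(
                    formula=formula, k=k, loglik=float(ols.llf), n=n,
                    aicc=aicc(float(ols.llf), k, n),
                    params=ols.params.copy(), bse=ols.bse.copy(),
                    cov_params=pd.DataFrame(ols.cov_params(),
                                            index=ols.params.index,
                                            columns=ols.params.index),
                    converged=True,
                )
            k_fe = len(res.fe_params)
            k = k_fe + 2  # + random-intercept variance + residual variance
            cov = res.cov_params().iloc[:k_fe, :k_fe]
            converged = True
        params = (res.fe_params if hasattr(res, "fe_params") else res.params)
        bse = res.bse[params.index]
        return ModelFit(
            formula=formula, k=k, loglik=float(res.llf), n=n,
            aicc=aicc(float(res.llf), k, n),
            params=params.copy(), bse=bse.copy(),
            cov_params=pd.DataFrame(cov, index=params.index, columns=params.index),
            converged=converged,
        )


@dataclass
class AveragedCoefficients:
    params: pd.Series
    importance: pd.Series      # per-variable sum of weights over the full set
    n_models: int


@dataclass
class Contrast:
    label: str
    estimate: float
    se: float
    statistic: float
    p_adjusted: float
    ci_lower: float
    ci_upper: float


class SelectionResults:
    """Ranked candidate fits for one response."""

    def __init__(self, candidate_set: CandidateSet, fits: list[ModelFit],
                 n: int, rows: pd.DataFrame):
        self.candidate_set = candidate_set
        self.n = n
        self.rows = rows
        if not any(np.isfinite(f.aicc) for f in fits):
            raise RuntimeError(
                "AICc undefined for every candidate (sample too small "
                "relative to parameter counts)"
            )
        order = np.argsort([f.aicc for f in fits])
        self.fits = [fits[i] for i in order]
        weights = akaike_weights([f.aicc for f in self.fits])
        best = self.fits[0].aicc
        for f, w in zip(self.fits, weights):
            f.delta_aicc = f.aicc - best
            f.weight = float(w)

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    @property
    def table(self) -> pd.DataFrame:
        """Selection table: formula, df, logLik, AICc, delta, weight."""
        return pd.DataFrame(
            {
                "model": [f.formula for f in self.fits],
                "df": [f.k for f in self.fits],
                "loglik": [f.loglik for f in self.fits],
                "aicc": [f.aicc for f in self.fits],
                "delta_aicc": [f.delta_aicc for f in self.fits],
                "weight": [f.weight for f in self.fits],
            }
        )

    def summary(self) -> str:
        kind = "LMM (random intercept per individual, ML)" \
            if self.candidate_set.groups else "OLS"
        head = (
            f"Model selection: {self.candidate_set.response} "
            f"[{kind}], n = {self.n}"
            + (", sqrt response" if self.candidate_set.sqrt_transform else "")
        )
        with pd.option_context("display.width", 100):
            body = self.table.round(3).to_string(index=False)
        return head + "\n" + body

    def average_top(self, threshold: float = 2.0) -> AveragedCoefficients:
        """Average coefficients across models with delta AICc < threshold.

        Weights are renormalised over the averaged subset; a coefficient is
        averaged over the subset models that contain it (natural/conditional
        averaging). Variable importance sums full-set weights over every
        candidate containing the variable.
        """
        top = [f for f in self.fits if f.delta_aicc < threshold]
        w = np.array([f.weight for f in top])
        w = w / w.sum()
        names: list[str] = []
        for f in top:
            names.extend(p for p in f.params.index if p not in names)
        avg = {}
        for name in names:
            vals, ws = [], []
            for f, wi in zip(top, w):
                if name in f.params.index:
                    vals.append(f.params[name])
                    ws.append(wi)
            avg[name] = float(np.average(vals, weights=ws))
        importance = {}
        for var in ["Group", *ALL_COVARIATES]:
            wsum = sum(f.weight for f in self.fits if var in _terms(f.formula))
            if any(var in _terms(f.formula) for f in self.fits):
                importance[var] = float(wsum)
        return AveragedCoefficients(
            params=pd.Series(avg), importance=pd.Series(importance),
            n_models=len(top),
        )

    def group_contrasts(self, alpha: float = 0.05,
                        fit: ModelFit | None = None) -> list[Contrast]:
        """All pairwise region-period group comparisons from the best model
        (single-step adjustment over the joint normal of the contrasts)."""
        fit = fit or self.best
        if "Group" not in _terms(fit.formula):
            raise ValueError("best model does not include the Group factor")
        levels = sorted(self.rows["Group"].astype(str).unique())
        if len(levels) < 2:
            raise ValueError("group contrasts need at least two group levels")
        names = list(fit.params.index)

        def level_vec(level: str) -> np.ndarray:
            v = np.zeros(len(names))
            tag = f"Group[T.{level}]"
            if tag in names:
                v[names.index(tag)] = 1.0
            return v

        pairs = list(itertools.combinations(levels, 2))
        C = np.array([level_vec(b) - level_vec(a) for a, b in pairs])
        est = C @ fit.params.to_numpy()
        V = C @ fit.cov_params.to_numpy() @ C.T
        se = np.sqrt(np.diag(V))
        zstat = est / se
        R = V / np.outer(se, se)
        R = (R + R.T) / 2 + 1e-10 * np.eye(len(se))

        m = len(se)

        def p_max_abs(c: float) -> float:
            # P(max_j |Z_j| <= c) under the contrasts' joint normal
            return float(stats.multivariate_normal.cdf(
                np.full(m, c), mean=np.zeros(m), cov=R,
                lower_limit=np.full(m, -c), allow_singular=True,
                maxpts=5_000 * m, abseps=1e-4, rng=np.random.default_rng(0),
            ))

        crit = optimize.brentq(lambda c: p_max_abs(c) - (1 - alpha),
                               0.5, 8.0, xtol=1e-3)
        out = []
        for i, (a, b) in enumerate(pairs):
            p_adj = 1.0 - p_max_abs(abs(zstat[i]))
            out.append(Contrast(
                label=f"{b} - {a}", estimate=float(est[i]), se=float(se[i]),
                statistic=float(zstat[i]),
                p_adjusted=float(min(max(p_adj, 0.0), 1.0)),
                ci_lower=float(est[i] - crit * se[i]),
                ci_upper=float(est[i] + crit * se[i]),
            ))
        return out


def contrasts_frame(contrasts: list[Contrast]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])
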