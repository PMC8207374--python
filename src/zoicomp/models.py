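"""Per-species neighborhood regressions with AICc multimodel averaging.

Growth of a focal tree over a census period is modelled on the log scale as

    ln(agr) = intercept + alpha*ln(ba_t1) + beta*ln(1 + SUM_CON) + gamma*ln(1 + SUM_HET) + error

by ordinary least squares, where ``SUM_CON``/``SUM_HET`` are the
distance-decayed basal-area sums of larger surviving conspecific and
heterospecific neighbors; survival over the period is the analogous logistic
regression on the 0/1 outcome.  One such model exists for every cell of the
(radius x overlap-tolerance) grid — 20 x 20 radii times 7 x 7 tolerances =
19,600 spatial cells — and the final neighbor effects are unweighted means of
the raw coefficients across all cells within 2 AICc units of the best one.

The public surface follows the Model -> fit() -> Results idiom:
:class:`GrowthModel` / :class:`SurvivalModel` fit a single cell, while
:class:`NeighborhoodScan` sweeps a grid and its :class:`ScanResults` provides
``average_band`` and ``compare_to_reference``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .allometry import AllometryCoefficients, PUBLISHED_17, basal_area
from .census import Census, PeriodSpec, focal_subset
from .crowns import fill_plot
from .neighborhood import predictor_table
from .overlap import DD_GRID, OverlapConfig, adjust_plot

__all__ = [
    "FitError",
    "aicc",
    "growth_rate",
    "growth_observations",
    "survival_observations",
    "exclude_outliers",
    "GrowthModel",
    "GrowthResults",
    "SurvivalModel",
    "SurvivalResults",
    "apply_fit_exclusions",
    "grid_cells",
    "ScanConfig",
    "NeighborhoodScan",
    "ScanResults",
    "GridSummary",
    "scan_pair",
    "compare_aicc",
]


class FitError(RuntimeError):
    """A single regression cell could not be fitted (collinear / unstable)."""

    def __init__(self, reason: str, message: str | None = None):
        super().__init__(message or reason)
        self.reason = reason


def aicc(llf: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# observations


def growth_rate(ba_start, ba_end, duration_years: float,
                epsilon: float = 0.01, nonpositive: str = "floor"):
    """Absolute growth rate in basal area, cm**2 / y.

    Non-positive rates are floored at ``epsilon`` before the log transform
    (``nonpositive='floor'``) or set to NaN for dropping (``'drop'``).
    """
    agr = (np.asarray(ba_end, float) - np.asarray(ba_start, float)) / duration_years
    if nonpositive == "floor":
        agr = np.maximum(agr, epsilon)
    elif nonpositive == "drop":
        agr = np.where(agr > 0, agr, np.nan)
    else:
        raise ValueError("nonpositive must be 'floor' or 'drop'")
    return agr


def growth_observations(census: Census, focal: pd.DataFrame, period: PeriodSpec,
                        epsilon: float = 0.01,
                        nonpositive: str = "floor") -> pd.DataFrame:
    """Growth observations for focal trees alive at both period ends."""
    g0, g1 = f"gbh_{period.start_census}", f"gbh_{period.end_census}"
    s1 = f"status_{period.end_census}"
    t = focal[focal[s1] == "alive"].copy()
    t = t[np.isfinite(t[g0]) & np.isfinite(t[g1])]
    ba0, ba1 = basal_area(t[g0].to_numpy(float)), basal_area(t[g1].to_numpy(float))
    agr = growth_rate(ba0, ba1, period.duration_years, epsilon, nonpositive)
    out = pd.DataFrame({
        "focal_id": t["tree_id"].to_numpy(), "species": t["species"].to_numpy(),
        "ln_ba": np.log(ba0), "agr": agr, "ln_agr": np.log(agr)})
    return out.dropna(subset=["ln_agr"]).reset_index(drop=True)


def survival_observations(census: Census, focal: pd.DataFrame,
                          period: PeriodSpec) -> pd.DataFrame:
    """0/1 survival outcomes (1 = survived) for focal trees."""
    g0, s1 = f"gbh_{period.start_census}", f"status_{period.end_census}"
    t = focal[focal[s1].isin(["alive", "dead"])].copy()
    ba0 = basal_area(t[g0].to_numpy(float))
    return pd.DataFrame({
        "focal_id": t["tree_id"].to_numpy(), "species": t["species"].to_numpy(),
        "ln_ba": np.log(ba0),
        "survived": (t[s1] == "alive").astype(int).to_numpy()})


def exclude_outliers(obs: pd.DataFrame, sd_threshold: float = 3.0,
                     max_iter: int = 50) -> tuple[pd.DataFrame, list]:
    """Iteratively drop strong negative growth outliers.

    Regresses ln_agr on ln_ba (the size regression only, no neighbor terms)
    and removes observations with residual < -sd_threshold * SD until none
    remain.  Idempotent on its own output.  Returns (kept, dropped ids).
    """
    obs = obs.reset_index(drop=True)
    dropped: list = []
    for _ in range(max_iter):
        if len(obs) < 3:
            break
        X = sm.add_constant(obs["ln_ba"].to_numpy())
        res = sm.OLS(obs["ln_agr"].to_numpy(), X).fit()
        resid = res.resid
        sd = float(np.std(resid, ddof=1))
        if sd == 0:
            break
        bad = resid < -sd_threshold * sd
        if not bad.any():
            break
        dropped.extend(obs.loc[bad, "focal_id"].tolist())
        obs = obs[~bad].reset_index(drop=True)
    return obs, dropped


# ---------------------------------------------------------------------------
# single-cell models


def _design(data: pd.DataFrame, terms: tuple) -> pd.DataFrame:
    X = data[list(terms)].astype(float)
    return sm.add_constant(X, has_constant="add")


class GrowthModel:
    """OLS growth model for one predictor setting.

    ``data`` needs a response column (default ``ln_agr``) plus the term
    columns (e.g. ``ln_ba, ln_con, ln_het``).
    """

    def __init__(self, endog, exog: pd.DataFrame):
        self.endog = np.asarray(endog, float)
        self.exog = exog
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            raise FitError("collinear", "rank-deficient design matrix")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame,
                       terms=("ln_ba", "ln_con", "ln_het"),
                       response: str = "ln_agr") -> "GrowthModel":
        return cls(data[response], _design(data, tuple(terms)))

    def fit(self) -> "GrowthResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return GrowthResults(self, res)


class GrowthResults:
    """OLS results with AICc, PRESS-predicted R**2 and partial effect sizes."""

    def __init__(self, model: GrowthModel, res):
        self._res = res
        self.params = res.params
        self.bse = res.bse
        self.tvalues = res.tvalues
        self.pvalues = res.pvalues
        self.nobs = int(res.nobs)
        self.df_resid = int(res.df_resid)
        #: mean parameters (incl. intercept) plus the residual variance
        self.k = len(res.params) + 1
        self.aicc = aicc(res.llf, self.nobs, self.k)
        self.adj_r2 = float(res.rsquared_adj)
        h = res.get_influence().hat_matrix_diag
        press = float(np.sum((res.resid / np.clip(1.0 - h, 1e-12, None)) ** 2))
        sst = float(np.sum((model.endog - model.endog.mean()) ** 2))
        self.press = press
        self.pred_r2 = 1.0 - press / sst if sst > 0 else np.nan

    def effect_size(self, term: str) -> float:
        """Squared partial correlation t**2 / (t**2 + df_resid) in [0, 1]."""
        t = float(self.tvalues[term])
        return t**2 / (t**2 + self.df_resid)

    def summary(self):
        s = self._res.summary()
        s.add_extra_txt([
            f"AICc: {self.aicc:.3f} (k={self.k} incl. error variance)",
            f"predicted R2 (PRESS): {self.pred_r2:.4f}",
            "effect sizes t2/(t2+df): " + ", ".join(
                f"{name}={self.effect_size(name):.3f}"
                for name in self.params.index if name != "const")])
        return s


class SurvivalModel:
    """Logistic (binomial GLM) survival model for one predictor setting."""

    def __init__(self, endog, exog: pd.DataFrame):
        self.endog = np.asarray(endog, float)
        self.exog = exog
        if len(np.unique(self.endog)) < 2:
            raise FitError("unstable", "only one outcome class present")
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            raise FitError("collinear", "rank-deficient design matrix")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame,
                       terms=("ln_ba", "ln_con", "ln_het"),
                       response: str = "survived") -> "SurvivalModel":
        return cls(data[response], _design(data, tuple(terms)))

    def fit(self) -> "SurvivalResults":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=100)
            except Exception as exc:  # separation, singularities
                raise FitError("unstable", str(exc)) from exc
        if not res.mle_retvals.get("converged", True):
            raise FitError("unstable", "logit fit did not converge")
        return SurvivalResults(self, res)


class SurvivalResults:
    """Logit results with AICc and the likelihood pseudo-R**2 (percent)."""

    def __init__(self, model: SurvivalModel, res):
        self._res = res
        self.params = res.params
        self.bse = res.bse
        self.tvalues = res.tvalues
        self.pvalues = res.pvalues
        self.nobs = int(res.nobs)
        self.k = len(res.params)
        self.aicc = aicc(res.llf, self.nobs, self.k)
        l0, lp = res.llnull, res.llf
        #: R_L^2 = [(L0 - Lp)/L0] * 100
        self.r_l2 = float((l0 - lp) / l0 * 100.0) if l0 != 0 else 0.0
        n, p = self.nobs, self.k - 1
        if n - p - 1 > 0:
            self.r_l2_adj = float(100.0 * (
                1.0 - (1.0 - self.r_l2 / 100.0) * (n - 1) / (n - p - 1)))
        else:
            self.r_l2_adj = np.nan

    def effect_size(self, term: str) -> float:
        """Survival effects are the raw logistic coefficients."""
        return float(self.params[term])

    def odds_percent(self, term: str) -> float:
        """(exp(beta) - 1) * 100: percent change in survival odds per unit."""
        return float((np.exp(self.params[term]) - 1.0) * 100.0)

    def summary(self):
        s = self._res.summary()
        s.add_extra_txt([
            f"AICc: {self.aicc:.3f}",
            f"R_L2: {self.r_l2:.2f}%  (adj {self.r_l2_adj:.2f}%)",
            "odds change %: " + ", ".join(
                f"{name}={self.odds_percent(name):+.1f}"
                for name in self.params.index if name != "const")])
        return s


def apply_fit_exclusions(sum_con: np.ndarray, sum_het: np.ndarray,
                         response: str = "growth", min_con: int = 5,
                         min_zero_het: int = 5) -> str | None:
    """Growth-model sample-composition exclusion rule.

    A growth cell is excluded when fewer than ``min_con`` focal trees have any
    CON neighbor, or fewer than ``min_zero_het`` have no HET neighbor at all
    (such fits ride on extreme radii).  Survival models are never excluded
    this way.  Returns the exclusion reason or ``None``.
    """
    if response != "growth":
        return None
    if int(np.sum(np.asarray(sum_con) > 0)) < min_con:
        return "few_con"
    if int(np.sum(np.asarray(sum_het) == 0)) < min_zero_het:
        return "few_zero_het"
    return None


# ---------------------------------------------------------------------------
# grid scan


def grid_cells(radii=tuple(range(1, 21)), dd_levels=DD_GRID,
               spatial: bool = True, form: str = "ba+con+het"):
    """Enumerate the model grid.

    Spatial two-term: (dd_con, dd_het, r_con, r_het) — 7*7*20*20 = 19,600
    cells at the defaults; nonspatial two-term: (r_con, r_het) — 400 cells;
    one-term (ba+all): radii only (times tolerance pairs when spatial).
    """
    if form == "ba":
        return [()]
    if form == "ba+all":
        if spatial:
            return list(itertools.product(dd_levels, dd_levels, radii))
        return [(r,) for r in radii]
    if spatial:
        return list(itertools.product(dd_levels, dd_levels, radii, radii))
    return list(itertools.product(radii, radii))


@dataclass(frozen=True)
class ScanConfig:
    """Mode and grid of a neighborhood scan."""

    spatial: bool = True
    fill_mode: str = "larsm"
    adjust_mode: str = "relocation"
    position_mode: str = "crown"
    decay: str = "linear"
    form: str = "ba+con+het"
    radii: tuple = tuple(range(1, 21))
    dd_levels: tuple = DD_GRID
    density: float = 10.0
    coeffs: AllometryCoefficients = PUBLISHED_17
    size_class: tuple = (10.0, 100.0)
    epsilon: float = 0.01
    sd_threshold: float = 3.0
    min_con: int = 5
    min_zero_het: int = 5
    se_limit: float = 100.0

    @property
    def mode_label(self) -> str:
        if not self.spatial:
            return "nonspatial"
        a = "reloc" if self.adjust_mode == "relocation" else "remov"
        return f"{self.fill_mode}/{a}/{self.position_mode}"


@dataclass
class GridSummary:
    """Model-averaged neighbor effect over the <=2 dAICc band."""

    species: str
    period: int
    response: str
    term: str
    coefficient: float
    n_models: int
    mean_radius: float
    radius_range: float
    mean_dd: float
    slope_vs_radius: float
    bimodal: bool
    bimodal_kind: str | None = None


def _bimodality(values: np.ndarray, mean: float):
    """Histogram-peak diagnostic for averaged-coefficient consistency.

    Bimodal when two clear modes sit on either side of zero or their peak
    separation is at least twice the absolute mean coefficient.
    """
    values = np.asarray(values, float)
    if len(values) < 10 or np.ptp(values) == 0:
        return False, None
    nbins = int(np.clip(np.sqrt(len(values)), 5, 25))
    counts, edges = np.histogram(values, bins=nbins)
    sm_counts = np.convolve(counts, [0.25, 0.5, 0.25], mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    pad = np.concatenate([[-np.inf], sm_counts, [-np.inf]])
    is_peak = (pad[1:-1] > pad[:-2]) & (pad[1:-1] >= pad[2:]) & (counts > 0)
    peaks = centers[is_peak]
    floor = 0.1 * sm_counts.max()
    peaks = peaks[sm_counts[is_peak] >= floor]
    if len(peaks) < 2:
        return False, None
    lo, hi = peaks.min(), peaks.max()
    if lo < 0 < hi:
        return True, "sign_split"
    if abs(hi - lo) >= 2.0 * abs(mean) > 0:
        return True, "peak_separation"
    return False, None


class ScanResults:
    """All per-cell fits of one species x period x response scan."""

    def __init__(self, species: str, period_index: int, response: str,
                 config: ScanConfig, results: pd.DataFrame,
                 observations: pd.DataFrame, dropped_outliers=(),
                 seed: int = 0):
        self.species = species
        self.period_index = period_index
        self.response = response
        self.config = config
        self.results = results
        self.observations = observations
        self.dropped_outliers = list(dropped_outliers)
        self.seed = seed

    @property
    def fitted(self) -> pd.DataFrame:
        return self.results[self.results["excluded_reason"].isna()]

    @property
    def best(self) -> pd.Series:
        f = self.fitted
        if len(f) == 0:
            raise ValueError("no retained fits in scan")
        return f.loc[f["aicc"].idxmin()]

    def band(self, delta: float = 2.0) -> pd.DataFrame:
        """Retained fits within ``delta`` AICc of the best one."""
        f = self.fitted
        if len(f) == 0:
            return f
        return f[f["aicc"] - f["aicc"].min() <= delta]

    def average_band(self, term: str = "con", delta: float = 2.0) -> GridSummary:
        """Unweighted mean raw coefficient over the <=2 dAICc band.

        For survival scans, cells whose term SE exceeds the configured limit
        (default 100) are dropped from the averaging.
        """
        band = self.band(delta)
        se_col = f"se_{term}"
        if self.response == "survival" and se_col in band:
            band = band[band[se_col].fillna(np.inf) <= self.config.se_limit]
        if len(band) == 0:
            raise ValueError("empty averaging band")
        beta = band[f"beta_{term}"].to_numpy(float)
        rcol = {"con": "r_con", "het": "r_het", "all": "r_all"}[term]
        radii = band[rcol].to_numpy(float) if rcol in band else np.full(len(band), np.nan)
        ddcol = {"con": "dd_con", "het": "dd_het", "all": "dd_con"}[term]
        dds = band[ddcol].to_numpy(float) if ddcol in band else np.full(len(band), np.nan)
        if len(band) >= 2 and np.nanstd(radii) > 0:
            slope = float(np.polyfit(radii, beta, 1)[0])
        else:
            slope = np.nan
        mean = float(np.mean(beta))
        bimodal, kind = _bimodality(beta, mean)
        return GridSummary(
            species=self.species, period=self.period_index,
            response=self.response, term=term, coefficient=mean,
            n_models=len(band),
            mean_radius=float(np.nanmean(radii)) if len(radii) else np.nan,
            radius_range=float(np.nanmax(radii) - np.nanmin(radii))
            if np.isfinite(radii).any() else np.nan,
            mean_dd=float(np.nanmean(dds)) if np.isfinite(dds).any() else np.nan,
            slope_vs_radius=slope, bimodal=bimodal, bimodal_kind=kind)

    def compare_to_reference(self, reference, threshold: float = 7.0) -> str:
        """Classify best AICc against a reference scan/value.

        'much_better' at dAICc <= -threshold, 'much_worse' at >= +threshold,
        otherwise 'indistinguishable'.
        """
        ref_aicc = reference if np.isscalar(reference) else reference.best["aicc"]
        return compare_aicc(float(self.best["aicc"]) - float(ref_aicc), threshold)

    def summary(self) -> str:
        lines = [
            f"Neighborhood scan: {self.species}, period {self.period_index}, "
            f"{self.response} ({self.config.mode_label}, decay={self.config.decay})",
            f"  observations: {len(self.observations)}"
            + (f" ({len(self.dropped_outliers)} outliers dropped)"
               if self.dropped_outliers else ""),
            f"  grid cells: {len(self.results)} "
            f"({len(self.fitted)} retained)"]
        if len(self.fitted):
            b = self.best
            lines.append(
                f"  best cell: r_con={b.get('r_con')}, r_het={b.get('r_het')}, "
                f"dd_con={b.get('dd_con')}, dd_het={b.get('dd_het')}, "
                f"AICc={b['aicc']:.2f}")
            for term in ("con", "het"):
                if f"beta_{term}" in self.results:
                    try:
                        g = self.average_band(term)
                        lines.append(
                            f"  {term.upper()}: mean coef {g.coefficient:+.4f} "
                            f"over {g.n_models} models, mean r {g.mean_radius:.1f} m"
                            + (" [bimodal]" if g.bimodal else ""))
                    except ValueError:
                        pass
        return "\n".join(lines)

    def plot_coefficient_hist(self, term: str = "con", delta: float = 2.0, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        band = self.band(delta)
        ax.hist(band[f"beta_{term}"], bins=20)
        ax.set_xlabel(f"{term.upper()} coefficient (<= {delta} dAICc band)")
        ax.set_ylabel("models")
        return ax


def compare_aicc(delta: float, threshold: float = 7.0) -> str:
    if delta <= -threshold:
        return "much_better"
    if delta >= threshold:
        return "much_worse"
    return "indistinguishable"


def _fit_cell(obs: pd.DataFrame, response: str, terms: tuple) -> dict:
    """Fit one grid cell, returning a flat result row."""
    row: dict = {"excluded_reason": None}
    try:
        if response == "growth":
            res = GrowthModel.from_dataframe(obs, terms=terms).fit()
        else:
            res = SurvivalModel.from_dataframe(obs, terms=terms,
                                               response="survived").fit()
    except FitError as err:
        row["excluded_reason"] = err.reason
        return row
    row.update(n=res.nobs, k=res.k, aicc=res.aicc,
               intercept=float(res.params["const"]))
    name_map = {"ln_ba": "ba", "ln_con": "con", "ln_het": "het", "ln_all": "all"}
    for term in terms:
        short = name_map[term]
        row[f"beta_{short}"] = float(res.params[term])
        row[f"se_{short}"] = float(res.bse[term])
        row[f"t_{short}"] = float(res.tvalues[term])
        row[f"p_{short}"] = float(res.pvalues[term])
        if response == "growth":
            row[f"es_{short}"] = res.effect_size(term)
    if response == "growth":
        row["adj_r2"] = res.adj_r2
        row["pred_r2"] = res.pred_r2
    else:
        row["r_l2"] = res.r_l2
        row["r_l2_adj"] = res.r_l2_adj
    return row


def _pivot(pred: pd.DataFrame, col: str) -> pd.DataFrame:
    return pred[col].unstack("r")


def _scan_one_response(response: str, obs: pd.DataFrame, predictors: dict,
                       config: ScanConfig) -> pd.DataFrame:
    """Fit every grid cell given per-(dd pair) predictor tables."""
    rows = []
    terms = {"ba": ("ln_ba",), "ba+all": ("ln_ba", "ln_all"),
             "ba+con+het": ("ln_ba", "ln_con", "ln_het")}[config.form]
    for (ddc, ddh), pred in predictors.items():
        ln_con = _pivot(pred, "ln_con").reindex(obs["focal_id"])
        ln_het = _pivot(pred, "ln_het").reindex(obs["focal_id"])
        ln_all = _pivot(pred, "ln_all").reindex(obs["focal_id"])
        s_con = _pivot(pred, "sum_con").reindex(obs["focal_id"])
        s_het = _pivot(pred, "sum_het").reindex(obs["focal_id"])
        if config.form == "ba":
            row = {"dd_con": ddc, "dd_het": ddh}
            row.update(_fit_cell(obs, response, terms))
            rows.append(row)
            continue
        if config.form == "ba+all":
            for r in config.radii:
                cell = obs.copy()
                cell["ln_all"] = ln_all[r].to_numpy()
                row = {"dd_con": ddc, "dd_het": ddh, "r_all": r}
                row.update(_fit_cell(cell, response, terms))
                rows.append(row)
            continue
        for r_con, r_het in itertools.product(config.radii, config.radii):
            cell = obs.copy()
            cell["ln_con"] = ln_con[r_con].to_numpy()
            cell["ln_het"] = ln_het[r_het].to_numpy()
            row = {"dd_con": ddc, "dd_het": ddh,
                   "r_con": r_con, "r_het": r_het}
            reason = apply_fit_exclusions(
                s_con[r_con].to_numpy(), s_het[r_het].to_numpy(), response,
                config.min_con, config.min_zero_het)
            if reason is not None:
                row["excluded_reason"] = reason
            else:
                row.update(_fit_cell(cell, response, terms))
            rows.append(row)
    out = pd.DataFrame(rows)
    if "excluded_reason" not in out:
        out["excluded_reason"] = None
    return out


def _build_predictors(census: Census, focal: pd.DataFrame, period: PeriodSpec,
                      config: ScanConfig, seed: int) -> dict:
    """Predictor tables keyed by (dd_con, dd_het); a single (nan, nan) key
    holds the nonspatial table."""
    if not config.spatial:
        pred = predictor_table(census, focal, period, config.radii,
                               config.decay, "stem", canopy=None)
        return {(np.nan, np.nan): pred}
    canopy = fill_plot(census.trees, period.start_census, config.coeffs,
                       config.fill_mode, config.density, seed)
    out = {}
    dd_pairs = list(itertools.product(config.dd_levels, config.dd_levels))
    for ddc, ddh in dd_pairs:
        adjusted = adjust_plot(canopy, OverlapConfig(
            ddc, ddh, config.adjust_mode, config.fill_mode,
            config.position_mode), seed)
        out[(ddc, ddh)] = predictor_table(
            census, focal, period, config.radii, config.decay,
            config.position_mode, canopy=adjusted)
    return out


class NeighborhoodScan:
    """Grid scan of neighborhood models for one species, period and response.

    Orchestrates crown filling, overlap adjustment, predictor construction
    and per-cell fitting; ``fit(seed)`` returns a :class:`ScanResults`.
    """

    def __init__(self, census: Census, species: str, period_index: int,
                 response: str = "growth", config: ScanConfig = ScanConfig()):
        if response not in ("growth", "survival"):
            raise ValueError("response must be 'growth' or 'survival'")
        self.census = census
        self.species = species
        self.period_index = period_index
        self.response = response
        self.config = config

    def observations(self) -> tuple[pd.DataFrame, list]:
        period = self.census.plot.period(self.period_index)
        focal = focal_subset(self.census, self.species, period,
                             self.config.size_class)
        if self.response == "growth":
            obs = growth_observations(self.census, focal, period,
                                      self.config.epsilon)
            return exclude_outliers(obs, self.config.sd_threshold)
        return survival_observations(self.census, focal, period), []

    def fit(self, seed: int = 0,
            predictors: dict | None = None) -> ScanResults:
        period = self.census.plot.period(self.period_index)
        obs, dropped = self.observations()
        if predictors is None:
            focal = focal_subset(self.census, self.species, period,
                                 self.config.size_class)
            focal = focal[focal["tree_id"].isin(obs["focal_id"])]
            predictors = _build_predictors(self.census, focal, period,
                                           self.config, seed)
        results = _scan_one_response(self.response, obs, predictors,
                                     self.config)
        return ScanResults(self.species, self.period_index, self.response,
                           self.config, results, obs, dropped, seed)


def scan_pair(census: Census, species: str, period_index: int,
              config: ScanConfig = ScanConfig(), seed: int = 0
              ) -> tuple[ScanResults, ScanResults]:
    """Growth and survival scans sharing one set of predictor tables.

    Predictors are computed for the union of focal trees, then each response
    restricts to its own observations; the expensive canopy work is done once.
    """
    period = census.plot.period(period_index)
    focal = focal_subset(census, species, period, config.size_class)
    predictors = _build_predictors(census, focal, period, config, seed)
    growth = NeighborhoodScan(census, species, period_index, "growth",
                              config).fit(seed, predictors=predictors)
    survival = NeighborhoodScan(census, species, period_index, "survival",
                                config).fit(seed, predictors=predictors)
    return growth, survival
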