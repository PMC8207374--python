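"""Cross-species (community-level) syntheses of neighbor effects.

One row per selected species: averaged CON/HET effects on growth (squared
partial correlations) and survival (raw logistic coefficients) per period,
their between-period differences, plot basal area and the over-understory
class.  Provides the effect-vs-abundance regression, the growth-difference
vs survival-effect correlation, and a Procrustes comparison of two
community-level ordinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial import procrustes as _procrustes

from .allometry import basal_area
from .census import Census

__all__ = [
    "species_plot_ba",
    "classify_oui",
    "community_table",
    "CommunityRegression",
    "effect_vs_abundance",
    "difference_vs_survival",
    "procrustes_correlation",
    "procrustes_compare",
    "plot_difference_vs_survival",
]


def species_plot_ba(census: Census, census_index: int = 1,
                    gbh_min: float = 10.0) -> pd.Series:
    """Total plot basal area per species (m**2), stems >= gbh_min, one census."""
    t = census.trees
    g, s = f"gbh_{census_index}", f"status_{census_index}"
    alive = t[(t[s] == "alive") & (t[g] >= gbh_min)]
    ba = basal_area(alive[g].to_numpy(float)) / 1e4  # cm**2 -> m**2
    return pd.Series(ba, index=alive["species"]).groupby(level=0).sum()


def classify_oui(oui) -> np.ndarray:
    """Over-understory class: <20 understory, 20-55 intermediate, >55 overstory."""
    oui = np.asarray(oui, float)
    out = np.where(oui < 20, "understory",
                   np.where(oui <= 55, "intermediate", "overstory"))
    return np.where(np.isfinite(oui), out, "unknown")


def community_table(grid_summaries, census: Census | None = None,
                    census_index: int = 1) -> pd.DataFrame:
    """Assemble the one-row-per-species community table.

    ``grid_summaries`` is an iterable of :class:`~zoicomp.models.GridSummary`;
    columns are named ``<response>_<term>_p<period>``.  Adds between-period
    differences (P2 - P1) and, if a census is given, per-species plot BA and
    its log10.
    """
    cells: dict = {}
    for g in grid_summaries:
        cells.setdefault(g.species, {})[
            f"{g.response}_{g.term}_p{g.period}"] = g.coefficient
    table = pd.DataFrame.from_dict(cells, orient="index").sort_index()
    table.index.name = "species"
    for resp in ("growth", "survival"):
        for term in ("con", "het"):
            c1, c2 = f"{resp}_{term}_p1", f"{resp}_{term}_p2"
            if c1 in table and c2 in table:
                table[f"{resp}_{term}_diff"] = table[c2] - table[c1]
    if census is not None:
        ba = species_plot_ba(census, census_index)
        table["plot_ba"] = ba.reindex(table.index)
        table["log10_ba"] = np.log10(table["plot_ba"])
        if "oui" in census.trees.columns:
            oui = census.trees.groupby("species")["oui"].mean()
            table["oui"] = oui.reindex(table.index)
            table["oui_class"] = classify_oui(table["oui"])
    return table


@dataclass
class CommunityRegression:
    slope: float
    intercept: float
    t_slope: float
    p_slope: float
    adj_r2: float
    pred_r2: float
    n: int


def _ols_with_press(y: np.ndarray, x: np.ndarray) -> CommunityRegression:
    X = sm.add_constant(np.asarray(x, float))
    res = sm.OLS(np.asarray(y, float), X).fit()
    h = res.get_influence().hat_matrix_diag
    press = float(np.sum((res.resid / np.clip(1 - h, 1e-12, None)) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    return CommunityRegression(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        t_slope=float(res.tvalues[1]), p_slope=float(res.pvalues[1]),
        adj_r2=float(res.rsquared_adj),
        pred_r2=1.0 - press / sst if sst > 0 else np.nan, n=int(res.nobs))


def effect_vs_abundance(table: pd.DataFrame, effect_col: str,
                        ba_col: str = "log10_ba") -> CommunityRegression:
    """OLS of a species-level neighbor effect on log10 plot basal area."""
    sub = table[[effect_col, ba_col]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 species")
    return _ols_with_press(sub[effect_col].to_numpy(), sub[ba_col].to_numpy())


def difference_vs_survival(table: pd.DataFrame, diff_col: str, surv_col: str,
                           subset=None, method: str = "pearson"):
    """Correlation (and regression) of growth-effect change on survival effect.

    ``subset`` optionally restricts to species (e.g. those with survival
    effects significant at p < .1).  Returns (r, p, CommunityRegression).
    """
    sub = table if subset is None else table.loc[subset]
    sub = sub[[diff_col, surv_col]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 paired records")
    if method == "pearson":
        r, p = stats.pearsonr(sub[surv_col], sub[diff_col])
    elif method == "spearman":
        r, p = stats.spearmanr(sub[surv_col], sub[diff_col])
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    reg = _ols_with_press(sub[diff_col].to_numpy(), sub[surv_col].to_numpy())
    return float(r), float(p), reg


def procrustes_correlation(X, Y) -> float:
    """Procrustes correlation sqrt(1 - m2) after optimal similarity fit of Y on X."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("matrices must have identical shape")
    for M in (X, Y):
        if np.linalg.matrix_rank(M - M.mean(axis=0)) < M.shape[1]:
            raise ValueError("rank-deficient matrix")
    _, _, m2 = _procrustes(X, Y)
    return float(np.sqrt(max(0.0, 1.0 - m2)))


def procrustes_compare(X, Y, n_perm: int = 999, seed: int = 0):
    """Procrustes correlation with a row-permutation significance test.

    Permutes the rows (species) of Y; p = (1 + #{perm >= observed}) /
    (n_perm + 1), the standard protest-style estimate.
    """
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    obs = procrustes_correlation(X, Y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(Y))
        if procrustes_correlation(X, Y[perm]) >= obs:
            count += 1
    return obs, (count + 1) / (n_perm + 1)


def plot_difference_vs_survival(table: pd.DataFrame, diff_col: str,
                                surv_col: str, ax=None):
    """Scatter of growth-effect change vs survival effect, colored by OUI class."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    colors = {"understory": "green", "intermediate": "blue",
              "overstory": "red", "unknown": "gray"}
    cls = table.get("oui_class", pd.Series("unknown", index=table.index))
    for c, grp in table.groupby(cls):
        ax.scatter(grp[surv_col], grp[diff_col], c=colors.get(c, "gray"),
                   label=c, s=25)
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel(surv_col)
    ax.set_ylabel(diff_col)
    ax.legend(fontsize=8)
    return ax
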