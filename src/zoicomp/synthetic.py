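"""Synthetic stem-mapped censuses with known neighborhood dynamics.

Stands emulate a permanent tropical-forest plot: clustered multi-species stem
maps (Thomas process or CSR), right-skewed girth distributions with a 10-cm
census floor, and two inter-census periods.  Growth and survival between
censuses are generated *from the neighborhood regression equations
themselves* — lognormal basal-area increments and Bernoulli survival driven
by the CON/HET basal-area sums at a known true radius and overlap tolerance —
so that the inference pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .allometry import AllometryCoefficients, PUBLISHED_17, basal_area, gbh_from_basal_area
from .census import Census, PlotSpec
from .crowns import fill_plot
from .neighborhood import NeighborPoints
from .overlap import OverlapConfig, adjust_plot

__all__ = ["GrowthParams", "SurvivalParams", "SyntheticSpec",
           "generate_stand", "generate_dynamics", "generate_census",
           "generate_study"]


@dataclass(frozen=True)
class GrowthParams:
    """True coefficients of the generative growth equation (ln agr scale)."""

    intercept: float = -1.3
    alpha: float = 0.5            # size (ln ba) exponent
    beta_con: float = -0.2
    gamma_het: float = -0.1
    sigma: float = 0.2            # SD of the normal error on ln agr


@dataclass(frozen=True)
class SurvivalParams:
    """True coefficients of the generative logistic survival equation."""

    intercept: float = 5.0
    alpha: float = 0.2
    beta_con: float = -0.5
    gamma_het: float = -0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions of a synthetic census.

    Defaults mirror the study design this generator emulates: a 100 x 400 m
    plot with a 20-m analysis border, two periods of 10.00 and 11.07 years,
    clustered species maps and truncated-exponential girths from 10 cm.
    """

    plot: PlotSpec = PlotSpec(100.0, 400.0, 20.0, (0.0, 10.0, 21.07))
    n_species: int = 20
    total_trees: int = 6000
    counts: tuple | None = None   # explicit per-species counts override
    abundance_x: float = 0.95     # log-series-style rank-abundance parameter
    cluster: str = "thomas"       # or "csr"
    mean_offspring: float = 40.0
    cluster_sd: float = 6.0
    gbh_rate: float = 0.05        # 1/cm; right-skewed girths
    gbh_max: float = 200.0
    growth: GrowthParams = GrowthParams()
    survival: SurvivalParams = SurvivalParams()
    #: per-period overrides, e.g. {2: GrowthParams(...)} for regime shifts
    growth_by_period: dict = field(default_factory=dict)
    survival_by_period: dict = field(default_factory=dict)
    true_r_con: float = 10.0
    true_r_het: float = 10.0
    true_dd: float = 0.0
    decay: str = "linear"
    spatial: bool = True
    fill_mode: str = "larsm"
    adjust_mode: str = "relocation"
    coeffs: AllometryCoefficients = PUBLISHED_17

    def species_counts(self, rng: np.random.Generator) -> np.ndarray:
        if self.counts is not None:
            return np.asarray(self.counts, int)
        k = np.arange(1, self.n_species + 1)
        w = self.abundance_x**k / k
        return rng.multinomial(self.total_trees, w / w.sum())


def _truncated_exp_gbh(n: int, rate: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    u = rng.random(n)
    c = 1.0 - np.exp(-rate * (hi - lo))
    return np.round(lo - np.log(1.0 - u * c) / rate, 1)


def _thomas_points(n: int, plot: PlotSpec, mu: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Exactly n offspring of a Thomas cluster process clipped to the plot."""
    pts = []
    got = 0
    for _ in range(50):
        n_parents = max(1, int(np.ceil((n - got) / mu)))
        parents = np.column_stack([rng.uniform(0, plot.width, n_parents),
                                   rng.uniform(0, plot.length, n_parents)])
        counts = rng.poisson(mu, n_parents)
        reps = np.repeat(np.arange(n_parents), counts)
        off = parents[reps] + rng.normal(0.0, sd, (len(reps), 2))
        keep = plot.contains(off[:, 0], off[:, 1])
        off = off[keep]
        pts.append(off)
        got += len(off)
        if got >= n:
            break
    if got < n:  # top up with CSR in pathological settings
        extra = np.column_stack([rng.uniform(0, plot.width, n - got),
                                 rng.uniform(0, plot.length, n - got)])
        pts.append(extra)
    return np.concatenate(pts)[:n]


def generate_stand(spec: SyntheticSpec, seed: int = 0) -> pd.DataFrame:
    """First-census tree table: clustered species maps and girths."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(1,)))
    counts = spec.species_counts(rng)
    frames = []
    tid = 0
    oui_by_species = np.round(rng.uniform(0, 100, len(counts)), 0)
    for si, n in enumerate(counts):
        if n == 0:
            continue
        sp = f"sp{si + 1:02d}"
        if spec.cluster == "thomas":
            xy = _thomas_points(int(n), spec.plot, spec.mean_offspring,
                                spec.cluster_sd, rng)
        else:
            xy = np.column_stack([rng.uniform(0, spec.plot.width, int(n)),
                                  rng.uniform(0, spec.plot.length, int(n))])
        gbh = _truncated_exp_gbh(int(n), spec.gbh_rate, 10.0, spec.gbh_max, rng)
        frames.append(pd.DataFrame({
            "tree_id": [f"t{tid + j:06d}" for j in range(int(n))],
            "species": sp,
            "x": np.round(xy[:, 0], 1), "y": np.round(xy[:, 1], 1),
            "gbh_1": gbh, "status_1": "alive",
            "oui": oui_by_species[si]}))
        tid += int(n)
    return pd.concat(frames, ignore_index=True)


def _true_predictors(trees: pd.DataFrame, spec: SyntheticSpec, census: int,
                     pool_ids: set, seed: int) -> pd.DataFrame:
    """ln(1 + CON/HET sums) at the spec's true radii for every alive tree."""
    alive = trees[trees[f"status_{census}"] == "alive"]
    if spec.spatial:
        canopy = fill_plot(trees, census, spec.coeffs, spec.fill_mode,
                           seed=seed)
        if spec.true_dd > 0:
            canopy = adjust_plot(canopy, OverlapConfig(
                spec.true_dd, spec.true_dd, spec.adjust_mode,
                spec.fill_mode), seed)
        pool = NeighborPoints.from_canopy(canopy, pool_ids)
    else:
        pool = NeighborPoints.from_stems(trees, census, pool_ids)
    rmax = max(spec.true_r_con, spec.true_r_het)
    kdt = pool.kdtree() if len(pool) else None
    gcol = f"gbh_{census}"
    out = np.zeros((len(alive), 2))
    if kdt is not None:
        positions = alive[["x", "y"]].to_numpy(float)
        hits = kdt.query_ball_point(positions, rmax, return_sorted=True)
        from .neighborhood import DISTANCE_FLOOR, _decay
        for i, row in enumerate(alive.itertuples(index=False)):
            idx = np.asarray(hits[i], dtype=int)
            if len(idx) == 0:
                continue
            d = np.hypot(pool.x[idx] - positions[i, 0],
                         pool.y[idx] - positions[i, 1])
            base = ((pool.gbh[idx] >= float(getattr(row, gcol)))
                    & (pool.tree_id[idx] != row.tree_id))
            vals = pool.weight[idx] * _decay(d, spec.decay)
            con = base & (pool.species[idx] == row.species)
            out[i, 0] = vals[con & (d <= spec.true_r_con)].sum()
            out[i, 1] = vals[base & ~con & (d <= spec.true_r_het)].sum()
    return pd.DataFrame({"tree_id": alive["tree_id"].to_numpy(),
                         "ln_con": np.log1p(out[:, 0]),
                         "ln_het": np.log1p(out[:, 1])}).set_index("tree_id")


def generate_dynamics(trees: pd.DataFrame, spec: SyntheticSpec,
                      seed: int = 0, period_index: int = 1) -> pd.DataFrame:
    """Add the next census (girth and status) to a tree table.

    Survival is drawn first from the logistic equation using the full
    period-start neighborhood; growth of the survivors then uses surviving
    larger neighbors only, matching the fitted growth model's neighbor
    definition.  Dead trees carry their last measured girth.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(2, int(period_index))))
    c0, c1 = period_index, period_index + 1
    period = spec.plot.period(period_index)
    gp = spec.growth_by_period.get(period_index, spec.growth)
    sp_par = spec.survival_by_period.get(period_index, spec.survival)

    out = trees.copy()
    alive = out[f"status_{c0}"] == "alive"
    ids_alive = set(out.loc[alive, "tree_id"])
    pred0 = _true_predictors(out, spec, c0, ids_alive, seed)

    ln_ba = pd.Series(np.log(basal_area(out.loc[alive, f"gbh_{c0}"].to_numpy(float))),
                      index=out.loc[alive, "tree_id"])
    logit = (sp_par.intercept + sp_par.alpha * ln_ba
             + sp_par.beta_con * pred0["ln_con"].reindex(ln_ba.index)
             + sp_par.gamma_het * pred0["ln_het"].reindex(ln_ba.index))
    survived = pd.Series(rng.random(len(logit)) < expit(logit.to_numpy()),
                         index=logit.index)

    survivor_ids = set(survived.index[survived])
    pred1 = _true_predictors(out, spec, c0, survivor_ids, seed)
    mu = (gp.intercept + gp.alpha * ln_ba
          + gp.beta_con * pred1["ln_con"].reindex(ln_ba.index)
          + gp.gamma_het * pred1["ln_het"].reindex(ln_ba.index))
    agr = np.exp(mu.to_numpy() + rng.normal(0.0, gp.sigma, len(mu)))

    ba0 = basal_area(out.loc[alive, f"gbh_{c0}"].to_numpy(float))
    ba1 = ba0 + agr * period.duration_years
    gbh1 = np.round(gbh_from_basal_area(ba1), 1)

    out[f"gbh_{c1}"] = np.nan
    out[f"status_{c1}"] = "absent"
    out.loc[alive, f"status_{c1}"] = np.where(survived.to_numpy(), "alive", "dead")
    out.loc[alive, f"gbh_{c1}"] = np.where(
        survived.to_numpy(), gbh1, out.loc[alive, f"gbh_{c0}"])
    prev_dead = out[f"status_{c0}"] == "dead"
    out.loc[prev_dead, f"status_{c1}"] = "dead"
    out.loc[prev_dead, f"gbh_{c1}"] = out.loc[prev_dead, f"gbh_{c0}"]
    return out


def generate_census(spec: SyntheticSpec, seed: int = 0,
                    n_periods: int | None = None) -> Census:
    """Full synthetic census over all periods of the plot spec."""
    trees = generate_stand(spec, seed)
    if n_periods is None:
        n_periods = spec.plot.n_census - 1
    for p in range(1, n_periods + 1):
        trees = generate_dynamics(trees, spec, seed, p)
    return Census(trees=trees, plot=spec.plot)


def generate_study(spec: SyntheticSpec, seed: int = 0,
                   n_plots: int = 2) -> list[Census]:
    """Independent replicate plots (the two-plot study design)."""
    return [generate_census(spec, int(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(10 + i,)).generate_state(1)[0] % 2**31))
        for i in range(n_plots)]
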