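"""Distance-decayed neighborhood basal-area predictors.

For each focal tree the basal area of all larger surviving neighbors within a
circle of radius r is summed, split into conspecific (CON) and heterospecific
(HET) components, with an optional per-point distance decay (1, 1/d or
1/d**2).  Spatially extended sums run over crown points (each carrying its
share of the neighbor's basal area); nonspatial sums place each neighbor's
whole basal area at its stem.  With every crown radius forced to zero the two
are identical by construction — the nonspatial limit.

``ln_*`` columns are ln(sum + 1): 1 cm**2 is added before the log transform
to keep empty neighborhoods finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .allometry import basal_area
from .census import Census, PeriodSpec
from .overlap import AdjustedCanopy
from .crowns import Canopy

__all__ = [
    "DECAYS",
    "DISTANCE_FLOOR",
    "NeighborPoints",
    "focal_position",
    "neighbor_sum",
    "neighbor_sum_spatial",
    "neighbor_sum_nonspatial",
    "predictor_table",
    "jensen_gap",
]

DECAYS = ("none", "linear", "squared")

#: Distances are floored here (m) before decay weighting — the coordinate
#: precision scale — so 1/d never blows up for coincident points.
DISTANCE_FLOOR = 0.1


def _decay(d: np.ndarray, decay: str) -> np.ndarray:
    dd = np.maximum(d, DISTANCE_FLOOR)
    if decay == "none":
        return np.ones_like(dd)
    if decay == "linear":
        return 1.0 / dd
    if decay == "squared":
        return 1.0 / dd**2
    raise ValueError(f"unknown decay {decay!r}")


@dataclass
class NeighborPoints:
    """Flat arrays of candidate neighbor points for one plot/period."""

    x: np.ndarray
    y: np.ndarray
    weight: np.ndarray            # cm**2 of basal area per point
    species: np.ndarray           # object array of species codes
    gbh: np.ndarray               # source tree gbh at period start
    tree_id: np.ndarray           # source tree id per point
    _kdtree: cKDTree | None = None

    def __len__(self):
        return len(self.x)

    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(np.column_stack([self.x, self.y]))
        return self._kdtree

    @classmethod
    def from_canopy(cls, canopy: Canopy | AdjustedCanopy,
                    survivors: set) -> "NeighborPoints":
        xs, ys, ws, sps, gs, tids = [], [], [], [], [], []
        for c in canopy:
            if c.tree_id not in survivors or c.n_points == 0:
                continue
            xs.append(c.points[:, 0])
            ys.append(c.points[:, 1])
            ws.append(np.full(c.n_points, c.point_weight))
            sps.append(np.full(c.n_points, c.species, dtype=object))
            gs.append(np.full(c.n_points, c.gbh))
            tids.append(np.full(c.n_points, c.tree_id, dtype=object))
        if not xs:
            z = np.empty(0)
            return cls(z, z, z, np.empty(0, object), z, np.empty(0, object))
        return cls(np.concatenate(xs), np.concatenate(ys), np.concatenate(ws),
                   np.concatenate(sps), np.concatenate(gs), np.concatenate(tids))

    @classmethod
    def from_stems(cls, trees: pd.DataFrame, census: int,
                   survivors: set, gbh_min: float = 10.0) -> "NeighborPoints":
        gcol, scol = f"gbh_{census}", f"status_{census}"
        keep = ((trees[scol] == "alive") & (trees[gcol] >= gbh_min)
                & trees["tree_id"].isin(survivors))
        t = trees[keep]
        return cls(t["x"].to_numpy(float), t["y"].to_numpy(float),
                   basal_area(t[gcol].to_numpy(float)),
                   t["species"].to_numpy(object),
                   t[gcol].to_numpy(float), t["tree_id"].to_numpy(object))


def survivor_ids(trees: pd.DataFrame, period: PeriodSpec) -> set:
    """Trees alive at both period ends (the neighbor pool condition)."""
    s0, s1 = f"status_{period.start_census}", f"status_{period.end_census}"
    keep = (trees[s0] == "alive") & (trees[s1] == "alive")
    return set(trees.loc[keep, "tree_id"])


def focal_position(tree_id: str, stem_xy: tuple,
                   canopy: AdjustedCanopy | Canopy | None,
                   position_mode: str = "stem") -> tuple:
    """Focal location: stem coordinates or unshaded-crown centroid.

    ``crown`` mode takes the mean coordinate of the tree's current unflagged
    points (for the largest tree this coincides with the disc centroid and
    hence the stem, up to sampling noise); it falls back to the stem when the
    cloud vanished.
    """
    if position_mode == "stem" or canopy is None:
        return stem_xy
    cloud = canopy.clouds.get(tree_id)
    if cloud is None or cloud.n_points == 0:
        return stem_xy
    return cloud.centroid()


def neighbor_sum(pos: tuple, focal_id: str, focal_gbh: float,
                 focal_species: str, pool: NeighborPoints, r: float,
                 decay: str = "linear", klass: str = "ALL",
                 idx: np.ndarray | None = None) -> float:
    """Sum of decay-weighted point weights within radius r (closed boundary).

    Neighbors are points of trees with gbh >= the focal's (self excluded);
    ``klass`` restricts to conspecific (CON) or heterospecific (HET) sources.
    """
    if idx is None:
        idx = np.asarray(
            pool.kdtree().query_ball_point(pos, r, return_sorted=True), dtype=int)
    if len(idx) == 0:
        return 0.0
    d = np.hypot(pool.x[idx] - pos[0], pool.y[idx] - pos[1])
    mask = (d <= r) & (pool.gbh[idx] >= focal_gbh) & (pool.tree_id[idx] != focal_id)
    if klass == "CON":
        mask &= pool.species[idx] == focal_species
    elif klass == "HET":
        mask &= pool.species[idx] != focal_species
    elif klass != "ALL":
        raise ValueError(f"unknown neighbor class {klass!r}")
    if not mask.any():
        return 0.0
    return float(np.sum(pool.weight[idx][mask] * _decay(d[mask], decay)))


def neighbor_sum_spatial(pos, focal_id, focal_gbh, focal_species,
                         canopy: Canopy | AdjustedCanopy, survivors: set,
                         r: float, decay: str = "linear",
                         klass: str = "ALL") -> float:
    """Spatial neighborhood sum over crown points (convenience wrapper)."""
    pool = NeighborPoints.from_canopy(canopy, survivors)
    return neighbor_sum(pos, focal_id, focal_gbh, focal_species, pool, r,
                        decay, klass)


def neighbor_sum_nonspatial(pos, focal_id, focal_gbh, focal_species,
                            trees: pd.DataFrame, census: int, survivors: set,
                            r: float, decay: str = "linear",
                            klass: str = "ALL") -> float:
    """Nonspatial sum: each neighbor's whole ba at its stem coordinates."""
    pool = NeighborPoints.from_stems(trees, census, survivors)
    return neighbor_sum(pos, focal_id, focal_gbh, focal_species, pool, r,
                        decay, klass)


def predictor_table(census: Census, focal: pd.DataFrame, period: PeriodSpec,
                    radii=tuple(range(1, 21)), decay: str = "linear",
                    position_mode: str = "stem",
                    canopy: Canopy | AdjustedCanopy | None = None) -> pd.DataFrame:
    """CON/HET/ALL neighborhood sums for every focal tree and radius.

    Pass an (adjusted) canopy for the spatially extended predictors or
    ``None`` for the nonspatial ones.  Returns a tidy frame indexed by
    (focal_id, r) with ``sum_*`` and ``ln_* = ln(sum + 1)`` columns.
    ALL is computed as CON + HET so the identity holds exactly.
    """
    surv = survivor_ids(census.trees, period)
    if canopy is None:
        pool = NeighborPoints.from_stems(census.trees, period.start_census, surv)
    else:
        pool = NeighborPoints.from_canopy(canopy, surv)
    radii = sorted(radii)
    rmax = radii[-1]
    gcol = f"gbh_{period.start_census}"
    rows = []
    kdt = pool.kdtree() if len(pool) else None
    positions = [focal_position(row.tree_id, (float(row.x), float(row.y)),
                                canopy, position_mode)
                 for row in focal.itertuples(index=False)]
    hits = (kdt.query_ball_point(np.asarray(positions).reshape(-1, 2), rmax,
                                 return_sorted=True)
            if kdt is not None and len(positions) else None)
    for i, row in enumerate(focal.itertuples(index=False)):
        pos = positions[i]
        fid, fgbh, fsp = row.tree_id, float(getattr(row, gcol)), row.species
        idx = (np.asarray(hits[i], dtype=int) if hits is not None
               else np.empty(0, dtype=int))
        base = (pool.gbh[idx] >= fgbh) & (pool.tree_id[idx] != fid)
        d = np.hypot(pool.x[idx] - pos[0], pool.y[idx] - pos[1])
        con = base & (pool.species[idx] == fsp)
        het = base & ~(pool.species[idx] == fsp)
        vals = pool.weight[idx] * _decay(d, decay)
        for r in radii:
            within = d <= r
            s_con = float(np.sum(vals[con & within]))
            s_het = float(np.sum(vals[het & within]))
            rows.append((fid, r, s_con, s_het, s_con + s_het))
    out = pd.DataFrame(rows, columns=["focal_id", "r", "sum_con", "sum_het",
                                      "sum_all"])
    for k in ("con", "het", "all"):
        out[f"ln_{k}"] = np.log1p(out[f"sum_{k}"])
    return out.set_index(["focal_id", "r"])


def jensen_gap(cr: float, center_dist: float, n_points: int = 10_000,
               seed: int = 0) -> tuple:
    """Monte-Carlo mean inverse distance to a disc crown vs. to its center.

    Because 1/d is convex, the expected spatial (per-point) linear-decay sum
    for a single neighbor exceeds the nonspatial one — the Jensen's-inequality
    diagnostic.  Returns (mean over disc points of 1/d, 1/center_dist).
    """
    rng = np.random.default_rng(seed)
    r = cr * np.sqrt(rng.random(n_points))
    theta = 2 * np.pi * rng.random(n_points)
    x = center_dist + r * np.cos(theta)
    y = r * np.sin(theta)
    d = np.maximum(np.hypot(x, y), DISTANCE_FLOOR)
    return float(np.mean(1.0 / d)), 1.0 / max(center_dist, DISTANCE_FLOOR)
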