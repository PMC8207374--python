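"""Crowns as weighted random point clouds.

Each tree's circular zone of influence (radius from the crown allometry) is
filled with uniform random points which jointly carry the tree's basal area:

* ``equal`` — constant density (default 10 points per m**2 crown area),
* ``larsm`` — as many points as the tree's basal area in cm**2, so larger
  trees get disproportionally denser crowns (asymmetric competition).

Point weights are ``ba / N`` within a tree, so the summed weight equals the
tree's basal area exactly in both modes.  Filling is reproducible: a master
seed plus a per-tree substream derived from the tree id, so per-tree clouds do
not depend on iteration order.  A tree with cr = 0 degenerates to a single
stem point of weight ba — the nonspatial limit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .allometry import AllometryCoefficients, PUBLISHED_17, basal_area, crown_radius, crown_area

__all__ = ["CrownPointCloud", "Canopy", "fill_crown", "fill_plot", "tree_rng"]

FILL_MODES = ("equal", "larsm")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def tree_rng(master_seed: int, tree_id) -> np.random.Generator:
    """Deterministic per-tree random substream (part of the public seeding API)."""
    key = zlib.crc32(str(tree_id).encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,)))


@dataclass
class CrownPointCloud:
    """A tree's crown as weighted points.

    ``point_weight`` is uniform within the tree (cm**2 of basal area per
    point); ``shaded`` flags points lying within the overlap tolerance of a
    larger tree's point.
    """

    tree_id: str
    species: str
    gbh: float
    center: tuple
    cr: float
    points: np.ndarray            # (N, 2) m
    point_weight: float           # cm**2 per point
    fill_mode: str
    shaded: np.ndarray = field(default=None)  # bool (N,)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.shaded is None:
            self.shaded = np.zeros(len(self.points), dtype=bool)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def total_weight(self) -> float:
        return self.point_weight * self.n_points

    @property
    def ba(self) -> float:
        return basal_area(self.gbh)

    def centroid(self) -> tuple:
        """Mean coordinate of the current (unshaded) points; stem if empty."""
        pts = self.points[~self.shaded]
        if len(pts) == 0:
            return self.center
        return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))


def fill_crown(tree_id, species, gbh, x, y,
               coeffs: AllometryCoefficients = PUBLISHED_17,
               fill_mode: str = "larsm", density: float = 10.0,
               rng: np.random.Generator | None = None,
               seed: int | None = None) -> CrownPointCloud:
    """Fill one crown with uniform random points on its disc.

    equal: N = max(1, round(density * ca)); larsm: N = max(1, round(ba)).
    Rounding is half-away-from-zero.  Sampling uses the radius = cr*sqrt(u)
    transform so points are uniform on the disc.
    """
    if fill_mode not in FILL_MODES:
        raise ValueError(f"unknown fill mode {fill_mode!r}")
    if rng is None:
        rng = tree_rng(0 if seed is None else seed, tree_id)
    cr = float(crown_radius(gbh, coeffs))
    ba = basal_area(gbh)
    if cr == 0.0:
        return CrownPointCloud(tree_id, species, gbh, (x, y), 0.0,
                               np.array([[x, y]]), ba, fill_mode)
    if fill_mode == "equal":
        n = max(1, _round_half_away(density * crown_area(cr)))
    else:
        n = max(1, _round_half_away(ba))
    r = cr * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    pts = np.column_stack([x + r * np.cos(theta), y + r * np.sin(theta)])
    return CrownPointCloud(tree_id, species, gbh, (x, y), cr, pts,
                           ba / n, fill_mode)


@dataclass
class Canopy:
    """All crown clouds of a plot census, in census row order."""

    clouds: dict                  # tree_id -> CrownPointCloud
    fill_mode: str
    seed: int
    coeffs: AllometryCoefficients = PUBLISHED_17

    def __iter__(self):
        return iter(self.clouds.values())

    def __len__(self):
        return len(self.clouds)

    def total_weight(self) -> float:
        return float(sum(c.total_weight for c in self))

    def copy(self) -> "Canopy":
        clouds = {k: replace(c, points=c.points.copy(), shaded=c.shaded.copy())
                  for k, c in self.clouds.items()}
        return Canopy(clouds, self.fill_mode, self.seed, self.coeffs)

    def to_frame(self):
        """Long point table (tree_id, species, x, y, weight, shaded) for dumps."""
        import pandas as pd
        rows = []
        for c in self:
            rows.append(pd.DataFrame({
                "tree_id": c.tree_id, "species": c.species,
                "x": c.points[:, 0], "y": c.points[:, 1],
                "weight": c.point_weight, "shaded": c.shaded}))
        return pd.concat(rows, ignore_index=True) if rows else None

    def plot(self, ax=None, max_points: int = 20000):
        """Quick-look scatter of crown points, colored by species."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        frame = self.to_frame()
        if frame is not None:
            if len(frame) > max_points:
                frame = frame.sample(max_points, random_state=0)
            for sp, grp in frame.groupby("species"):
                ax.scatter(grp["x"], grp["y"], s=2, label=sp, alpha=0.5)
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
        ax.set_ylabel("y (m)")
        return ax


def fill_plot(trees, census: int = 1,
              coeffs: AllometryCoefficients = PUBLISHED_17,
              fill_mode: str = "larsm", density: float = 10.0,
              seed: int = 0, gbh_min: float = 10.0) -> Canopy:
    """Fill every alive tree's crown (gbh >= gbh_min) at one census.

    Per-tree substreams are derived from ``(seed, tree_id)`` so the result is
    independent of row order; the summed point weight over the plot equals the
    summed basal area exactly.
    """
    gbh_col, status_col = f"gbh_{census}", f"status_{census}"
    clouds = {}
    for row in trees.itertuples(index=False):
        if getattr(row, status_col) != "alive":
            continue
        gbh = getattr(row, gbh_col)
        if not np.isfinite(gbh) or gbh < gbh_min:
            continue
        clouds[row.tree_id] = fill_crown(
            row.tree_id, row.species, float(gbh), float(row.x), float(row.y),
            coeffs, fill_mode, density, rng=tree_rng(seed, row.tree_id))
    return Canopy(clouds, fill_mode, seed, coeffs)
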