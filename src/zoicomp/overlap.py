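"""Crown overlap flagging and plasticity adjustment.

A crown point is "shaded" when a point of a strictly larger (taller) tree's
crown lies within a tolerance Δd of it; Δd may differ for conspecific
(``dd_con``) and heterospecific (``dd_het``) larger neighbors.  Shaded points
are then either removed (pruning) or relocated into the unshaded part of the
crown, whose outline is taken as the outermost contour of a 2-D kernel
density estimate of the unshaded points.  Adjustment is hierarchical: trees
are processed from largest to smallest and each tree is flagged against the
*already adjusted* clouds of its larger neighbors, so no residual overlap
remains at tolerance Δd.

Δd = 0 flags nothing: with continuous coordinates two points never coincide
exactly, so the crowns overlap "symmetrically" and stay fully present.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .crowns import Canopy, CrownPointCloud

__all__ = [
    "DD_GRID",
    "OverlapConfig",
    "AdjustedCanopy",
    "dd_combinations",
    "flag_shaded",
    "adjust_removal",
    "adjust_relocation",
    "adjust_plot",
    "lowest_density_contour",
]

#: Overlap tolerance grid, m (7 levels; 49 conspecific x heterospecific pairs).
DD_GRID = tuple(np.round(np.arange(0.0, 1.21, 0.2), 1))

ADJUST_MODES = ("removal", "relocation")
POSITION_MODES = ("stem", "crown")


@dataclass(frozen=True)
class OverlapConfig:
    dd_con: float = 0.0
    dd_het: float = 0.0
    adjust_mode: str = "relocation"
    fill_mode: str = "larsm"
    position_mode: str = "stem"

    def __post_init__(self):
        if self.dd_con < 0 or self.dd_het < 0:
            raise ValueError("overlap tolerances must be >= 0")
        if self.adjust_mode not in ADJUST_MODES:
            raise ValueError(f"unknown adjust mode {self.adjust_mode!r}")
        if self.position_mode not in POSITION_MODES:
            raise ValueError(f"unknown position mode {self.position_mode!r}")

    @property
    def max_dd(self) -> float:
        return max(self.dd_con, self.dd_het)


def dd_combinations(grid=DD_GRID):
    """All (dd_con, dd_het) pairs of the tolerance grid (49 by default)."""
    return list(itertools.product(grid, grid))


@dataclass
class AdjustedCanopy:
    """Adjusted clouds plus the trees that vanished (lost every point)."""

    config: OverlapConfig
    clouds: dict                  # tree_id -> CrownPointCloud (adjusted)
    vanished: set = field(default_factory=set)
    seed: int = 0

    def __iter__(self):
        return iter(self.clouds.values())


# ---------------------------------------------------------------------------
# neighbor-point accumulator for the hierarchical sweep


class _LargerPoints:
    """Points of already-processed (strictly larger) trees, queryable by species.

    Backed by one cKDTree per species, rebuilt lazily when that species grew.
    Results are identical to the O(n^2) all-pairs distance check.
    """

    def __init__(self):
        self._chunks: dict[str, list[np.ndarray]] = {}
        self._trees: dict[str, cKDTree | None] = {}

    def add(self, species: str, pts: np.ndarray) -> None:
        if len(pts) == 0:
            return
        self._chunks.setdefault(species, []).append(pts)
        self._trees[species] = None  # mark dirty

    def _tree(self, species: str) -> cKDTree | None:
        if species not in self._chunks:
            return None
        t = self._trees.get(species)
        if t is None:
            t = cKDTree(np.concatenate(self._chunks[species]))
            self._trees[species] = t
        return t

    def _within(self, pts: np.ndarray, species_sel, dd: float) -> np.ndarray:
        """True where any point of the selected species lies within dd."""
        out = np.zeros(len(pts), dtype=bool)
        if dd <= 0:
            return out
        for sp in species_sel:
            t = self._tree(sp)
            if t is None:
                continue
            d, _ = t.query(pts, k=1, distance_upper_bound=dd * (1 + 1e-12))
            out |= d <= dd
        return out

    def shade_flags(self, pts: np.ndarray, species: str,
                    dd_con: float, dd_het: float) -> np.ndarray:
        het_species = [sp for sp in self._chunks if sp != species]
        flags = self._within(pts, [species], dd_con)
        flags |= self._within(pts, het_species, dd_het)
        return flags

    def clear_mask(self, pts: np.ndarray, species: str,
                   dd_con: float, dd_het: float) -> np.ndarray:
        """True where a candidate point would NOT be shaded."""
        return ~self.shade_flags(pts, species, dd_con, dd_het)


def _size_order(clouds: dict) -> list[list[str]]:
    """Tree ids in descending gbh, grouped into equal-gbh batches.

    Ties are broken by tree_id for determinism, but trees of equal gbh never
    shade each other (larger gbh is taken to mean taller).
    """
    items = sorted(clouds.values(), key=lambda c: (-c.gbh, str(c.tree_id)))
    batches = []
    for _, grp in itertools.groupby(items, key=lambda c: c.gbh):
        batches.append([c.tree_id for c in grp])
    return batches


def flag_shaded(canopy: Canopy | dict, config: OverlapConfig) -> dict:
    """Shading flags per tree against the *current* clouds of larger trees.

    This is the single-pass flagging primitive (no adjustment): every tree's
    points are tested against the as-given clouds of all strictly larger
    trees.  cr = 0 clouds are exempt in both directions (they are mathematical
    points, the nonspatial limit).
    """
    clouds = canopy.clouds if isinstance(canopy, Canopy) else canopy
    flags = {tid: np.zeros(c.n_points, dtype=bool) for tid, c in clouds.items()}
    if config.max_dd <= 0:
        return flags
    larger = _LargerPoints()
    for batch in _size_order(clouds):
        for tid in batch:
            c = clouds[tid]
            if c.cr > 0:
                flags[tid] = larger.shade_flags(
                    c.points, c.species, config.dd_con, config.dd_het)
        for tid in batch:
            c = clouds[tid]
            if c.cr > 0:
                larger.add(c.species, c.points)
    return flags


def adjust_removal(cloud: CrownPointCloud, flags: np.ndarray) -> CrownPointCloud:
    """Delete flagged points; survivor weights unchanged (effective ba shrinks)."""
    flags = np.asarray(flags, bool)
    return replace(cloud, points=cloud.points[~flags],
                   shaded=np.zeros(int((~flags).sum()), dtype=bool))


# ---------------------------------------------------------------------------
# KDE contour machinery for relocation


def _pretty(lo: float, hi: float, n: int = 10) -> np.ndarray:
    """R-style pretty axis levels covering [lo, hi] (steps 1, 2, 2.5, 5 x 10^k)."""
    if hi <= lo:
        return np.array([lo])
    raw = (hi - lo) / n
    mag = 10.0 ** np.floor(np.log10(raw))
    for mult in (1.0, 2.0, 2.5, 5.0, 10.0):
        step = mult * mag
        if step >= raw:
            break
    lo_i = np.floor(lo / step) * step
    hi_i = np.ceil(hi / step) * step
    return np.arange(lo_i, hi_i + 0.5 * step, step)


def _nrd_bandwidth(v: np.ndarray) -> float:
    """Normal-reference bandwidth 1.06 * min(sd, IQR/1.34) * n^(-1/5)."""
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    q1, q3 = np.percentile(v, [25, 75])
    iqr = (q3 - q1) / 1.34
    scale = min(x for x in (sd, iqr) if x > 0) if max(sd, iqr) > 0 else 0.0
    return 1.06 * scale * len(v) ** (-0.2)


def lowest_density_contour(points: np.ndarray, grid_size: int = 25):
    """Outermost KDE contour region of a 2-D point set as a shapely geometry.

    Gaussian product kernel with a normal-reference bandwidth per axis,
    evaluated on a ``grid_size x grid_size`` grid spanning the points padded
    by one bandwidth; the region is the filled contour at the lowest pretty
    level strictly between the grid minimum and maximum (the outermost
    contour line a default density plot would draw).  Returns ``None`` for
    degenerate inputs (fewer than 3 points or a zero-variance axis).
    """
    points = np.asarray(points, float)
    if len(points) < 3:
        return None
    hx, hy = _nrd_bandwidth(points[:, 0]), _nrd_bandwidth(points[:, 1])
    if hx <= 0 or hy <= 0:
        return None
    gx = np.linspace(points[:, 0].min() - hx, points[:, 0].max() + hx, grid_size)
    gy = np.linspace(points[:, 1].min() - hy, points[:, 1].max() + hy, grid_size)
    ux = np.exp(-0.5 * ((gx[:, None] - points[None, :, 0]) / hx) ** 2)
    uy = np.exp(-0.5 * ((gy[:, None] - points[None, :, 1]) / hy) ** 2)
    z = (ux @ uy.T).T / (2 * np.pi * hx * hy * len(points))  # z[iy, ix]
    levels = _pretty(float(z.min()), float(z.max()))
    inner = levels[(levels > z.min()) & (levels < z.max())]
    if len(inner) == 0:
        return None
    level = float(inner[0])

    from contourpy import FillType, contour_generator
    gen = contour_generator(x=gx, y=gy, z=z, fill_type=FillType.OuterOffset)
    pts_list, off_list = gen.filled(level, np.inf)
    polys = []
    for pts, offs in zip(pts_list, off_list):
        rings = [pts[offs[i]:offs[i + 1]] for i in range(len(offs) - 1)]
        if len(rings[0]) >= 3:
            polys.append(Polygon(rings[0], holes=[r for r in rings[1:] if len(r) >= 3]))
    if not polys:
        return None
    region = unary_union(polys)
    return region if not region.is_empty else None


def _sample_in_region(region, n: int, rng: np.random.Generator,
                      clear_fn=None, max_batches: int = 200) -> np.ndarray | None:
    """Uniform rejection sample n points inside a shapely region.

    ``clear_fn(pts) -> bool mask`` optionally imposes an extra acceptance
    condition (staying outside the shade tolerance of larger trees).
    """
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((0, 2))
    for _ in range(max_batches):
        m = max(4 * (n - len(out)), 32)
        cand = np.column_stack([rng.uniform(minx, maxx, m),
                                rng.uniform(miny, maxy, m)])
        ok = shapely.contains_xy(region, cand[:, 0], cand[:, 1])
        if clear_fn is not None and ok.any():
            ok[ok] = clear_fn(cand[ok])
        out = np.vstack([out, cand[ok]])
        if len(out) >= n:
            return out[:n]
    return None


def adjust_relocation(cloud: CrownPointCloud, flags: np.ndarray,
                      rng: np.random.Generator,
                      clear_fn=None) -> CrownPointCloud | None:
    """Move flagged points into the unshaded crown contour.

    Point count and summed weight are conserved.  The target region is the
    outermost KDE contour of the unshaded points (it may extend beyond the
    original disc — plastic crowns).  Candidate positions failing ``clear_fn``
    (still within Δd of a larger tree's point) are rejected.  Degenerate
    unshaded sets fall back to jittered copies of unshaded points, and
    ultimately to exact copies (unshaded by definition).  Returns ``None``
    when every point is flagged (the tree vanishes as a neighbor).
    """
    flags = np.asarray(flags, bool)
    if not flags.any():
        return replace(cloud, shaded=np.zeros(cloud.n_points, dtype=bool))
    unshaded = cloud.points[~flags]
    if len(unshaded) == 0:
        return None
    k = int(flags.sum())
    region = lowest_density_contour(unshaded)
    moved = None
    if region is not None:
        moved = _sample_in_region(region, k, rng, clear_fn)
    if moved is None:
        # documented fallback: jittered copies of unshaded points
        jitter = max(_nrd_bandwidth(unshaded[:, 0]),
                     _nrd_bandwidth(unshaded[:, 1]), 0.05)
        for _ in range(50):
            base = unshaded[rng.integers(0, len(unshaded), k)]
            cand = base + rng.normal(0.0, jitter, (k, 2))
            ok = (clear_fn(cand) if clear_fn is not None
                  else np.ones(k, dtype=bool))
            if ok.all():
                moved = cand
                break
        if moved is None:
            moved = unshaded[rng.integers(0, len(unshaded), k)]
    pts = cloud.points.copy()
    pts[flags] = moved
    return replace(cloud, points=pts,
                   shaded=np.zeros(cloud.n_points, dtype=bool))


def adjust_plot(canopy: Canopy, config: OverlapConfig,
                seed: int | None = None) -> AdjustedCanopy:
    """Hierarchical overlap adjustment of a whole plot canopy.

    Trees are processed in descending gbh (ties by id); each tree is flagged
    against the already-adjusted clouds of strictly larger trees, adjusted
    (removal or relocation), and only then added to the shading pool — the
    [A -> B] -> C scheme that leaves no overlap at tolerance Δd among the
    adjusted crowns.  Deterministic given the seed.  Input clouds are not
    mutated.
    """
    if seed is None:
        seed = canopy.seed
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(0x5EED,)))
    clouds = canopy.clouds
    out: dict = {}
    vanished: set = set()
    if config.max_dd <= 0:
        out = {tid: replace(c, points=c.points.copy(),
                            shaded=np.zeros(c.n_points, dtype=bool))
               for tid, c in clouds.items()}
        return AdjustedCanopy(config, out, set(), seed)

    larger = _LargerPoints()
    adjusted_batches: dict = {}
    for batch in _size_order(clouds):
        batch_result = {}
        for tid in batch:
            c = clouds[tid]
            if c.cr == 0:
                batch_result[tid] = replace(c, points=c.points.copy())
                continue
            flags = larger.shade_flags(c.points, c.species,
                                       config.dd_con, config.dd_het)
            if config.adjust_mode == "removal":
                adj = adjust_removal(c, flags)
                if adj.n_points == 0:
                    adj = None
            else:
                def clear(pts, _sp=c.species):
                    return larger.clear_mask(pts, _sp,
                                             config.dd_con, config.dd_het)
                adj = adjust_relocation(c, flags, rng, clear_fn=clear)
            if adj is None:
                vanished.add(tid)
            else:
                batch_result[tid] = adj
        for tid, adj in batch_result.items():
            if clouds[tid].cr > 0 and adj.n_points:
                larger.add(adj.species, adj.points)
        adjusted_batches.update(batch_result)

    # preserve census order of the input canopy
    out = {tid: adjusted_batches[tid] for tid in clouds if tid in adjusted_batches}
    return AdjustedCanopy(config, out, vanished, seed)
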