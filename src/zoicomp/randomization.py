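"""Location-randomization null model.

Tree positions are re-drawn uniformly in the plot under minimum nearest-
neighbor distance rules that differ within and between stem size classes,
preserving every species' size structure exactly.  Re-running the analysis
pipeline on each randomized layout yields null distributions for the
per-species neighbor effects (±3 SE envelopes) and for the community-level
regression slope (sign counts and a t-value envelope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import Census, PlotSpec

__all__ = [
    "RandomizationConfig",
    "size_class",
    "randomize_positions",
    "null_envelopes",
    "NullSlopeSummary",
    "null_slope_distribution",
]

#: Effect-magnitude bands for |observed - null mean|: (moderate, large).
MAGNITUDE_BANDS = {"growth": (0.06, 0.1), "survival": (0.6, 1.0)}


@dataclass(frozen=True)
class RandomizationConfig:
    """Placement rules for the location randomization.

    Six gbh size classes partition [10, inf); nearest neighbors must be at
    least ``min_same`` m apart within a class and ``min_dist`` m apart across
    classes.  The class bounds and distances follow simple packing rules and
    are fully configurable.
    """

    n_runs: int = 100
    class_bounds: tuple = (10.0, 30.0, 60.0, 120.0, 240.0, 480.0)
    min_same: float = 1.0
    min_diff: float = 0.5
    max_attempts: int = 200

    def __post_init__(self):
        if self.min_same < 0 or self.min_diff < 0:
            raise ValueError("minimum distances must be >= 0")
        if list(self.class_bounds) != sorted(self.class_bounds):
            raise ValueError("class bounds must be increasing")


def size_class(gbh, bounds=(10.0, 30.0, 60.0, 120.0, 240.0, 480.0)):
    """0-based size-class index; the last class is open above."""
    return np.clip(np.searchsorted(np.asarray(bounds), np.asarray(gbh),
                                   side="right") - 1, 0, len(bounds) - 1)


def randomize_positions(trees: pd.DataFrame, plot: PlotSpec,
                        config: RandomizationConfig = RandomizationConfig(),
                        seed: int = 0, run_index: int = 0,
                        gbh_col: str = "gbh_1") -> pd.DataFrame:
    """One randomized layout: new x, y; species, sizes and statuses unchanged.

    Sequential random placement in descending gbh (large trees first, the
    feasibility logic of minimum-distance packing) with rejection until the
    distance rules hold; after ``max_attempts`` draws the tree is placed
    anyway with a warning (documented relaxation).  The same (seed,
    run_index) always reproduces the same layout.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(run_index),)))
    out = trees.copy().reset_index(drop=True)
    order = np.argsort(-out[gbh_col].fillna(0.0).to_numpy(), kind="stable")
    cls = size_class(out[gbh_col].fillna(10.0).to_numpy(), config.class_bounds)
    cell = max(config.min_same, config.min_diff, 1e-6)
    grid: dict = {}
    xs = np.empty(len(out))
    ys = np.empty(len(out))
    relaxed = 0
    for i in order:
        ci = cls[i]
        placed = False
        for _ in range(config.max_attempts):
            x = rng.uniform(0.0, plot.width)
            y = rng.uniform(0.0, plot.length)
            gx, gy = int(x / cell), int(y / cell)
            ok = True
            for nx in range(gx - 1, gx + 2):
                for ny in range(gy - 1, gy + 2):
                    for (px, py, pc) in grid.get((nx, ny), ()):
                        need = config.min_same if pc == ci else config.min_diff
                        if (x - px) ** 2 + (y - py) ** 2 < need**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                placed = True
                break
        if not placed:
            relaxed += 1
        xs[i], ys[i] = x, y
        grid.setdefault((int(x / cell), int(y / cell)), []).append((x, y, cls[i]))
    if relaxed:
        warnings.warn(f"minimum-distance rules relaxed for {relaxed} trees "
                      "after attempt cap", stacklevel=2)
    out["x"], out["y"] = np.round(xs, 1), np.round(ys, 1)
    return out


def null_envelopes(observed: pd.Series, null_runs: pd.DataFrame,
                   response: str = "growth") -> pd.DataFrame:
    """Per-species ±3 SE null envelopes and significance classification.

    ``observed`` maps species -> observed averaged effect; ``null_runs`` has
    one row per randomization run and one column per species.  The SE is the
    standard deviation of the effect across runs (each run yields one effect
    estimate, so the across-run SD estimates its sampling SE under the null).
    Species outside null mean ± 3 SE are classified positive/negative;
    |observed - null mean| is banded as small / moderate / large.
    """
    if len(null_runs) < 2:
        raise ValueError("need at least 2 randomization runs")
    mod, large = MAGNITUDE_BANDS[response]
    mean = null_runs.mean(axis=0)
    se = null_runs.std(axis=0, ddof=1)
    rows = []
    for sp in observed.index:
        m, s, obs = mean.get(sp, np.nan), se.get(sp, np.nan), observed[sp]
        lo, hi = m - 3 * s, m + 3 * s
        if not np.isfinite(obs) or not np.isfinite(m):
            cls = "na"
        elif obs > hi:
            cls = "positive"
        elif obs < lo:
            cls = "negative"
        else:
            cls = "ns"
        diff = abs(obs - m)
        band = ("large" if diff >= large else
                "moderate" if diff >= mod else "small")
        rows.append((sp, obs, m, s, lo, hi, cls, band))
    return pd.DataFrame(rows, columns=[
        "species", "observed", "null_mean", "null_se", "lower", "upper",
        "classification", "magnitude"]).set_index("species")


@dataclass
class NullSlopeSummary:
    n_positive: int
    n_negative: int
    t_min: float
    t_max: float
    observed_slope: float
    observed_t: float
    p_two_tailed: float
    n_runs: int


def null_slope_distribution(observed_slope: float, observed_t: float,
                            null_df: pd.DataFrame) -> NullSlopeSummary:
    """Community-regression slope null: sign counts, t envelope, empirical p.

    ``null_df`` needs columns ``slope`` and ``t`` (one row per run).  The
    two-tailed p is the rank of |observed t| among the null |t| values:
    (1 + #{|t_null| >= |t_obs|}) / (n + 1).
    """
    slopes = null_df["slope"].to_numpy(float)
    ts = null_df["t"].to_numpy(float)
    n = len(null_df)
    more_extreme = int(np.sum(np.abs(ts) >= abs(observed_t)))
    return NullSlopeSummary(
        n_positive=int(np.sum(slopes > 0)), n_negative=int(np.sum(slopes < 0)),
        t_min=float(ts.min()), t_max=float(ts.max()),
        observed_slope=float(observed_slope), observed_t=float(observed_t),
        p_two_tailed=(more_extreme + 1) / (n + 1), n_runs=n)
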