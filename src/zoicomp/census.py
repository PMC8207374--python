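"""Census tables, plot geometry and focal-tree selection.

A census is stored as a wide :class:`pandas.DataFrame` with one row per stem
and columns ``tree_id, species, x, y, gbh_<c>, status_<c>[, oui]`` for census
indices ``c = 1..n``.  Coordinates are meters from the plot origin (corner),
recorded to 0.1 m.  Statuses are ``alive``, ``dead`` or ``absent`` (not yet
recruited / not measured); a tree never transitions dead -> alive.  Dead trees
carry their last measured gbh.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STATUSES",
    "PlotSpec",
    "PeriodSpec",
    "TreeRecord",
    "Census",
    "read_census",
    "read_census_long",
    "write_census",
    "select_focal_species",
    "focal_subset",
]

STATUSES = ("alive", "dead", "absent")

REQUIRED_COLUMNS = ("tree_id", "species", "x", "y")


@dataclass(frozen=True)
class PlotSpec:
    """Plot geometry and census timing.

    ``census_dates`` are in (decimal) years; consecutive differences define
    the period lengths.  ``border`` is the width of the edge strip whose trees
    are never focal (but remain valid neighbors).
    """

    width: float = 100.0
    length: float = 400.0
    border: float = 20.0
    census_dates: tuple = (0.0, 10.0, 21.07)

    def __post_init__(self) -> None:
        if self.border >= min(self.width, self.length) / 2:
            raise ValueError("border must be < min(width, length)/2")
        if len(self.census_dates) >= 2:
            if np.any(np.diff(self.census_dates) <= 0):
                raise ValueError("census dates must be strictly increasing")

    @property
    def n_census(self) -> int:
        return len(self.census_dates)

    @property
    def area_m2(self) -> float:
        return self.width * self.length

    def period(self, index: int) -> "PeriodSpec":
        """1-based period index -> PeriodSpec between censuses index, index+1."""
        if not 1 <= index <= self.n_census - 1:
            raise ValueError(f"period index {index} out of range")
        d0, d1 = self.census_dates[index - 1], self.census_dates[index]
        return PeriodSpec(index, index + 1, round(d1 - d0, 6))

    def contains(self, x, y) -> np.ndarray:
        x, y = np.asarray(x, float), np.asarray(y, float)
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.length)

    def in_core(self, x, y) -> np.ndarray:
        """Inside the focal core, i.e. >= border from every edge (closed test)."""
        x, y = np.asarray(x, float), np.asarray(y, float)
        b = self.border
        return ((x >= b) & (x <= self.width - b)
                & (y >= b) & (y <= self.length - b))


@dataclass(frozen=True)
class PeriodSpec:
    start_census: int
    end_census: int
    duration_years: float

    def __post_init__(self) -> None:
        if self.duration_years <= 0:
            raise ValueError("period duration must be positive")


@dataclass
class TreeRecord:
    """One stem; row-level view of a census table."""

    tree_id: str
    species: str
    x: float
    y: float
    gbh_by_census: dict = field(default_factory=dict)
    status_by_census: dict = field(default_factory=dict)
    oui: float | None = None


@dataclass
class Census:
    """A parsed census: tree table, plot geometry, and a rejection report."""

    trees: pd.DataFrame
    plot: PlotSpec
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tree_id", "reason"]))

    @property
    def census_indices(self) -> list[int]:
        return sorted(int(m.group(1)) for c in self.trees.columns
                      if (m := re.fullmatch(r"gbh_(\d+)", c)))

    def records(self) -> list[TreeRecord]:
        idx = self.census_indices
        out = []
        for row in self.trees.itertuples(index=False):
            out.append(TreeRecord(
                tree_id=row.tree_id, species=row.species, x=row.x, y=row.y,
                gbh_by_census={c: getattr(row, f"gbh_{c}") for c in idx},
                status_by_census={c: getattr(row, f"status_{c}") for c in idx},
                oui=getattr(row, "oui", None),
            ))
        return out


def _validate(df: pd.DataFrame, plot: PlotSpec, gbh_floor: float):
    """Split a raw table into (valid, rejected-with-reason)."""
    reasons = {}

    def reject(mask, reason):
        for tid in df.loc[mask, "tree_id"]:
            reasons.setdefault(tid, reason)

    xy_bad = ~np.isfinite(df["x"].to_numpy()) | ~np.isfinite(df["y"].to_numpy())
    reject(xy_bad, "unparseable coordinate")
    oob = ~xy_bad & ~plot.contains(df["x"], df["y"])
    reject(oob, "coordinate outside plot extent")

    gbh_cols = [c for c in df.columns if re.fullmatch(r"gbh_\d+", c)]
    status_cols = [c for c in df.columns if re.fullmatch(r"status_\d+", c)]
    for c in status_cols:
        bad = ~df[c].isin(STATUSES)
        reject(bad, f"invalid status in {c}")
    for c in gbh_cols:
        sc = "status_" + c.split("_")[1]
        if sc in df.columns:
            alive = df[sc] == "alive"
            bad = alive & (df[c].isna() | (df[c] < gbh_floor))
            reject(bad, f"alive tree below gbh floor in {c}")
    # dead -> alive transitions are impossible
    order = sorted(int(c.split("_")[1]) for c in status_cols)
    for a, b in zip(order, order[1:]):
        bad = (df[f"status_{a}"] == "dead") & (df[f"status_{b}"] == "alive")
        reject(bad, f"dead->alive transition {a}->{b}")

    dup = df["tree_id"].duplicated(keep=False)
    reject(dup, "duplicate tree_id")

    bad_ids = set(reasons)
    valid = df[~df["tree_id"].isin(bad_ids)].reset_index(drop=True)
    rejected = pd.DataFrame(
        {"tree_id": list(reasons), "reason": list(reasons.values())})
    return valid, rejected


def read_census(path, plot: PlotSpec | None = None, schema: dict | None = None,
                sep: str = ",", gbh_floor: float = 10.0) -> Census:
    """Read a wide delimited census file.

    ``schema`` optionally maps file column names onto the canonical ones
    (e.g. ``{"stem": "tree_id", "sp": "species"}``).  Records with
    unparseable or out-of-bounds coordinates, invalid statuses, or alive
    girths below the floor are dropped and listed, per tree, in
    ``Census.rejected``.  A missing required column is a hard error.
    """
    df = pd.read_csv(path, sep=sep, dtype={"tree_id": str, "species": str})
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"census file {path} missing required columns: {missing}")
    if not any(re.fullmatch(r"gbh_\d+", c) for c in df.columns):
        raise ValueError(f"census file {path} has no gbh_<census> column")
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    if plot is None:
        plot = PlotSpec(width=float(np.ceil(df["x"].max())),
                        length=float(np.ceil(df["y"].max())),
                        border=0.0, census_dates=(0.0, 1.0))
    valid, rejected = _validate(df, plot, gbh_floor)
    return Census(trees=valid, plot=plot, rejected=rejected)


def read_census_long(path, plot: PlotSpec | None = None, sep: str = ",",
                     gbh_floor: float = 10.0) -> Census:
    """Read a long-format census (one row per tree x census).

    Expects columns ``tree_id, species, x, y, census, gbh, status[, oui]``.
    """
    df = pd.read_csv(path, sep=sep, dtype={"tree_id": str, "species": str})
    needed = {"tree_id", "species", "x", "y", "census", "gbh", "status"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"long census file missing columns: {sorted(missing)}")
    keys = ["tree_id", "species", "x", "y"] + (["oui"] if "oui" in df else [])
    wide = df.pivot_table(index=keys, columns="census",
                          values=["gbh", "status"], aggfunc="first")
    wide.columns = [f"{v}_{int(c)}" for v, c in wide.columns]
    wide = wide.reset_index()
    for c in wide.columns:
        if c.startswith("status_"):
            wide[c] = wide[c].fillna("absent")
    census = Census(trees=wide, plot=plot or PlotSpec(
        width=float(np.ceil(wide["x"].max())),
        length=float(np.ceil(wide["y"].max())), border=0.0,
        census_dates=(0.0, 1.0)))
    valid, rejected = _validate(census.trees, census.plot, gbh_floor)
    return Census(trees=valid, plot=census.plot, rejected=rejected)


def write_census(census: Census, path, sep: str = ",",
                 metadata: dict | None = None) -> None:
    """Write a census as delimited text plus a JSON sidecar with the plot spec."""
    census.trees.to_csv(path, sep=sep, index=False)
    side = {"plot": dataclasses.asdict(census.plot)}
    side["plot"]["census_dates"] = list(side["plot"]["census_dates"])
    if metadata:
        side.update(metadata)
    Path(str(path) + ".json").write_text(json.dumps(side, indent=1))


def select_focal_species(census: Census, period: PeriodSpec,
                         size_class: tuple = (10.0, 100.0),
                         min_n: int = 50, min_dead: int = 5) -> list[str]:
    """Species with enough focal-sized trees and enough deaths in a period.

    Counts use only trees inside the core (>= border from every edge) that are
    alive at period start with gbh in ``[size_class[0], size_class[1])``; the
    death count is the subset of those dead by period end.
    """
    t = census.trees
    if len(t) == 0:
        return []
    s0, s1 = f"status_{period.start_census}", f"status_{period.end_census}"
    g0 = f"gbh_{period.start_census}"
    core = census.plot.in_core(t["x"], t["y"])
    pool = (core & (t[s0] == "alive")
            & (t[g0] >= size_class[0]) & (t[g0] < size_class[1]))
    sub = t[pool]
    n = sub.groupby("species").size()
    dead = sub[sub[s1] == "dead"].groupby("species").size()
    out = [sp for sp in n.index
           if n[sp] >= min_n and dead.get(sp, 0) >= min_dead]
    return sorted(out)


def focal_subset(census: Census, species: str, period: PeriodSpec,
                 size_class: tuple = (10.0, 100.0)) -> pd.DataFrame:
    """Focal trees of one species for one period.

    Alive at period start, in the half-open size class, and >= border from
    every plot edge (closed boundary).  Neighbors are *not* restricted this
    way.  Idempotent and order-independent.
    """
    t = census.trees
    s0, g0 = f"status_{period.start_census}", f"gbh_{period.start_census}"
    mask = ((t["species"] == species) & (t[s0] == "alive")
            & (t[g0] >= size_class[0]) & (t[g0] < size_class[1])
            & census.plot.in_core(t["x"], t["y"]))
    return t[mask].reset_index(drop=True)
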