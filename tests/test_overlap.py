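import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.spatial.distance import cdist

from zoicomp import (Canopy, CrownPointCloud, OverlapConfig, adjust_plot,
                     adjust_relocation, adjust_removal, basal_area,
                     dd_combinations, fill_plot, flag_shaded)
from zoicomp.allometry import AllometryCoefficients
from zoicomp.overlap import lowest_density_contour
from tests.conftest import make_trees


def mini_canopy(seed=0, n=30, fill_mode="larsm"):
    """A small clustered canopy for oracle comparisons."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append((f"t{i:02d}", "spA" if i % 3 else "spB",
                     round(rng.uniform(5, 25), 1), round(rng.uniform(5, 25), 1),
                     round(rng.uniform(10, 45), 1), "alive",
                     25.0, "alive"))
    trees = make_trees(rows)
    return fill_plot(trees, 1, fill_mode=fill_mode, seed=seed)


def brute_force_flags(clouds, dd_con, dd_het):
    """O(n^2) all-pairs oracle for the shading rule."""
    flags = {tid: np.zeros(c.n_points, bool) for tid, c in clouds.items()}
    for c in clouds.values():
        if c.cr == 0:
            continue
        for other in clouds.values():
            if other.cr == 0 or other.gbh <= c.gbh:
                continue
            dd = dd_con if other.species == c.species else dd_het
            if dd <= 0 or other.n_points == 0:
                continue
            d = cdist(c.points, other.points)
            flags[c.tree_id] |= d.min(axis=1) <= dd
    return flags


def hand_cloud(tid, species, gbh, points, cr=1.0):
    points = np.asarray(points, float)
    center = tuple(points.mean(axis=0))
    return CrownPointCloud(tid, species, gbh, center, cr, points,
                           basal_area(gbh) / len(points), "larsm")


def test_dd_zero_flags_nothing():
    canopy = mini_canopy()
    flags = flag_shaded(canopy, OverlapConfig(0.0, 0.0))
    assert not any(f.any() for f in flags.values())


def test_disjoint_crowns_never_flagged():
    a = hand_cloud("a", "spA", 100.0, [[0, 0], [1, 0], [0, 1]])
    b = hand_cloud("b", "spA", 50.0, [[50, 50], [51, 50], [50, 51]])
    flags = flag_shaded({"a": a, "b": b}, OverlapConfig(1.2, 1.2))
    assert not flags["a"].any() and not flags["b"].any()


def test_hand_built_configuration_matches_rule():
    """Six points, two trees: only the small tree's near points are shaded."""
    big = hand_cloud("big", "spA", 100.0, [[0, 0], [1, 0], [2, 0]])
    small = hand_cloud("small", "spA", 50.0, [[0.1, 0], [2.0, 0.3], [5, 5]])
    flags = flag_shaded({"big": big, "small": small}, OverlapConfig(0.35, 0.0))
    assert not flags["big"].any()           # nothing is larger than "big"
    assert list(flags["small"]) == [True, True, False]
    # heterospecific tolerance applies between different species
    small_b = hand_cloud("small", "spB", 50.0, [[0.1, 0], [2.0, 0.3], [5, 5]])
    flags = flag_shaded({"big": big, "small": small_b}, OverlapConfig(0.35, 0.0))
    assert not flags["small"].any()


@pytest.mark.parametrize("dd_con, dd_het", [(0.2, 0.2), (0.4, 1.2), (1.2, 0.4)])
def test_flags_match_brute_force_oracle(dd_con, dd_het):
    canopy = mini_canopy(seed=3)
    got = flag_shaded(canopy, OverlapConfig(dd_con, dd_het))
    expected = brute_force_flags(canopy.clouds, dd_con, dd_het)
    for tid in canopy.clouds:
        np.testing.assert_array_equal(got[tid], expected[tid])


def test_equal_gbh_trees_do_not_shade_each_other():
    a = hand_cloud("a", "spA", 50.0, [[0, 0], [0.1, 0]])
    b = hand_cloud("b", "spA", 50.0, [[0.05, 0], [0.15, 0]])
    flags = flag_shaded({"a": a, "b": b}, OverlapConfig(1.2, 1.2))
    assert not flags["a"].any() and not flags["b"].any()


def test_removal_arithmetic():
    cloud = hand_cloud("t", "spA", 60.0, np.random.default_rng(0).normal(size=(40, 2)))
    no_flags = np.zeros(40, bool)
    same = adjust_removal(cloud, no_flags)
    np.testing.assert_array_equal(same.points, cloud.points)
    k = 15
    flags = np.zeros(40, bool)
    flags[:k] = True
    pruned = adjust_removal(cloud, flags)
    assert pruned.n_points == 25
    assert pruned.total_weight == pytest.approx(
        cloud.ba * (40 - k) / 40, rel=1e-12)


def test_fully_shaded_tree_vanishes():
    big = hand_cloud("big", "spA", 100.0,
                     np.random.default_rng(1).uniform(-1, 1, (200, 2)))
    small = hand_cloud("small", "spA", 20.0, [[0.0, 0.0], [0.2, 0.1]], cr=0.3)
    canopy = Canopy({"big": big, "small": small}, "larsm", 0)
    for mode in ("removal", "relocation"):
        adj = adjust_plot(canopy, OverlapConfig(1.2, 1.2, mode), seed=0)
        assert adj.vanished == {"small"}
        assert "small" not in adj.clouds


def test_relocation_conserves_and_respects_contour():
    rng = np.random.default_rng(2)
    r = np.sqrt(rng.random(400)) * 3.0
    th = 2 * np.pi * rng.random(400)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    cloud = hand_cloud("t", "spA", 80.0, pts, cr=3.0)
    flags = pts[:, 0] > 0  # the right half-disc is shaded
    adj = adjust_relocation(cloud, flags, np.random.default_rng(3))
    assert adj.n_points == cloud.n_points
    assert adj.total_weight == pytest.approx(cloud.total_weight, rel=1e-12)
    region = lowest_density_contour(pts[~flags])
    moved = adj.points[flags]
    assert shapely.contains_xy(region, moved[:, 0], moved[:, 1]).all()
    # untouched points stay put
    np.testing.assert_array_equal(adj.points[~flags], pts[~flags])


def test_relocation_degenerate_unshaded_set_falls_back():
    pts = np.array([[0, 0], [0.2, 0], [1, 0], [1.2, 0], [2, 0]], float)
    cloud = hand_cloud("t", "spA", 40.0, pts, cr=1.0)
    flags = np.array([False, False, True, True, True])
    adj = adjust_relocation(cloud, flags, np.random.default_rng(0))
    assert adj is not None and adj.n_points == 5
    assert adj.total_weight == pytest.approx(cloud.total_weight, rel=1e-12)


def test_hierarchical_flags_use_adjusted_larger_clouds():
    """After a mid-sized tree's shaded points vanish, they no longer shade."""
    a = hand_cloud("a", "spA", 100.0, [[0.0, 0.0]])
    b = hand_cloud("b", "spA", 60.0, [[0.1, 0.0]])      # removed under a
    c = hand_cloud("c", "spA", 30.0, [[0.25, 0.0]])     # near b's old point
    canopy = Canopy({"a": a, "b": b, "c": c}, "larsm", 0)
    adj = adjust_plot(canopy, OverlapConfig(0.2, 0.2, "removal"), seed=0)
    assert adj.vanished == {"b"}
    # c is 0.25 m from a's point (> dd) and b is gone: c keeps its point
    assert adj.clouds["c"].n_points == 1
    # sanity: against the *original* clouds, c would have been flagged by b
    orig_flags = brute_force_flags(canopy.clouds, 0.2, 0.2)
    assert orig_flags["c"].any()


@pytest.mark.parametrize("mode", ["removal", "relocation"])
def test_reflag_after_adjustment_finds_no_shaded_points(mode):
    canopy = mini_canopy(seed=5, n=25)
    config = OverlapConfig(0.4, 0.4, mode)
    adj = adjust_plot(canopy, config, seed=1)
    reflag = flag_shaded(adj.clouds, config)
    assert not any(f.any() for f in reflag.values())
    if mode == "relocation":
        for tid, cloud in adj.clouds.items():
            orig = canopy.clouds[tid]
            assert cloud.n_points == orig.n_points
            assert cloud.total_weight == pytest.approx(orig.total_weight,
                                                       rel=1e-12)
    else:
        for tid, cloud in adj.clouds.items():
            assert cloud.total_weight <= canopy.clouds[tid].total_weight + 1e-9


def test_flag_count_monotone_in_dd():
    canopy = mini_canopy(seed=7, n=25)
    counts = []
    for dd in (0.0, 0.2, 0.4, 0.8, 1.2):
        flags = flag_shaded(canopy, OverlapConfig(dd, dd))
        counts.append(sum(int(f.sum()) for f in flags.values()))
    assert counts == sorted(counts)
    assert counts[0] == 0


def test_zero_cr_canopy_is_inert_for_any_dd():
    tiny = AllometryCoefficients(-100.0, 1e-6, "zero-cr")
    rows = [(f"t{i}", "spA", 1.0 + 0.05 * i, 1.0, 20.0 + i, "alive",
             22.0, "alive") for i in range(8)]
    trees = make_trees(rows)
    canopy = fill_plot(trees, 1, coeffs=tiny, seed=0)
    for dd in (0.0, 0.6, 1.2):
        adj = adjust_plot(canopy, OverlapConfig(dd, dd, "removal"), seed=0)
        assert adj.vanished == set()
        for tid, cloud in adj.clouds.items():
            np.testing.assert_array_equal(cloud.points,
                                          canopy.clouds[tid].points)


def test_dd_grid_and_config_validation():
    assert len(dd_combinations()) == 49
    with pytest.raises(ValueError):
        OverlapConfig(-0.1, 0.0)
    with pytest.raises(ValueError):
        OverlapConfig(0.0, 0.0, adjust_mode="prune")
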