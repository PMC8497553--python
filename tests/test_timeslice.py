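"""Interpolation tables, disparity metrics, centroid paths, summed series."""

import numpy as np
import pandas as pd
import pytest

from paleodiv import (
    RegimePainting,
    SimulationConfig,
    apply_trait_selective_pulse,
    centroid_path,
    clade_summed_series,
    disparity_at_slice,
    disparity_series,
    exclude_edges,
    interpolate,
    largest_drop,
    parse_tree,
    simulate_bm_traits,
    simulate_fbd_tree,
    slice_distribution_summary,
    tag_clades,
    ltt_at_slices,
)
from paleodiv.timeslice import _hull_area, _mst_length


def _cross2(u, v):
    return u[0] * v[1] - u[1] * v[0]


# ---------------------------------------------------------------------------
# interpolation


def test_midpoint_and_endpoint_identities():
    tree = parse_tree("(A:10,B:10);", root_age=40)
    # edge from root (40 Ma) to tip A (30 Ma) with values 1.0 -> 2.0
    # (tips at depth 10 from a 40 Ma root sit at age 30)
    vals = {tree.root: 1.0}
    for nd in tree.tips():
        vals[nd.id] = 2.0 if nd.label == "A" else 5.0
    tab = interpolate(tree, vals, [35.0, 30.0])
    a_row = [i for i, (_, c) in enumerate(tree.edges()) if tree.nodes[c].label == "A"][0]
    assert tab.iloc[a_row][35.0] == pytest.approx(1.5)  # midpoint linearity
    assert tab.iloc[a_row][30.0] == pytest.approx(2.0)  # child value at child age


def test_cells_match_crossing_convention_and_bruteforce(fossil_trees):
    tree = fossil_trees[1]
    painting = RegimePainting(groups=(frozenset(["x"]),))
    vals = simulate_bm_traits(tree, painting, [np.array([[0.1]])], [0.0], seed=0)
    ages = np.arange(0, tree.root_age + 0.5, 2.0)[::-1]
    tab = interpolate(tree, vals["trait1"].to_dict(), ages)
    # brute-force nested-loop oracle
    for row, (pid, cid) in enumerate(tree.edges()):
        a_p, a_c = tree.nodes[pid].age, tree.nodes[cid].age
        v_p, v_c = vals.loc[pid, "trait1"], vals.loc[cid, "trait1"]
        for t in ages:
            cell = tab.iloc[row][t]
            if a_p > t >= a_c:
                expected = v_p + (v_c - v_p) * (a_p - t) / (a_p - a_c)
                assert cell == pytest.approx(expected)
            else:
                assert np.isnan(cell)


def test_lineage_counts_from_table_match_ltt(fossil_trees):
    for tree in fossil_trees[:4]:
        painting = RegimePainting(groups=(frozenset(["x"]),))
        vals = simulate_bm_traits(tree, painting, [np.array([[0.1]])], [0.0], seed=0)
        ages = np.arange(0, tree.root_age - 1e-9, 1.0)[::-1]
        tab = interpolate(tree, vals["trait1"].to_dict(), ages)
        series = ltt_at_slices(tree, ages[0], 0.0, 1.0)
        for age, count in zip(series.ages, series.counts):
            assert tab[age].notna().sum() == count


def test_missing_node_value_names_the_node(three_tip_tree):
    vals = {nd.id: 0.0 for nd in three_tip_tree.nodes}
    missing = three_tip_tree.tips()[0].id
    del vals[missing]
    with pytest.raises(KeyError, match=str(missing)):
        interpolate(three_tip_tree, vals, [1.0])


def test_exclude_edges():
    tab = pd.DataFrame(np.ones((6, 3)), index=pd.RangeIndex(6, name="edge"))
    out = exclude_edges(tab, [1, 4])
    assert len(out) == 4 and 1 not in out.index
    assert exclude_edges(tab, []).equals(tab)
    with pytest.raises(KeyError, match="99"):
        exclude_edges(tab, [99])


# ---------------------------------------------------------------------------
# disparity metrics


def test_single_point_disparity():
    d = disparity_at_slice(np.array([[0.3, -0.2]]))
    assert d["MST"] == 0.0 and d["SoR"] == 0.0
    assert np.isnan(d["SR2DHA"]) and np.isnan(d["SoV"])


def test_unit_square_hand_enumeration():
    d = disparity_at_slice(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
    assert d["SoR"] == pytest.approx(2.0)
    assert d["SR2DHA"] == pytest.approx(1.0)
    assert d["MST"] == pytest.approx(3.0)
    assert d["SoV"] == pytest.approx(2 * (1 / 3))


def test_collinear_points_have_no_hull_but_other_metrics():
    pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
    d = disparity_at_slice(pts)
    assert np.isnan(d["SR2DHA"])
    assert d["MST"] == pytest.approx(3 * np.sqrt(2))
    assert d["SoR"] == pytest.approx(6.0)


def test_concavity_argument_convex_warns_small_raises():
    pts = np.array([[0, 0], [1, 0], [0, 1]], float)
    with pytest.warns(UserWarning, match="convex"):
        disparity_at_slice(pts, concavity=10_000)
    with pytest.raises(ValueError):
        disparity_at_slice(pts, concavity=1.0)


def exhaustive_prim(points):
    """Independent Prim's-algorithm oracle for MST length."""
    n = len(points)
    in_tree = [0]
    total = 0.0
    dist = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    while len(in_tree) < n:
        best = np.inf
        best_j = None
        for i in in_tree:
            for j in range(n):
                if j not in in_tree and dist[i, j] < best:
                    best, best_j = dist[i, j], j
        total += best
        in_tree.append(best_j)
    return total


def shoelace_on_hull(points):
    """Hull-area oracle: gift-wrap the hull, then the shoelace formula."""
    pts = points[np.lexsort((points[:, 1], points[:, 0]))]

    def half(iterable):
        out = []
        for p in iterable:
            while len(out) >= 2 and _cross2(out[-1] - out[-2], p - out[-2]) <= 0:
                out.pop()
            out.append(p)
        return out

    lower, upper = half(pts), half(pts[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    x, y = hull[:, 0], hull[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def test_mst_and_hull_match_bruteforce_oracles():
    rng = np.random.default_rng(5)
    for _ in range(25):
        pts = rng.normal(size=(50, 2))
        d = disparity_at_slice(pts)
        assert d["MST"] == pytest.approx(exhaustive_prim(pts), abs=1e-9)
        assert d["SR2DHA"] ** 2 == pytest.approx(shoelace_on_hull(pts), abs=1e-9)


def test_sov_bounded_by_squared_range():
    rng = np.random.default_rng(8)
    for _ in range(20):
        pts = rng.normal(size=(rng.integers(2, 40), 2)) * rng.uniform(0.1, 5)
        d = disparity_at_slice(pts)
        assert d["SoV"] <= d["SoR"] ** 2 / 2 + 1e-12


# ---------------------------------------------------------------------------
# series, centroids, sums


def _toy_series():
    idx = pd.Index([3.0, 2.0, 1.0, 0.0], name="age_ma")
    return pd.DataFrame(
        {
            "n_lineages": [2, 3, 3, 3],
            "SR2DHA": [np.nan, 0.5, 0.7, 0.6],
            "MST": [1.0, 1.5, 1.2, 1.1],
            "SoV": [0.1, 0.2, 0.2, 0.2],
            "SoR": [0.5, 0.8, 0.7, 0.7],
            "centroid_pc1": [0.0, 3.0, 3.0, 4.0],
            "centroid_pc2": [0.0, 4.0, 4.0, 4.0],
        },
        index=idx,
    )


def test_centroid_path_345():
    out = centroid_path(_toy_series(), 3.0, 2.0)
    assert out["path_length"] == pytest.approx(5.0)
    assert out["rate_per_myr"] == pytest.approx(5.0)


def test_centroid_path_stationary_is_zero():
    s = _toy_series()
    s[["centroid_pc1", "centroid_pc2"]] = 1.0
    out = centroid_path(s, 3.0, 0.0)
    assert out["path_length"] == 0.0 and out["rate_per_myr"] == 0.0


def test_centroid_path_needs_two_slices():
    with pytest.raises(ValueError, match="2 populated"):
        centroid_path(_toy_series().iloc[:1], 3.0, 2.9)


def test_clade_summed_series_rules():
    a = _toy_series()
    b = _toy_series()
    b["SR2DHA"] = [0.7, 0.7, 0.7, 0.7]
    total = clade_summed_series({"a": a, "b": b}, "SR2DHA")
    # slice 2.0: 0.5 + 0.7
    assert total.loc[2.0] == pytest.approx(1.2)
    # slice 3.0: clade a has lineages but undefined hull -> NaN propagates
    assert np.isnan(total.loc[3.0])
    # a clade with zero lineages contributes 0
    c = _toy_series()
    c["n_lineages"] = 0
    tot2 = clade_summed_series({"a": b, "c": c}, "SR2DHA")
    assert tot2.loc[2.0] == pytest.approx(0.7)
    # identity for a single clade
    solo = clade_summed_series({"a": b}, "SR2DHA")
    assert solo.loc[0.0] == pytest.approx(0.7)
    with pytest.raises(ValueError, match="grid"):
        clade_summed_series({"a": a, "b": b.iloc[:2]}, "SR2DHA")


def test_slice_distribution_summary_kde_normalizes():
    rng = np.random.default_rng(0)
    tab = pd.DataFrame(rng.normal(size=(30, 3)), columns=[2.0, 1.0, 0.0])
    out = slice_distribution_summary(tab)
    for d in out:
        assert not d.degenerate
        assert len(d.values) == 30
        integral = np.trapezoid(d.density, d.grid)
        assert abs(integral - 1.0) < 1e-3


def test_slice_distribution_degenerate_flagged():
    tab = pd.DataFrame({5.0: [1.0, 1.0, 1.0], 4.0: [np.nan, 2.0, np.nan]})
    out = slice_distribution_summary(tab)
    assert out[0].degenerate and out[1].degenerate


def test_pooled_count_equals_lineage_count(fossil_trees):
    tree = fossil_trees[2]
    painting = RegimePainting(groups=(frozenset(["x"]),))
    vals = simulate_bm_traits(tree, painting, [np.array([[0.1]])], [0.0], seed=0)
    ages = np.arange(0, tree.root_age - 1e-9, 2.5)[::-1]
    tab = interpolate(tree, vals["trait1"].to_dict(), ages)
    for d in slice_distribution_summary(tab):
        assert len(d.values) == tab[d.age].notna().sum()


# ---------------------------------------------------------------------------
# end-to-end pulse recovery


def test_extinction_pulse_age_recovered_in_disparity_drop():
    """A programmed trait-selective pulse must register as the largest
    single-slice drop in hull disparity exactly at the pulse slice."""
    from paleodiv import pulse_disparity_experiment

    out = pulse_disparity_experiment(seed=0)
    assert out["detected_age"] == pytest.approx(out["pulse_age"])
    assert out["drop"] > 0
    # the victims are still counted (and valued) at exactly the pulse slice
    assert out["series"].loc[out["pulse_age"], "n_lineages"] > out["series"].loc[
        out["pulse_age"] - 0.5, "n_lineages"
    ]
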