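"""Time-slice trait interpolation and disparity-through-time summaries.

Once every node of a time-scaled tree carries a trait value (tips observed,
internal nodes from ancestral-state reconstruction), every edge defines a
linear trajectory in time, and any age grid can sample the trait values of
all lineages crossing each slice.  The resulting edge x slice table (NA where
an edge does not cross a slice) feeds four per-slice disparity measures on
the PC1-PC2 morphospace:

* ``SoV``    — variance of PC1 + variance of PC2 (sample variance);
* ``SoR``    — range of PC1 + range of PC2;
* ``SR2DHA`` — square root of the 2-D hull area of the point cloud;
* ``MST``    — total Euclidean length of the minimum spanning tree;

plus point-cloud centroids, centroid paths/rates, and clade-summed series
(sumSR2DHA, sumMST).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import gaussian_kde

from .tree import TimeScaledTree

__all__ = [
    "interpolate",
    "exclude_edges",
    "disparity_at_slice",
    "disparity_series",
    "centroid_path",
    "clade_summed_series",
    "largest_drop",
    "slice_distribution_summary",
]

#: concavity values at or above this are treated as "effectively convex"
CONVEX_CONCAVITY_THRESHOLD = 100.0


def interpolate(
    tree: TimeScaledTree,
    node_values: pd.Series | dict,
    slice_ages: Sequence[float],
) -> pd.DataFrame:
    """Edge x slice table of linearly interpolated trait values.

    ``node_values`` maps node id -> trait value and must cover every node.
    An edge (parent age ``a_p``, value ``v_p``; child age ``a_c``, value
    ``v_c``) contributes to slice ``t`` iff ``a_p > t >= a_c`` (the package
    edge-crossing convention), with value ``v_p + (v_c - v_p) * (a_p - t) /
    (a_p - a_c)``.  Cells for non-crossing edges are NaN.
    """
    vals = dict(node_values)
    ages = np.asarray(list(slice_ages), dtype=float)
    edges = tree.edges()
    out = np.full((len(edges), ages.size), np.nan)
    for row, (pid, cid) in enumerate(edges):
        if pid not in vals:
            raise KeyError(f"no trait value for node {pid}")
        if cid not in vals:
            raise KeyError(f"no trait value for node {cid}")
        a_p, a_c = tree.nodes[pid].age, tree.nodes[cid].age
        v_p, v_c = float(vals[pid]), float(vals[cid])
        crossing = (a_p > ages) & (ages >= a_c)
        if a_p == a_c:  # zero-length terminal branch: child value at its age
            crossing = ages == a_c
            out[row, crossing] = v_c
            continue
        frac = (a_p - ages[crossing]) / (a_p - a_c)
        out[row, crossing] = v_p + (v_c - v_p) * frac
    return pd.DataFrame(out, index=pd.RangeIndex(len(edges), name="edge"), columns=ages)


def exclude_edges(table: pd.DataFrame, exclusion_list: Sequence[int]) -> pd.DataFrame:
    """Drop edge rows (e.g. stems not attributable to the study landmass).

    Rows are removed before any summarization; unknown edge identifiers are
    an error rather than a silent no-op.
    """
    unknown = [e for e in exclusion_list if e not in table.index]
    if unknown:
        raise KeyError(f"unknown edge identifiers: {unknown}")
    return table.drop(index=list(exclusion_list))


def _mst_length(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    return float(minimum_spanning_tree(d).sum())


def _hull_area(points: np.ndarray) -> float:
    """2-D convex hull area; NaN when the hull is degenerate."""
    if len(points) < 3:
        return np.nan
    try:
        hull = ConvexHull(points)
    except QhullError:
        return np.nan  # collinear or otherwise degenerate
    return float(hull.volume)  # in 2-D, .volume is the area


def disparity_at_slice(points: np.ndarray, concavity: Optional[float] = None) -> dict:
    """Four disparity measures of one slice's (PC1, PC2) point cloud.

    A ``concavity`` argument is accepted for interface compatibility with
    concave-hull workflows but ignored (with a warning) at or above
    ``CONVEX_CONCAVITY_THRESHOLD``, where a concave hull degenerates to the
    convex hull computed here; smaller values are unsupported.
    """
    if concavity is not None:
        if concavity >= CONVEX_CONCAVITY_THRESHOLD:
            warnings.warn(
                "concavity >= %g is effectively convex; computing the convex hull"
                % CONVEX_CONCAVITY_THRESHOLD,
                stacklevel=2,
            )
        else:
            raise ValueError("concave hulls are not supported; pass a convex-range concavity")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("need at least one point")
    if points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(points)
    sov = float(points[:, 0].var(ddof=1) + points[:, 1].var(ddof=1)) if n > 1 else np.nan
    sor = float(np.ptp(points[:, 0]) + np.ptp(points[:, 1]))
    area = _hull_area(points)
    return {
        "n": n,
        "SoV": sov,
        "SoR": sor,
        "SR2DHA": float(np.sqrt(area)) if np.isfinite(area) else np.nan,
        "MST": _mst_length(points),
    }


def disparity_series(pc1_table: pd.DataFrame, pc2_table: pd.DataFrame) -> pd.DataFrame:
    """Per-slice disparity and centroid series from two interpolation tables.

    Tables must share edge rows and slice columns (one per PC).  Slices with
    no crossing lineage get a zero lineage count and NaN metrics; the series
    conventionally starts at each clade's oldest data-affirmative slice, which
    is simply the oldest column with a nonzero count.
    """
    if not pc1_table.index.equals(pc2_table.index) or not pc1_table.columns.equals(
        pc2_table.columns
    ):
        raise ValueError("PC1 and PC2 tables must share rows and columns")
    rows = []
    for age in pc1_table.columns:
        x = pc1_table[age].to_numpy()
        y = pc2_table[age].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if not ok.any():
            rows.append(
                {"age_ma": age, "n_lineages": 0, "SoV": np.nan, "SoR": np.nan,
                 "SR2DHA": np.nan, "MST": np.nan, "centroid_pc1": np.nan,
                 "centroid_pc2": np.nan}
            )
            continue
        pts = np.column_stack([x[ok], y[ok]])
        d = disparity_at_slice(pts)
        rows.append(
            {
                "age_ma": age,
                "n_lineages": d["n"],
                "SoV": d["SoV"],
                "SoR": d["SoR"],
                "SR2DHA": d["SR2DHA"],
                "MST": d["MST"],
                "centroid_pc1": float(pts[:, 0].mean()),
                "centroid_pc2": float(pts[:, 1].mean()),
            }
        )
    return pd.DataFrame(rows).set_index("age_ma")


def centroid_path(series: pd.DataFrame, start: float, stop: float) -> dict:
    """Centroid movement between ``start`` (older) and ``stop`` (younger) Ma.

    Sums Euclidean distances between centroids of adjacent populated slices;
    the rate divides the path length by the elapsed time between the first
    and last populated slice in the window.
    """
    if start < stop:
        raise ValueError("start must be older (larger) than stop")
    window = series[(series.index <= start) & (series.index >= stop)]
    window = window.dropna(subset=["centroid_pc1", "centroid_pc2"])
    if len(window) < 2:
        raise ValueError("fewer than 2 populated slices in the window")
    window = window.sort_index(ascending=False)  # oldest first
    xy = window[["centroid_pc1", "centroid_pc2"]].to_numpy()
    steps = np.sqrt(((np.diff(xy, axis=0)) ** 2).sum(axis=1))
    elapsed = float(window.index[0] - window.index[-1])
    total = float(steps.sum())
    return {
        "step_distances": steps,
        "path_length": total,
        "elapsed_myr": elapsed,
        "rate_per_myr": total / elapsed if elapsed > 0 else np.nan,
        "ages": window.index.to_numpy(),
    }


def clade_summed_series(
    per_clade: dict[str, pd.DataFrame], metric: str = "SR2DHA"
) -> pd.Series:
    """Sum a disparity metric over clades at each slice (sumSR2DHA / sumMST).

    A clade with *no crossing lineages* at a slice contributes 0; a clade
    that has lineages but an undefined metric (e.g. a hull needs 3
    non-collinear points) propagates NaN, so undefined is never silently
    treated as zero disparity.
    """
    if metric not in ("SR2DHA", "MST", "SoV", "SoR"):
        raise ValueError(f"unknown metric {metric!r}")
    frames = list(per_clade.values())
    for f in frames[1:]:
        if not f.index.equals(frames[0].index):
            raise ValueError("clade series must share the slice grid")
    total = pd.Series(0.0, index=frames[0].index, name=f"sum{metric}")
    for f in frames:
        contrib = f[metric].where(f["n_lineages"] > 0, 0.0)
        total = total + contrib
    return total


def largest_drop(
    series: pd.Series,
    counts: Optional[pd.Series] = None,
    min_n_before: int = 1,
    step: Optional[float] = None,
) -> tuple[float, float, float]:
    """Locate the biggest single-step decrease in a per-slice series.

    Returns ``(age_before, age_after, drop)`` where ``age_before`` is the
    older slice of the pair with the largest decrease — for an extinction
    pulse at a grid age, the pulse age itself (victims still cross the slice
    at exactly their terminal age, then vanish at the next one).

    ``step`` restricts candidate pairs to consecutive grid slices (a decline
    accumulated across a gap of undefined slices is not a single-step drop);
    ``counts``/``min_n_before`` restrict to pairs whose older slice has at
    least that many lineages, since metrics on very small point clouds
    fluctuate too much to localize anything.
    """
    s = series.sort_index(ascending=False)
    ages = s.index.to_numpy(dtype=float)
    vals = s.to_numpy(dtype=float)
    n = counts.reindex(s.index).to_numpy() if counts is not None else None
    best = -np.inf
    pair = None
    for i in range(len(ages) - 1):
        if step is not None and abs((ages[i] - ages[i + 1]) - step) > 1e-9:
            continue
        if not (np.isfinite(vals[i]) and np.isfinite(vals[i + 1])):
            continue
        if n is not None and n[i] < min_n_before:
            continue
        d = vals[i] - vals[i + 1]
        if d > best:
            best, pair = d, (ages[i], ages[i + 1])
    if pair is None:
        raise ValueError("need at least 2 comparable populated slices")
    return float(pair[0]), float(pair[1]), float(best)


@dataclass
class SliceDistribution:
    age: float
    values: np.ndarray
    grid: Optional[np.ndarray]  # None for sparse/degenerate slices
    density: Optional[np.ndarray]
    degenerate: bool  # all values identical (or < 2 values)


def slice_distribution_summary(
    table: pd.DataFrame,
    slice_ages: Optional[Sequence[float]] = None,
    grid_size: int = 256,
) -> list[SliceDistribution]:
    """Pooled per-slice value distributions with violin-ready KDEs.

    For each requested slice, all non-missing interpolated values are pooled
    (one per crossing lineage) and a Gaussian KDE is evaluated on a regular
    grid spanning the data plus 3 bandwidths.  Slices with fewer than 2
    values, or with all values identical, are reported raw and flagged
    degenerate instead of being smoothed.
    """
    ages = list(table.columns) if slice_ages is None else list(slice_ages)
    out = []
    for age in ages:
        vals = table[age].dropna().to_numpy(dtype=float)
        degenerate = vals.size < 2 or np.allclose(vals, vals[0] if vals.size else 0.0)
        if degenerate:
            out.append(SliceDistribution(float(age), vals, None, None, True))
            continue
        kde = gaussian_kde(vals)
        bw = kde.factor * vals.std(ddof=1)
        grid = np.linspace(vals.min() - 3 * bw, vals.max() + 3 * bw, grid_size)
        out.append(SliceDistribution(float(age), vals, grid, kde(grid), False))
    return out
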