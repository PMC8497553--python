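"""Lineage-through-time summarization for trees with fossil tips.

On an extant-only tree the lineage count is non-decreasing toward the present;
fossil terminals make it drop, which is what exposes extinction pulses.  The
edge-crossing convention used throughout the package:

* an edge with parent age ``a_p`` and child age ``a_c`` crosses slice age
  ``t`` iff ``a_p > t >= a_c`` — a fossil tip is still counted in the slice at
  exactly its own age, and internal nodes are never double counted;
* the count at exactly the root age is 1 (the stem lineage), immediately
  younger it is 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tree import AGE_TOL, TimeScaledTree

__all__ = [
    "LTTSeries",
    "lineage_count_at",
    "ltt_continuous",
    "ltt_at_slices",
    "percent_lineage_loss",
]


@dataclass
class LTTSeries:
    """Piecewise-constant lineage counts against age (Ma, descending)."""

    ages: np.ndarray  # descending, Ma before present
    counts: np.ndarray  # lineage count at each age (crossing convention)
    mode: str  # "continuous-event" | "discrete-slice"

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.ages.size != self.counts.size:
            raise ValueError("ages and counts must have equal length")
        if self.ages.size and np.any(np.diff(self.ages) > 0):
            raise ValueError("ages must be descending (older to younger)")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"age_ma": self.ages, "n_lineages": self.counts})

    def count_in_window(self, older: float, younger: float) -> tuple[int, int]:
        """(max, min) lineage count over the closed age window [younger, older].

        The series is a step function changing only at its stored event ages,
        so evaluating at the window endpoints and every stored age inside the
        window covers all pieces.
        """
        if older < younger:
            raise ValueError("window must be given as (older, younger)")
        inside = self.ages[(self.ages <= older) & (self.ages >= younger)]
        probes = np.concatenate([[older, younger], inside])
        vals = np.array([self.evaluate(t) for t in probes])
        return int(vals.max()), int(vals.min())

    def evaluate(self, t: float) -> int:
        """Count at age ``t`` by step lookup (counts apply at and just below
        their event age, until the next younger event)."""
        if t > self.ages[0]:
            return 0
        # value on (age_{i+1}, age_i] is the count stored at the next
        # younger-or-equal event age
        idx = int(np.searchsorted(-self.ages, -t, side="left"))
        idx = min(idx, self.ages.size - 1)
        return int(self.counts[idx])


def lineage_count_at(tree: TimeScaledTree, t: float) -> int:
    """Number of lineages crossing age ``t`` under the package convention."""
    if t > tree.root_age:
        return 0
    if abs(t - tree.root_age) <= AGE_TOL:
        return 1
    pa, ca = tree.edge_arrays()
    return int(np.sum((pa > t) & (ca <= t)))


def _counts_at(tree: TimeScaledTree, ages: np.ndarray) -> np.ndarray:
    pa, ca = tree.edge_arrays()
    ages = np.asarray(ages, dtype=float)
    counts = np.sum((pa[None, :] > ages[:, None]) & (ca[None, :] <= ages[:, None]), axis=1)
    counts[np.abs(ages - tree.root_age) <= AGE_TOL] = 1
    counts[ages > tree.root_age + AGE_TOL] = 0
    return counts.astype(int)


def ltt_continuous(tree: TimeScaledTree) -> LTTSeries:
    """Exact LTT step series: one entry per distinct node age.

    Counts increase by one at each internal-node age (a divergence) and drop
    by one at each fossil-tip age; the count at age 0 equals the number of
    extant tips.
    """
    if tree.n_tips == 0:
        raise ValueError("empty tree")
    ages = np.unique([nd.age for nd in tree.nodes])[::-1]
    if ages[-1] > 0:  # extend the series to the present even if no node is extant
        ages = np.append(ages, 0.0)
    counts = _counts_at(tree, ages)
    return LTTSeries(ages=ages, counts=counts, mode="continuous-event")


def ltt_at_slices(tree: TimeScaledTree, start: float, stop: float, step: float) -> LTTSeries:
    """Lineage counts on an inclusive age grid from ``start`` down to ``stop``.

    The grid has ``floor((start - stop)/step) + 1`` slices (start 76, stop 0,
    step 0.5 -> 153 slices).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start < stop:
        raise ValueError("start must be older (larger) than stop")
    n = int(np.floor((start - stop) / step + 1e-9)) + 1
    ages = start - step * np.arange(n)
    counts = _counts_at(tree, ages)
    return LTTSeries(ages=ages, counts=counts, mode="discrete-slice")


#: default windows bracketing the late-Eocene diversity peak and the
#: early-Oligocene trough (Ma before present)
DEFAULT_PEAK_WINDOW = (38.0, 33.9)
DEFAULT_TROUGH_WINDOW = (33.9, 27.0)


def percent_lineage_loss(
    series: LTTSeries,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    trough_window: tuple[float, float] = DEFAULT_TROUGH_WINDOW,
) -> float:
    """Fractional lineage loss from a diversity peak into a younger trough.

    Returns ``(max count in peak_window - min count in trough_window) / max
    count in peak_window``.  Windows are (older, younger) age pairs in Ma and
    the peak window must be older than the trough window.
    """
    if peak_window[0] < trough_window[0]:
        warnings.warn("peak window is younger than trough window", stacklevel=2)
    peak, _ = series.count_in_window(*peak_window)
    _, trough = series.count_in_window(*trough_window)
    if peak == 0:
        raise ValueError("no lineages in the peak window; loss undefined")
    return (peak - trough) / peak
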