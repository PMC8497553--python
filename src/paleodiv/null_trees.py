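"""Random time-scaled trees that preserve observed tip ages and root age.

The null model asks: how much apparent lineage loss does a tree *have* to show
merely because its tips are dated when they are, regardless of phylogenetic
structure?  Each null tree keeps the observed tip labels, tip ages and root
age, but draws a uniformly random rooted binary labeled topology and random
internal-node ages compatible with those constraints.

Sampling scheme
---------------
* Topology: sequential random addition — tip ``k+1`` is attached to one of
  the ``2k - 1`` edges (including the root stem) of the current ``k``-tip
  tree, chosen uniformly.  This yields the exact uniform distribution over
  rooted binary labeled topologies.
* Node ages: in preorder, each internal node's age is drawn uniformly between
  the maximum tip age in its subtree (exclusive lower bound) and its parent's
  age (the root is pinned at the fixed root age).  The interval is always
  nonempty, so every draw is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ltt import DEFAULT_PEAK_WINDOW, DEFAULT_TROUGH_WINDOW, LTTSeries, ltt_continuous, percent_lineage_loss
from .tree import Node, TimeScaledTree

__all__ = ["random_tree_fixed_tips", "NullEnsemble", "build_null_ensemble", "null_loss_distribution"]


def random_tree_fixed_tips(
    tip_ages: Sequence[tuple[str, float]],
    root_age: float,
    seed: int | np.random.Generator,
) -> TimeScaledTree:
    """One random time-scaled tree with the given tip labels/ages and root age.

    Deterministic for a fixed integer seed: repeated calls give an identical
    Newick string.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [str(lb) for lb, _ in tip_ages]
    ages = [float(a) for _, a in tip_ages]
    if len(labels) < 2:
        raise ValueError("need at least 2 tips")
    bad = [lb for lb, a in tip_ages if a >= root_age]
    if bad:
        raise ValueError(f"tip ages must be younger than the root age; offending tips: {bad}")
    # deep chains of ancestors above the oldest tip can shrink the valid age
    # interval below float resolution; such draws are rejected and redrawn
    from .tree import TreeError

    last_err = None
    for _ in range(100):
        try:
            return _draw_tree(labels, ages, root_age, rng)
        except TreeError as err:
            last_err = err
    raise RuntimeError(f"could not draw a valid tree in 100 attempts: {last_err}")


def _draw_tree(
    labels: list[str],
    ages: list[float],
    root_age: float,
    rng: np.random.Generator,
) -> TimeScaledTree:
    # --- topology by sequential random addition ---------------------------
    # nodes: 0..n-1 tips, then internals; root handled implicitly via parent
    n = len(labels)
    parent: dict[int, Optional[int]] = {0: None}
    children: dict[int, list[int]] = {0: []}
    edges: list[int] = [0]  # edge list identified by child node ("root stem" = root child of None)
    next_id = n
    for k in range(1, n):
        attach_child = edges[int(rng.integers(len(edges)))]
        new_internal = next_id
        next_id += 1
        gp = parent[attach_child]
        parent[new_internal] = gp
        children[new_internal] = [attach_child, k]
        if gp is not None:
            children[gp][children[gp].index(attach_child)] = new_internal
        parent[attach_child] = new_internal
        parent[k] = new_internal
        children.setdefault(k, [])
        edges.append(new_internal)
        edges.append(k)

    roots = [nid for nid, p in parent.items() if p is None]
    assert len(roots) == 1
    old_root = roots[0]

    # --- renumber and assign ages ------------------------------------------
    nodes: list[Node] = []
    old2new: dict[int, int] = {}
    order: list[int] = []
    stack = [old_root]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(reversed(children[nid]))
    for old in order:
        new_id = len(nodes)
        old2new[old] = new_id
        p = parent[old]
        nodes.append(
            Node(
                id=new_id,
                age=0.0,
                label=labels[old] if old < n else None,
                parent=old2new[p] if p is not None else None,
            )
        )
        if p is not None:
            nodes[old2new[p]].children.append(new_id)

    # subtree max tip age (postorder over new ids)
    max_tip_age = [0.0] * len(nodes)
    for old in reversed(order):
        nid = old2new[old]
        nd = nodes[nid]
        if not nd.children:
            max_tip_age[nid] = ages[old]
        else:
            max_tip_age[nid] = max(max_tip_age[c] for c in nd.children)

    for old in order:  # preorder: parents before children
        nid = old2new[old]
        nd = nodes[nid]
        if not nd.children:
            nd.age = ages[old]
        elif nd.parent is None:
            nd.age = float(root_age)
        else:
            hi = nodes[nd.parent].age
            lo = max_tip_age[nid]
            age = lo + (hi - lo) * rng.uniform(0.0, 1.0)
            # keep the draw strictly interior despite float rounding
            if not age < hi:
                age = np.nextafter(hi, lo)
            if not age > lo:
                age = lo + (hi - lo) * 0.5
            nd.age = age
    root_new = old2new[old_root]
    return TimeScaledTree(nodes, root_new)


@dataclass
class NullEnsemble:
    """A set of random trees sharing one tip-age spectrum and root age."""

    tip_age_spectrum: list[tuple[str, float]]
    root_age: float
    seed: int
    trees: list[TimeScaledTree] = field(default_factory=list)
    ltt: list[LTTSeries] = field(default_factory=list)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def build_null_ensemble(
    tip_ages: Sequence[tuple[str, float]],
    root_age: float,
    n_trees: int = 10_000,
    seed: int = 0,
    keep_trees: bool = True,
) -> NullEnsemble:
    """Generate ``n_trees`` random trees plus their continuous LTT series.

    One tree per child generator spawned from ``seed`` via SeedSequence, so
    individual trees are reproducible independently of ensemble size.
    """
    ens = NullEnsemble(tip_age_spectrum=list(tip_ages), root_age=float(root_age), seed=int(seed))
    children = np.random.SeedSequence(seed).spawn(n_trees)
    for ss in children:
        tr = random_tree_fixed_tips(tip_ages, root_age, np.random.default_rng(ss))
        ens.ltt.append(ltt_continuous(tr))
        if keep_trees:
            ens.trees.append(tr)
    return ens


def null_loss_distribution(
    ensemble: NullEnsemble,
    peak_window: tuple[float, float] = DEFAULT_PEAK_WINDOW,
    trough_window: tuple[float, float] = DEFAULT_TROUGH_WINDOW,
    quantiles: Sequence[float] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> dict:
    """Summary of percent lineage loss over the null ensemble."""
    if ensemble.n_trees == 0 and not ensemble.ltt:
        raise ValueError("empty ensemble")
    losses = np.array(
        [percent_lineage_loss(s, peak_window, trough_window) for s in ensemble.ltt]
    )
    return {
        "n_trees": losses.size,
        "mean": float(losses.mean()),
        "sd": float(losses.std(ddof=1)) if losses.size > 1 else 0.0,
        "quantiles": {q: float(np.quantile(losses, q)) for q in quantiles},
        "losses": losses,
    }
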