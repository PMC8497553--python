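"""Time-scaled phylogenetic trees with fossil and extant tips.

The central container is :class:`TimeScaledTree`: a rooted, binary tree whose
nodes carry ages in Ma before present (larger = older).  Tips at age 0 are
extant; tips at age > 0 are fossil (extinct) terminals.  Edges may carry a
clade tag (e.g. ``"anthropoid"``) used downstream for rate-regime painting and
per-clade disparity summaries.

Ages are the primary coordinate everywhere in this package; branch lengths in
Myr are derived quantities (``parent_age - child_age``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy
import numpy as np

__all__ = ["TreeError", "Node", "TimeScaledTree", "parse_tree"]

#: ages closer to zero than this are snapped to exactly 0 (extant)
AGE_TOL = 1e-9


class TreeError(ValueError):
    """Raised for malformed or unsupported tree input."""


@dataclass
class Node:
    id: int
    age: float
    label: Optional[str] = None
    parent: Optional[int] = None
    children: list[int] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class TimeScaledTree:
    """Rooted binary tree with node ages in Ma before present.

    Parameters
    ----------
    nodes:
        Sequence of :class:`Node`; ids must equal list positions.
    root:
        id of the root node.
    clade_tags:
        Optional mapping ``child node id -> clade tag`` identifying the clade
        membership of the edge ending at that node.  Untagged edges are
        allowed (stem/backbone branches).
    """

    def __init__(
        self,
        nodes: Sequence[Node],
        root: int,
        clade_tags: Optional[dict[int, str]] = None,
    ):
        self.nodes: list[Node] = list(nodes)
        self.root = root
        self.clade_tags: dict[int, str] = dict(clade_tags or {})
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        for i, nd in enumerate(self.nodes):
            if nd.id != i:
                raise TreeError(f"node id {nd.id} does not match position {i}")
        root = self.nodes[self.root]
        if root.parent is not None:
            raise TreeError("root must have no parent")
        for nd in self.nodes:
            if nd.id == self.root:
                continue
            if nd.parent is None:
                raise TreeError(f"non-root node {nd.id} has no parent; tree not singly rooted")
            parent = self.nodes[nd.parent]
            # zero-length terminal branches are tolerated (a fossil tip can sit
            # exactly at its parent's age); internal durations must be positive
            ok = parent.age >= nd.age if nd.is_tip else parent.age > nd.age
            if not ok:
                raise TreeError(
                    f"edge {parent.id}->{nd.id} has non-positive duration "
                    f"(parent age {parent.age}, child age {nd.age})"
                )
            if nd.age < 0:
                raise TreeError(f"node {nd.id} has negative age {nd.age}")
        for nd in self.nodes:
            if nd.children and len(nd.children) != 2:
                raise TreeError(
                    f"node {nd.id} has {len(nd.children)} children; tree must be binary"
                )
        if abs(root.age - max(nd.age for nd in self.nodes)) > AGE_TOL:
            raise TreeError("root age must equal the maximum node age")

    # -- basic accessors ----------------------------------------------------

    @property
    def root_age(self) -> float:
        return self.nodes[self.root].age

    @property
    def n_tips(self) -> int:
        return sum(1 for nd in self.nodes if nd.is_tip)

    def tips(self) -> list[Node]:
        return [nd for nd in self.nodes if nd.is_tip]

    def extant_tips(self) -> list[Node]:
        return [nd for nd in self.tips() if nd.age <= AGE_TOL]

    def fossil_tips(self) -> list[Node]:
        return [nd for nd in self.tips() if nd.age > AGE_TOL]

    def tip_ages(self) -> list[tuple[str, float]]:
        return [(nd.label or str(nd.id), nd.age) for nd in self.tips()]

    # -- edges --------------------------------------------------------------

    def edges(self) -> list[tuple[int, int]]:
        """``(parent_id, child_id)`` pairs in deterministic preorder.

        The position of an edge in this list is its *edge number*, the row key
        of interpolation tables.  The numbering is this package's own
        deterministic preorder scheme (documented, stable across runs); a
        label-based mapping is available via :meth:`edge_table`.
        """
        out: list[tuple[int, int]] = []
        for nd in self.preorder():
            for c in nd.children:
                out.append((nd.id, c))
        return out

    def edge_index(self) -> dict[int, int]:
        """Mapping ``child node id -> edge number``."""
        return {c: i for i, (_, c) in enumerate(self.edges())}

    def edge_table(self):
        """Edge metadata table: number, parent/child ids, ages, clade tag, tip label."""
        import pandas as pd

        rows = []
        for i, (p, c) in enumerate(self.edges()):
            child = self.nodes[c]
            rows.append(
                {
                    "edge": i,
                    "parent_id": p,
                    "child_id": c,
                    "parent_age": self.nodes[p].age,
                    "child_age": child.age,
                    "clade": self.clade_tags.get(c),
                    "tip_label": child.label if child.is_tip else None,
                }
            )
        return pd.DataFrame(rows).set_index("edge")

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Parent and child age arrays aligned with :meth:`edges`."""
        es = self.edges()
        pa = np.array([self.nodes[p].age for p, _ in es])
        ca = np.array([self.nodes[c].age for _, c in es])
        return pa, ca

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = self.nodes[stack.pop()]
            yield nd
            # reversed so first child is visited first
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        order = list(self.preorder())
        return iter(reversed(order))

    def subtree_tip_ids(self, node_id: int) -> list[int]:
        out = []
        stack = [node_id]
        while stack:
            nd = self.nodes[stack.pop()]
            if nd.is_tip:
                out.append(nd.id)
            stack.extend(nd.children)
        return out

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with branch lengths in Myr."""

        def rec(nid: int) -> str:
            nd = self.nodes[nid]
            if nd.is_tip:
                core = _quote(nd.label or f"t{nid}")
            else:
                core = "(" + ",".join(rec(c) for c in nd.children) + ")"
                if nd.label:
                    core += _quote(nd.label)
            if nd.parent is not None:
                bl = self.nodes[nd.parent].age - nd.age
                core += f":{bl!r}"  # repr: shortest exact float round-trip
            return core

        return rec(self.root) + ";"

    def prune_to(self, keep_labels: Iterable[str]) -> "TimeScaledTree":
        """Subtree induced by the given tip labels (unifurcations suppressed).

        Node ages are preserved; clade tags are carried over where the tagged
        child node survives.
        """
        keep = set(keep_labels)
        tip_ids = [nd.id for nd in self.tips() if (nd.label or str(nd.id)) in keep]
        missing = keep - {nd.label or str(nd.id) for nd in self.tips()}
        if missing:
            raise TreeError(f"unknown tip labels: {sorted(missing)}")
        if len(tip_ids) < 2:
            raise TreeError("pruned tree needs at least 2 tips")
        keep_nodes: set[int] = set()
        for t in tip_ids:
            nid: Optional[int] = t
            while nid is not None and nid not in keep_nodes:
                keep_nodes.add(nid)
                nid = self.nodes[nid].parent
        # rebuild, suppressing nodes with a single surviving child
        parent_of: dict[int, Optional[int]] = {}
        kept_children: dict[int, list[int]] = {nid: [] for nid in keep_nodes}
        for nid in keep_nodes:
            p = self.nodes[nid].parent
            if p is not None:
                kept_children[p].append(nid)

        def resolve(nid: int) -> int:
            # collapse chains of single-child nodes
            while len(kept_children[nid]) == 1:
                nid = kept_children[nid][0]
            return nid

        new_root_old = resolve(self.root)
        old2new: dict[int, int] = {}
        new_nodes: list[Node] = []
        new_tags: dict[int, str] = {}

        def build(old_id: int, new_parent: Optional[int]) -> int:
            nd = self.nodes[old_id]
            new_id = len(new_nodes)
            new_nodes.append(Node(id=new_id, age=nd.age, label=nd.label, parent=new_parent))
            old2new[old_id] = new_id
            if old_id in self.clade_tags:
                new_tags[new_id] = self.clade_tags[old_id]
            for c in kept_children[old_id]:
                c = resolve(c)
                cid = build(c, new_id)
                new_nodes[new_id].children.append(cid)
            return new_id

        root_new = build(new_root_old, None)
        return TimeScaledTree(new_nodes, root_new, new_tags)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def parse_tree(
    text: str,
    root_age: Optional[float] = None,
    schema: str = "newick",
) -> TimeScaledTree:
    """Parse a Newick or NEXUS tree into a :class:`TimeScaledTree`.

    Branch lengths are read as Myr.  Node ages are ``root_age - depth``; when
    ``root_age`` is not supplied it is taken as the maximum root-to-tip path
    length, which places the deepest tip at age 0 (assumed extant).

    Raises
    ------
    TreeError
        For non-binary nodes, negative branch lengths, or missing branch
        lengths.
    """
    dtree = dendropy.Tree.get(data=text, schema=schema)
    dtree.is_rooted = True
    seed = dtree.seed_node
    # depth per dendropy node
    depths: dict[int, float] = {id(seed): 0.0}
    order = []
    for nd in dtree.preorder_node_iter():
        order.append(nd)
        if nd is seed:
            continue
        el = nd.edge.length
        if el is None:
            raise TreeError(f"missing branch length on edge to {_dlabel(nd)}")
        if el < 0:
            raise TreeError(f"negative branch length {el} on edge to {_dlabel(nd)}")
        depths[id(nd)] = depths[id(nd.parent_node)] + float(el)
    max_depth = max(depths[id(nd)] for nd in dtree.leaf_node_iter())
    # tolerate float drift from serialized branch lengths
    depth_tol = 1e-6 * max(1.0, max_depth)
    if root_age is None:
        root_age = max_depth
    elif root_age + depth_tol < max_depth:
        raise TreeError(
            f"supplied root age {root_age} is younger than the deepest tip ({max_depth})"
        )

    nodes: list[Node] = []
    idmap: dict[int, int] = {}
    for nd in order:
        n_child = len(nd.child_nodes())
        if n_child not in (0, 2):
            raise TreeError(
                f"node {_dlabel(nd)} has {n_child} children; only binary trees are supported"
            )
        age = root_age - depths[id(nd)]
        if abs(age) <= depth_tol:
            age = 0.0
        new_id = len(nodes)
        idmap[id(nd)] = new_id
        parent = idmap[id(nd.parent_node)] if nd is not seed else None
        label = nd.taxon.label if nd.taxon is not None else nd.label
        nodes.append(Node(id=new_id, age=age, label=label, parent=parent))
        if parent is not None:
            nodes[parent].children.append(new_id)
    return TimeScaledTree(nodes, idmap[id(seed)])


def _dlabel(nd) -> str:
    if nd.taxon is not None:
        return str(nd.taxon.label)
    return nd.label or "<internal>"
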