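"""Rooted, timed gene genealogies.

A :class:`Genealogy` is a rooted binary tree over ``n`` tips with node times
measured backward from the present: tips sit at time 0 and each of the
``n - 1`` internal nodes records one coalescence.  The time unit is whatever
the producer used (generations for the coalescent simulator, p-distance for
UPGMA trees, years after clock calibration); the container is unit-agnostic.

Nodes are integers: ``0 .. n-1`` are tips, ``n .. 2n-2`` are internal nodes
ordered by increasing time, with ``2n-2`` the root.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["Genealogy", "CoalescentInterval"]


@dataclass(frozen=True)
class CoalescentInterval:
    """An inter-coalescent interval: ``k`` lineages for a span ``length``."""

    k: int
    length: float


class Genealogy:
    """Rooted binary timed tree with tips at time 0."""

    def __init__(self, parent: np.ndarray, time: np.ndarray, labels=None):
        parent = np.asarray(parent, dtype=np.int64)
        time = np.asarray(time, dtype=float)
        if parent.shape != time.shape or parent.ndim != 1:
            raise ValueError("parent and time must be equal-length 1-D arrays")
        n_nodes = parent.size
        if n_nodes < 3 or n_nodes % 2 == 0:
            raise ValueError("a binary genealogy has 2n-1 nodes for n >= 2 tips")
        n = (n_nodes + 1) // 2
        if labels is None:
            labels = tuple(f"s{i}" for i in range(n))
        labels = tuple(labels)
        if len(labels) != n:
            raise ValueError("need one label per tip")
        if (parent == -1).sum() != 1 or parent[-1] != -1:
            raise ValueError("exactly the last node must be the root")
        if np.any(time[:n] != 0):
            raise ValueError("tips must be at time 0")
        child_time = time[:-1]
        parent_time = time[parent[:-1]]
        if np.any(parent_time < child_time):
            raise ValueError("node times must not decrease toward the root")
        self.parent = parent
        self.time = time
        self.labels = labels
        self._children: list[list[int]] = [[] for _ in range(n_nodes)]
        for v in range(n_nodes - 1):
            self._children[parent[v]].append(v)
        for v in range(n, n_nodes):
            if len(self._children[v]) != 2:
                raise ValueError(f"internal node {v} is not binary")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return (self.parent.size + 1) // 2

    @property
    def root(self) -> int:
        return self.parent.size - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def children(self, v: int) -> tuple[int, ...]:
        return tuple(self._children[v])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above every non-root node."""
        return self.time[self.parent[:-1]] - self.time[:-1]

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def scale_times(self, factor: float) -> "Genealogy":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Genealogy(self.parent.copy(), self.time * factor, self.labels)

    # -- coalescent structure ---------------------------------------------

    def coalescent_intervals(self) -> list[CoalescentInterval]:
        """Intervals between successive coalescences, from ``n`` lineages
        down to 2.  Lengths are non-negative and sum to the TMRCA; tied
        coalescence times yield zero-length intervals."""
        n = self.n_tips
        times = np.sort(self.time[n:])
        widths = np.diff(np.concatenate([[0.0], times]))
        ks = np.arange(n, 1, -1)
        return [CoalescentInterval(int(k), float(w)) for k, w in zip(ks, widths)]

    def descendant_masks(self) -> np.ndarray:
        """Boolean array ``(n_nodes, n_tips)``: tips below each node."""
        n = self.n_tips
        masks = np.zeros((self.parent.size, n), dtype=bool)
        masks[np.arange(n), np.arange(n)] = True
        for v in np.argsort(self.time, kind="stable"):
            for c in self._children[v]:
                masks[v] |= masks[c]
        return masks

    def root_partition(self) -> tuple[frozenset, frozenset]:
        """The two tip-label sets separated by the root."""
        a, b = self._children[self.root]
        masks = self.descendant_masks()
        la = frozenset(self.labels[i] for i in np.flatnonzero(masks[a]))
        lb = frozenset(self.labels[i] for i in np.flatnonzero(masks[b]))
        return la, lb

    def clade_subtree(self, side: int) -> "Genealogy":
        """Subtree rooted at root child ``side`` (0 or 1), times unchanged.

        The clade must contain at least 2 tips.
        """
        top = self._children[self.root][side]
        keep: list[int] = []
        stack = [top]
        while stack:
            v = stack.pop()
            keep.append(v)
            stack.extend(self._children[v])
        tips = sorted(v for v in keep if v < self.n_tips)
        # root of the subtree must come last even when times are tied
        internal = sorted(
            (v for v in keep if v >= self.n_tips),
            key=lambda v: (self.time[v], v == top),
        )
        m = len(tips)
        if m < 2:
            raise ValueError("clade has fewer than 2 tips")
        remap = {v: i for i, v in enumerate(tips)}
        remap.update({v: m + i for i, v in enumerate(internal)})
        parent = np.full(2 * m - 1, -1, dtype=np.int64)
        time = np.zeros(2 * m - 1)
        for v in keep:
            time[remap[v]] = self.time[v]
            if v != top:
                parent[remap[v]] = remap[self.parent[v]]
        return Genealogy(parent, time, tuple(self.labels[v] for v in tips))

    # -- newick ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string with branch lengths in the genealogy's time unit."""

        def fmt(v: int) -> str:
            if v < self.n_tips:
                return self.labels[v]
            a, b = self._children[v]
            la = self.time[v] - self.time[a]
            lb = self.time[v] - self.time[b]
            return f"({fmt(a)}:{la:.17g},{fmt(b)}:{lb:.17g})"

        return fmt(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, source: str, tol: float = 1e-6) -> "Genealogy":
        """Parse a rooted, ultrametric, binary newick tree.

        ``source`` may be a newick string or a path.  Node times are
        reconstructed from root-to-node distances; all tips must sit at the
        same depth within ``tol`` (relative), since a timed genealogy has
        its tips at the present.
        """
        text = source
        if "(" not in str(source):
            with open(source) as fh:
                text = fh.read()
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises rich parse errors
            raise ValueError(f"malformed newick: {exc}") from exc
        # depth of every node from the root
        depth: dict = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                edge = node.edge.length if node.edge.length is not None else 0.0
                depth[node] = depth[node.parent_node] + edge
        leaves = tree.leaf_nodes()
        if len(leaves) < 2:
            raise ValueError("genealogy needs at least 2 tips")
        height = max(depth[lf] for lf in leaves)
        if height <= 0:
            raise ValueError("degenerate zero-height tree")
        for lf in leaves:
            if abs(depth[lf] - height) > tol * max(height, 1.0):
                raise ValueError("tree is not ultrametric: tips at unequal depths")
        internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
        for nd in internal:
            if len(nd.child_nodes()) != 2:
                raise ValueError("genealogy must be strictly binary")
        n = len(leaves)
        leaves_sorted = sorted(
            leaves, key=lambda lf: lf.taxon.label if lf.taxon else ""
        )
        internal_sorted = sorted(
            internal,
            key=lambda nd: (height - depth[nd], nd.parent_node is None),
        )
        index = {lf: i for i, lf in enumerate(leaves_sorted)}
        index.update({nd: n + i for i, nd in enumerate(internal_sorted)})
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        time = np.zeros(2 * n - 1)
        for node, idx in index.items():
            time[idx] = 0.0 if node.is_leaf() else height - depth[node]
            if node.parent_node is not None:
                parent[idx] = index[node.parent_node]
        labels = tuple(
            lf.taxon.label if lf.taxon else f"s{i}"
            for i, lf in enumerate(leaves_sorted)
        )
        time[:n] = 0.0
        return cls(parent, time, labels)
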