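"""Distance-based phylogenetics: p-distance, NJ, UPGMA, bootstrap, clades.

Neighbor joining (via scikit-bio's Saitou–Nei implementation) is used for
clade discovery on haploid SNP matrices; UPGMA (scipy average linkage)
provides the clock-like rooted trees that the skyline machinery calibrates.
Clade delineation cuts the longest internal edges of the NJ tree — the
operational rule validated on synthetic data where clade truth is known.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .genealogy import Genealogy
from .haplotypes import HaplotypeMatrix

__all__ = [
    "p_distance",
    "neighbor_joining",
    "upgma",
    "bootstrap_support",
    "cut_clades",
    "clade_frequencies",
]


def p_distance(matrix: HaplotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distances: fraction of SNP columns at which two samples
    differ.  Assumes complete (no-missing) haploid genotypes."""
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        raise ValueError("empty haplotype matrix")
    X = matrix.genotypes.astype(np.float64)
    ones = X.sum(axis=1)
    cross = X @ X.T
    diffs = ones[:, None] + ones[None, :] - 2.0 * cross
    D = diffs / matrix.n_sites
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(D, ids=matrix.samples)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ tree; negative branch lengths are clamped to zero.

    Deterministic for a fixed input order (ties resolved in scan order).
    """
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    return nj(d, neg_as_zero=True)


def upgma(d: DistanceMatrix) -> Genealogy:
    """Average-linkage (UPGMA) tree as a rooted ultrametric genealogy.

    Node height is half the average-linkage merge distance, so tip-to-node
    heights are in the same units as the input distances.
    """
    m = d.shape[0]
    if m < 2:
        raise ValueError("UPGMA needs at least 2 samples")
    Z = linkage(squareform(d.data, checks=False), method="average")
    parent = np.full(2 * m - 1, -1, dtype=np.int64)
    time = np.zeros(2 * m - 1)
    for step in range(m - 1):
        a, b, height, _ = Z[step]
        node = m + step
        parent[int(a)] = parent[int(b)] = node
        time[node] = height / 2.0
    # scipy guarantees monotone merge heights for average linkage
    return Genealogy(parent, time, tuple(d.ids))


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set[frozenset]:
    """Internal-edge bipartitions, each canonicalised to the side not
    containing the lexicographically smallest taxon."""
    anchor = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            parts.add(side if anchor not in side else taxa - side)
    return parts


def bootstrap_support(
    matrix: HaplotypeMatrix, n_reps: int, seed: int = 0
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree of ``matrix`` with bootstrap supports on internal edges.

    SNP columns are resampled with replacement ``n_reps`` times, the NJ
    tree rebuilt, and each full-data bipartition's recovery frequency
    recorded as percent support (stored as ``node.support`` and returned as
    a bipartition -> percent mapping).
    """
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    full = neighbor_joining(p_distance(matrix))
    taxa = frozenset(matrix.samples)
    target = _bipartitions(full, taxa)
    counts = {part: 0 for part in target}
    for _ in range(n_reps):
        cols = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        boot = HaplotypeMatrix(matrix.genotypes[:, cols], matrix.samples)
        parts = _bipartitions(neighbor_joining(p_distance(boot)), taxa)
        for part in target & parts:
            counts[part] += 1
    support = {part: 100.0 * c / n_reps for part, c in counts.items()}
    anchor = min(taxa)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = side if anchor not in side else taxa - side
            node.support = support[key]
    return full, support


def cut_clades(tree: TreeNode, k: int) -> pd.Series:
    """Partition tips into ``k`` clades by removing the ``k-1`` longest
    edges (ties broken by the sorted tip set under the edge); internal
    stem edges dominate in clade-structured data, while pendant edges let
    a single divergent chromosome form its own clade.

    Returns a Series mapping sample id -> clade label; clades are named
    ``clade1..cladeK`` in decreasing size (ties by smallest member id), the
    convention used for frequency tables.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    tips = [t.name for t in tree.tips()]
    if k > len(tips):
        raise ValueError("cannot cut more clades than tips")
    candidates = [
        node for node in tree.traverse(include_self=False)
        if node.parent is not None
    ]
    def under(nd):
        return [t.name for t in nd.tips()] or [nd.name]

    keyed = sorted(
        candidates,
        key=lambda nd: (-(nd.length or 0.0), tuple(sorted(under(nd)))),
    )

    def partition(cut_nodes):
        comp_of: dict[str, int] = {}
        comp_ids: dict[int, int] = {}
        for tip in tree.tips():
            node = tip
            stop = None
            while node is not None:
                if node in cut_nodes:
                    stop = node
                    break
                node = node.parent
            key = id(stop) if stop is not None else -1
            comp_ids.setdefault(key, len(comp_ids))
            comp_of[tip.name] = comp_ids[key]
        return comp_of

    # cutting an edge adds at most one tip-bearing component (a cut can
    # strand a tipless region), so grow the cut set until k groups exist
    cut_nodes: set = set()
    comp_of = partition(cut_nodes)
    for node in keyed:
        if len(set(comp_of.values())) >= k:
            break
        cut_nodes.add(node)
        comp_of = partition(cut_nodes)
    # relabel components: decreasing size, ties by smallest member
    members: dict[int, list[str]] = {}
    for name, c in comp_of.items():
        members.setdefault(c, []).append(name)
    ranked = sorted(members, key=lambda c: (-len(members[c]), min(members[c])))
    rename = {c: f"clade{i + 1}" for i, c in enumerate(ranked)}
    return pd.Series({name: rename[c] for name, c in comp_of.items()}).loc[tips]


def clade_frequencies(labels: pd.Series | dict) -> pd.Series:
    """Per-clade relative frequencies from a sample -> clade mapping,
    ordered by clade label."""
    labels = pd.Series(labels)
    if labels.empty:
        raise ValueError("no samples")
    counts = labels.value_counts().sort_index()
    return counts / len(labels)
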