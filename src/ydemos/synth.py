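"""Clade-structured synthetic haploid SNP data.

Real Y-chromosome panels of this kind (hundreds of males, tens of
thousands of SNPs, a handful of deeply separated haplogroup clades) are
rarely redistributable, so every downstream stage is exercised on generated
data with known clade truth: per-sample clade membership is multinomial in
the requested clade frequencies, each clade's internal genealogy is a
constant-size Kingman coalescent, clades are joined by long stems (making
them monophyletic by construction), and a fixed budget of infinite-sites
mutations is dropped branch-proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalescent import DemographicModel, drop_mutations, simulate_genealogy
from .genealogy import Genealogy
from .haplotypes import HaplotypeMatrix

__all__ = ["SynthConfig", "generate_clade_haplotypes"]


@dataclass
class SynthConfig:
    """Generator settings.

    ``clade_freqs`` drives the multinomial clade-size draw; ``stem_scale``
    is the stem length between clades as a multiple of the mean within-clade
    depth (large values force deep, well-supported clades).  Defaults mirror
    a 345-male, 28,254-SNP panel with the seven-clade mainland Japanese
    frequency spectrum.
    """

    n_samples: int = 345
    n_snps: int = 28_254
    clade_freqs: tuple = (0.354, 0.354, 0.197, 0.041, 0.041, 0.009, 0.006)
    stem_scale: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.n_snps < 1:
            raise ValueError("n_snps must be at least 1")
        if self.stem_scale <= 0:
            raise ValueError("stem_scale must be positive")
        f = np.asarray(self.clade_freqs, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 0.05:
            raise ValueError("clade_freqs must be non-negative and sum to ~1")


def _join_clades(
    subtrees: list[tuple[Genealogy | None, list[str]]], stem: float
) -> Genealogy:
    """Ladder the clade subtrees together with stems of length ``stem``.

    Joins happen at heights ``H + stem``, ``H + 2*stem``, ... above the
    deepest clade, so every clade is separated from the rest by at least one
    stem-length of branch.
    """
    n = sum(len(labels) for _, labels in subtrees)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    labels: list[str] = []
    roots: list[int] = []  # (node index in merged tree) per clade
    tip_base = 0
    internal_entries: list[tuple[float, int, int]] = []  # (time, local parent...)
    # first pass: copy each subtree with its own tip/internal numbering
    copied: list[tuple[np.ndarray, np.ndarray, list[str]]] = []
    max_depth = 0.0
    for sub, labs in subtrees:
        if sub is None:  # singleton clade
            copied.append((np.array([-1], dtype=np.int64), np.zeros(1), labs))
        else:
            copied.append((sub.parent, sub.time, labs))
            max_depth = max(max_depth, sub.tmrca)
    # merged numbering: tips 0..n-1 in clade order, then internal nodes of
    # all clades by time, then the join nodes on top.
    tip_offset = []
    off = 0
    for _, _, labs in copied:
        tip_offset.append(off)
        off += len(labs)
        labels.extend(labs)
    internal_nodes: list[tuple[float, int, int]] = []  # (time, clade, local idx)
    for ci, (par, tim, labs) in enumerate(copied):
        m = len(labs)
        for local in range(m, 2 * m - 1):
            internal_nodes.append((tim[local], ci, local))
    internal_nodes.sort(key=lambda t: t[0])
    index: dict[tuple[int, int], int] = {}
    for ci, (par, tim, labs) in enumerate(copied):
        for local in range(len(labs)):
            index[(ci, local)] = tip_offset[ci] + local
    nxt = n
    for tval, ci, local in internal_nodes:
        index[(ci, local)] = nxt
        nxt += 1
    for ci, (par, tim, labs) in enumerate(copied):
        m = len(labs)
        n_local = 1 if m == 1 else 2 * m - 1
        for local in range(n_local):
            g = index[(ci, local)]
            time[g] = tim[local]
            if par[local] != -1:
                parent[g] = index[(ci, int(par[local]))]
    # ladder joins
    current = index[(0, 0 if len(copied[0][2]) == 1 else 2 * len(copied[0][2]) - 2)]
    h = max_depth
    for ci in range(1, len(copied)):
        m = len(copied[ci][2])
        sub_root = index[(ci, 0 if m == 1 else 2 * m - 2)]
        h += stem
        parent[current] = nxt
        parent[sub_root] = nxt
        time[nxt] = h
        current = nxt
        nxt += 1
    return Genealogy(parent, time, tuple(labels))


def generate_clade_haplotypes(
    config: SynthConfig,
) -> tuple[HaplotypeMatrix, pd.Series, Genealogy]:
    """Generate a clade-structured haploid SNP matrix.

    Returns the matrix, the true clade label per sample (Series indexed by
    sample id), and the generating genealogy.  Deterministic given
    ``config.seed``.  Clades drawn with zero samples are simply absent.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.clade_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    sizes = rng.multinomial(config.n_samples, freqs)
    constant = DemographicModel(n0=1.0)
    subtrees: list[tuple[Genealogy | None, list[str]]] = []
    labels_flat: list[str] = []
    sample_counter = 0
    depths = []
    for ci, size in enumerate(sizes):
        if size == 0:
            continue
        labs = [f"s{sample_counter + j:03d}" for j in range(size)]
        sample_counter += size
        labels_flat.extend([f"clade{ci + 1}"] * size)
        if size == 1:
            subtrees.append((None, labs))
        else:
            sub = simulate_genealogy(constant, int(size), rng)
            sub = Genealogy(sub.parent, sub.time, tuple(labs))
            depths.append(sub.tmrca)
            subtrees.append((sub, labs))
    mean_depth = float(np.mean(depths)) if depths else 1.0
    if len(subtrees) == 1 and subtrees[0][0] is not None:
        gen = subtrees[0][0]
    else:
        gen = _join_clades(subtrees, config.stem_scale * mean_depth)
    matrix = drop_mutations(gen, config.n_snps, rng)
    truth = pd.Series(labels_flat, index=list(gen.labels))
    return matrix, truth, gen
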