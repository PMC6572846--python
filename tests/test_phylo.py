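import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import ydemos as yd
from ydemos.haplotypes import HaplotypeMatrix
from ydemos.phylo import (
    bootstrap_support,
    clade_frequencies,
    cut_clades,
    neighbor_joining,
    p_distance,
    upgma,
)


class TestPDistance:
    def test_identical_rows(self):
        m = HaplotypeMatrix(np.zeros((2, 10), dtype=np.uint8), ["a", "b"])
        assert p_distance(m)["a", "b"] == 0.0

    def test_fraction_of_differences(self):
        g = np.zeros((2, 10), dtype=np.uint8)
        g[1, :2] = 1
        m = HaplotypeMatrix(g, ["a", "b"])
        assert p_distance(m)["a", "b"] == pytest.approx(0.2)

    def test_complementary_rows(self):
        g = np.zeros((2, 8), dtype=np.uint8)
        g[1] = 1
        m = HaplotypeMatrix(g, ["a", "b"])
        assert p_distance(m)["a", "b"] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            p_distance(HaplotypeMatrix(np.zeros((0, 0), dtype=np.uint8), []))


def _lstsq_fit(topology, d):
    """Least-squares branch lengths for a labelled 4-taxon topology.

    ``topology`` is ((i, j), (k, l)): the two cherries of the unrooted
    quartet.  Unknowns: 4 pendant branches + 1 internal.
    """
    (i, j), (k, l) = topology
    taxa = [i, j, k, l]
    rows, rhs = [], []
    for a, b in itertools.combinations(range(4), 2):
        row = np.zeros(5)
        row[a] = row[b] = 1.0
        same_cherry = {taxa[a], taxa[b]} in ({i, j}, {k, l})
        if not same_cherry:
            row[4] = 1.0
        rows.append(row)
        rhs.append(d[taxa[a], taxa[b]])
    sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    fitted = np.array(rows) @ sol
    return sol, float(((fitted - np.array(rhs)) ** 2).sum())


class TestNeighborJoining:
    def additive_matrix(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        ids = list("ABCD")
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        return DistanceMatrix(d, ids=ids)

    def test_additive_matrix_recovered_exactly(self):
        """NJ reproduces an additive matrix; the brute-force oracle
        (topology enumeration + least squares) agrees on the topology."""
        dm = self.additive_matrix()
        tree = neighbor_joining(dm)
        paths = tree.tip_tip_distances(list("ABCD"))
        for a, b in itertools.combinations("ABCD", 2):
            assert paths[a, b] == pytest.approx(dm[a, b], abs=1e-9)
        # oracle: of the 3 quartet topologies only AB|CD fits with zero
        # residual
        topos = [
            (("A", "B"), ("C", "D")),
            (("A", "C"), ("B", "D")),
            (("A", "D"), ("B", "C")),
        ]
        residuals = [_lstsq_fit(t, dm)[1] for t in topos]
        assert np.argmin(residuals) == 0
        assert residuals[0] == pytest.approx(0.0, abs=1e-18)
        # and NJ put A with B: the tree has a bipartition {A,B} | {C,D}
        parts = {
            frozenset(t.name for t in nd.tips())
            for nd in tree.non_tips(include_self=False)
        }
        assert frozenset({"A", "B"}) in parts or frozenset({"C", "D"}) in parts

    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0.0]]), ids=list("ABC")
        )
        tree = neighbor_joining(d)
        # v_A = (d_AB + d_AC - d_BC)/2 = 1, v_B = 2, v_C = 4
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_too_few_samples(self):
        d = DistanceMatrix(np.array([[0, 1], [1, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(d)

    def test_synthetic_clades_monophyletic(self, clade_structured):
        """Every true clade appears as one side of a bipartition of the
        (unrooted) NJ tree."""
        matrix, truth, _ = clade_structured
        tree = neighbor_joining(p_distance(matrix))
        all_tips = frozenset(truth.index)
        parts = set()
        for nd in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in nd.tips())
            parts.add(side)
            parts.add(all_tips - side)
        for clade in truth.unique():
            members = frozenset(truth.index[truth == clade])
            if len(members) < 2:
                continue
            assert members in parts


class TestUpgma:
    def test_two_samples_root_height(self):
        d = DistanceMatrix(np.array([[0, 0.2], [0.2, 0.0]]), ids=["a", "b"])
        assert upgma(d).tmrca == pytest.approx(0.1)

    def test_ultrametric_input_recovered(self):
        # ultrametric tree: ((a:1,b:1):2,(c:2,d:2):1) heights 1, 2, 3
        d = np.array(
            [
                [0, 2, 6, 6],
                [2, 0, 6, 6],
                [6, 6, 0, 4],
                [6, 6, 4, 0.0],
            ]
        )
        gen = upgma(DistanceMatrix(d, ids=list("abcd")))
        heights = sorted(gen.time[gen.n_tips:])
        assert heights == pytest.approx([1.0, 2.0, 3.0])

    def test_output_is_ultrametric(self, small_matrix):
        gen = upgma(p_distance(small_matrix))
        # tips all at zero by construction; parent times monotone
        assert (gen.time[: gen.n_tips] == 0).all()
        assert (gen.branch_lengths() >= -1e-12).all()

    def test_tmrca_recovery_under_constant_clock(self):
        """UPGMA on p-distances recovers the true TMRCA within 20% on
        average (n = 50, constant size, fixed mutation budget)."""
        rng = np.random.default_rng(21)
        errs = []
        for _ in range(100):
            gen = yd.simulate_genealogy(yd.DemographicModel(n0=1000.0), 50, rng)
            m = yd.drop_mutations(gen, 5000, rng)
            tree = upgma(p_distance(m))
            est = tree.tmrca * gen.total_branch_length()
            errs.append(abs(est - gen.tmrca) / gen.tmrca)
        assert np.mean(errs) < 0.20


@pytest.fixture(scope="module")
def small_clades():
    cfg = yd.SynthConfig(
        n_samples=40, n_snps=1500,
        clade_freqs=(0.4, 0.3, 0.2, 0.1, 0, 0, 0),
        stem_scale=20.0, seed=13,
    )
    return yd.generate_clade_haplotypes(cfg)


def _canonical(members, all_tips):
    anchor = min(all_tips)
    return members if anchor not in members else all_tips - members


class TestBootstrap:
    def test_supports_bounded_and_deep_stems_supported(self, small_clades):
        matrix, truth, _ = small_clades
        tree, support = bootstrap_support(matrix, n_reps=100, seed=1)
        all_tips = frozenset(matrix.samples)
        assert all(0.0 <= s <= 100.0 for s in support.values())
        for clade in truth.unique():
            members = frozenset(truth.index[truth == clade])
            if not 1 < len(members) < matrix.n_samples - 1:
                continue
            assert support[_canonical(members, all_tips)] >= 95.0

    def test_clade_support_order_invariance(self, small_clades):
        """Deep-clade supports do not depend on sample order for a fixed
        resample sequence."""
        matrix, truth, _ = small_clades
        perm = np.random.default_rng(2).permutation(matrix.n_samples)
        shuffled = HaplotypeMatrix(
            matrix.genotypes[perm], [matrix.samples[i] for i in perm]
        )
        all_tips = frozenset(matrix.samples)
        _, s1 = bootstrap_support(matrix, n_reps=30, seed=5)
        _, s2 = bootstrap_support(shuffled, n_reps=30, seed=5)
        for clade in truth.unique():
            members = frozenset(truth.index[truth == clade])
            if not 1 < len(members) < matrix.n_samples - 1:
                continue
            key = _canonical(members, all_tips)
            assert s1[key] == pytest.approx(s2[key], abs=5.0)

    def test_zero_reps_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            bootstrap_support(small_matrix, 0)


class TestCutClades:
    def test_single_clade(self, clade_structured):
        matrix, truth, _ = clade_structured
        tree = neighbor_joining(p_distance(matrix))
        labels = cut_clades(tree, 1)
        assert labels.nunique() == 1

    def test_singleton_clades(self, small_matrix):
        tree = neighbor_joining(p_distance(small_matrix))
        labels = cut_clades(tree, small_matrix.n_samples)
        assert labels.nunique() == small_matrix.n_samples

    def test_recovers_generator_truth(self, clade_structured):
        matrix, truth, _ = clade_structured
        tree = neighbor_joining(p_distance(matrix))
        labels = cut_clades(tree, truth.nunique())
        ct = pd.crosstab(truth, labels.loc[truth.index])
        agreement = ct.max(axis=1).sum() / len(truth)
        assert agreement == 1.0

    def test_invalid_k(self, small_matrix):
        tree = neighbor_joining(p_distance(small_matrix))
        with pytest.raises(ValueError):
            cut_clades(tree, 0)


class TestCladeFrequencies:
    def test_printed_clade_counts(self):
        labels = (
            ["clade1"] * 122 + ["clade3"] * 68 + ["clade2"] * 122
            + ["clade4"] * 14 + ["clade5"] * 14 + ["clade6"] * 3
            + ["clade7"] * 2
        )
        labels = pd.Series(labels, index=[f"s{i}" for i in range(345)])
        f = clade_frequencies(labels)
        assert round(f["clade1"], 3) == 0.354
        assert round(f["clade3"], 3) == 0.197

    def test_single_sample(self):
        f = clade_frequencies(pd.Series({"s0": "clade2"}))
        assert f.tolist() == [1.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            clade_frequencies(pd.Series(dtype=object))
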