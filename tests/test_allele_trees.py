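"""Allele trees: p-distances, NJ consistency, CPD_w-b, permutation test,
and the ancient/recent classification rule."""

import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from balscan.allele_trees import (
    CpdResult,
    LocusSkipped,
    basins_reciprocally_monophyletic,
    build_tree,
    classify_locus,
    cophenetic,
    cpd_wb,
    pairwise_distance,
    permutation_test,
)
from balscan.formats_io import HaplotypeLabel, HaplotypeSet, read_newick


def _hapset(seqs, pops, mask=None, species=None):
    n, m = len(seqs), len(seqs[0])
    species = species or ["focal"] * n
    labels = [
        HaplotypeLabel(f"s{i}", pops[i], species[i], i % 2) for i in range(n)
    ]
    haps = np.array([list(s) for s in seqs], dtype="U1")
    mask = np.zeros((n, m), bool) if mask is None else np.asarray(mask, bool)
    return HaplotypeSet("c", (0, m), np.arange(1, m + 1), np.array(["A"] * m),
                        haps, mask, labels)


class TestPairwiseDistance:
    def test_identical_haplotypes_zero(self):
        hs = _hapset(["ACGT", "ACGT"], ["P1", "P1"])
        dm = pairwise_distance(hs)
        assert dm.data[0, 1] == 0.0

    def test_one_mismatch_of_four(self):
        hs = _hapset(["ACGT", "ACGA"], ["P1", "P1"])
        assert pairwise_distance(hs).data[0, 1] == pytest.approx(0.25)

    def test_masked_sites_excluded_from_denominator(self):
        mask = np.zeros((2, 4), bool)
        mask[0, 0] = True
        hs = _hapset(["ACGT", "TCGA"], ["P1", "P1"], mask=mask)
        # comparable sites: positions 2-4, one mismatch
        assert pairwise_distance(hs).data[0, 1] == pytest.approx(1 / 3)

    def test_no_shared_sites_skips_locus(self):
        mask = np.array([[True, False], [False, True]])
        hs = _hapset(["AC", "AC"], ["P1", "P1"], mask=mask)
        with pytest.raises(LocusSkipped):
            pairwise_distance(hs)

    def test_metric_properties_on_random_haplotypes(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(8)]
        d = pairwise_distance(_hapset(seqs, ["P"] * 8)).data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestBuildTree:
    def test_nj_recovers_additive_tree(self):
        # distances generated by ((A:1,B:2):1,(C:3,D:4):1)
        dm = DistanceMatrix(
            np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
            ["A", "B", "C", "D"],
        )
        tree, rooted = build_tree(dm, ["D"])
        assert rooted
        coph = cophenetic(tree)
        for a, b in itertools.combinations("ABCD", 2):
            assert coph[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    def test_two_tips_single_edge(self):
        dm = DistanceMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]), ["A", "B"])
        tree, rooted = build_tree(dm, [])
        assert not rooted
        assert cophenetic(tree)["A", "B"] == pytest.approx(0.4)

    def test_all_zero_matrix_star(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("ABCD"))
        tree, _ = build_tree(dm, [])
        assert all((t.length or 0) == 0 for t in tree.traverse())

    def test_negative_lengths_clamped(self, rng):
        # a non-additive matrix that drives NJ to negative branch estimates
        d = np.array([
            [0, 1.0, 1.0, 1.0],
            [1.0, 0, 1.0, 0.1],
            [1.0, 1.0, 0, 1.0],
            [1.0, 0.1, 1.0, 0],
        ])
        tree, _ = build_tree(DistanceMatrix(d, list("ABCD")), [])
        assert all((n.length or 0) >= 0 for n in tree.traverse())


class TestCpdWb:
    def test_ancient_type_hand_example(self):
        tree = read_newick("((P1x:1,P2x:1):4,(P1y:1,P2y:1):4);")
        labels = {"P1x": "P1", "P1y": "P1", "P2x": "P2", "P2y": "P2"}
        stat, wiqr, biqr = cpd_wb(cophenetic(tree), labels)
        assert stat == pytest.approx(4.0)
        assert wiqr == (10.0, 10.0)

    def test_phylogeographic_hand_example(self):
        tree = read_newick("((P1a:1,P1b:1):4,(P2a:1,P2b:1):4);")
        labels = {"P1a": "P1", "P1b": "P1", "P2a": "P2", "P2b": "P2"}
        stat, _, _ = cpd_wb(cophenetic(tree), labels)
        assert stat == pytest.approx(-8.0)

    def test_star_tree_zero(self):
        tree = read_newick("(P1a:1,P1b:1,P2a:1,P2b:1);")
        labels = {"P1a": "P1", "P1b": "P1", "P2a": "P2", "P2b": "P2"}
        stat, _, _ = cpd_wb(cophenetic(tree), labels)
        assert stat == pytest.approx(0.0)

    def test_outgroup_excluded(self):
        tree = read_newick("(((P1a:1,P1b:1):4,(P2a:1,P2b:1):4):10,Ou:50);")
        labels = {"P1a": "P1", "P1b": "P1", "P2a": "P2", "P2b": "P2"}
        stat, _, _ = cpd_wb(cophenetic(tree), labels)
        assert stat == pytest.approx(-8.0)  # Ou's long branch plays no role

    def test_no_within_pairs_missing(self):
        tree = read_newick("(A:1,B:1,C:1);")
        stat, _, _ = cpd_wb(cophenetic(tree), {"A": "P1", "B": "P2", "C": "P3"})
        assert stat is None

    def test_population_relabeling_invariance(self):
        tree = read_newick("((P1x:1,P2x:1):4,(P1y:1,P2y:1):4);")
        labels = {"P1x": "P1", "P1y": "P1", "P2x": "P2", "P2y": "P2"}
        renamed = {t: {"P1": "P2", "P2": "P1"}[p] for t, p in labels.items()}
        assert cpd_wb(cophenetic(tree), labels)[0] == pytest.approx(
            cpd_wb(cophenetic(tree), renamed)[0]
        )


class TestPermutationTest:
    def _strong_case(self, rng):
        """12 tips, 6 populations, every population's pair split across two
        deep clades: the observed CPD_w-b is essentially maximal."""
        n_pop = 6
        xs = [f"P{i}x" for i in range(n_pop)]
        ys = [f"P{i}y" for i in range(n_pop)]
        ids = xs + ys
        d = np.zeros((12, 12))
        for i in range(12):
            for j in range(i + 1, 12):
                cross = (i < n_pop) != (j < n_pop)
                base = 10.0 if cross else 0.5
                d[i, j] = d[j, i] = base + rng.uniform(0, 0.05)
        labels = {f"P{i}x": f"P{i}" for i in range(n_pop)}
        labels.update({f"P{i}y": f"P{i}" for i in range(n_pop)})
        return DistanceMatrix(d, ids), labels

    def test_extreme_statistic_hits_floor_p(self, rng):
        dm, labels = self._strong_case(rng)
        p = permutation_test(dm, labels, n_perm=999, seed=42)
        # the minimum attainable p is bounded by the probability that a
        # random relabeling also pairs every population across the clades
        assert p <= 2 ** 6 / math.comb(12, 6) * 3 + 1 / 1000

    def test_determinism(self, rng):
        dm, labels = self._strong_case(rng)
        assert permutation_test(dm, labels, seed=7) == permutation_test(
            dm, labels, seed=7
        )

    def test_formula_when_no_permutation_reaches_observed(self):
        """p = 1/(n_perm+1) when the observed statistic strictly exceeds
        every sampled permutation value."""
        rng = np.random.default_rng(123)
        n_pop = 6
        ids = [f"P{i}{s}" for i in range(n_pop) for s in "ab"]
        d = rng.uniform(0.0, 0.2, size=(12, 12))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        for i in range(n_pop):  # the 6 true pairs are far apart
            a, b = 2 * i, 2 * i + 1
            d[a, b] = d[b, a] = 50.0 + i
        labels = {f"P{i}{s}": f"P{i}" for i in range(n_pop) for s in "ab"}
        p = permutation_test(DistanceMatrix(d, ids), labels, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)

    def test_single_population_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"])
        with pytest.raises(ValueError, match="two populations"):
            permutation_test(dm, {"a": "P1", "b": "P1"})

    def test_min_permutations_enforced(self, rng):
        dm, labels = self._strong_case(rng)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(dm, labels, n_perm=10)

    def test_null_uniformity_on_star_trees(self, rng):
        """Exchangeable labels on star trees: rejection rate at alpha=0.05
        stays in [0.01, 0.09] over 200 replicates.

        On a pure star tree CPD_w-b is identically zero for every labeling
        (each tip enters exactly one within pair), so the null carries the
        per-pair jitter that finite-sites distances always have; label
        exchangeability is preserved."""
        n_rej = 0
        reps = 200
        for _ in range(reps):
            lengths = rng.uniform(0.5, 1.5, size=12)
            d = lengths[:, None] + lengths[None, :]
            jit = rng.normal(0, 0.05, size=(12, 12))
            d = np.abs(d + (jit + jit.T) / 2)
            np.fill_diagonal(d, 0)
            ids = [f"t{i}" for i in range(12)]
            labels = {f"t{i}": f"P{i % 6}" for i in range(12)}
            p = permutation_test(DistanceMatrix(d, ids), labels, n_perm=199,
                                 seed=int(rng.integers(2**31)))
            if p <= 0.05:
                n_rej += 1
        assert 0.01 <= n_rej / reps <= 0.09


class TestClassification:
    def test_monophyly_detection(self):
        tree = read_newick("(((A1:1,A2:1):1,(B1:1,B2:1):1):1,Ou:5);")
        basins = {"A1": "atl", "A2": "atl", "B1": "pac", "B2": "pac"}
        assert basins_reciprocally_monophyletic(tree, basins)
        mixed = {"A1": "atl", "B1": "atl", "A2": "pac", "B2": "pac"}
        assert not basins_reciprocally_monophyletic(tree, mixed)

    def _result(self, cpd, adj_p):
        return CpdResult("g", cpd, (0, 1), (0, 1), p_value=adj_p, adjusted_p=adj_p)

    def test_ancient_requires_all_three_conditions(self):
        tree = read_newick("((P1x:1,P2x:1):4,(P1y:1,P2y:1):4);")
        basins = {"P1x": "atl", "P1y": "atl", "P2x": "pac", "P2y": "pac"}
        assert classify_locus(self._result(4.0, 0.001), tree, basins) == "ancient"
        assert classify_locus(self._result(-8.0, 0.001), tree, basins) == "recent"
        assert classify_locus(self._result(4.0, 0.2), tree, basins) == "recent"

    def test_monophyletic_basins_stay_recent(self):
        tree = read_newick("(((A1:1,A2:1):1,(B1:1,B2:1):1):1,Ou:5);")
        basins = {"A1": "atl", "A2": "atl", "B1": "pac", "B2": "pac"}
        assert classify_locus(self._result(4.0, 0.001), tree, basins) == "recent"

    def test_unrooted_tree_skips_monophyly(self):
        tree = read_newick("(((A1:1,A2:1):1,(B1:1,B2:1):1):1,Ou:5);")
        basins = {"A1": "atl", "A2": "atl", "B1": "pac", "B2": "pac"}
        assert classify_locus(self._result(4.0, 0.001), tree, basins,
                              rooted=False) == "ancient"
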