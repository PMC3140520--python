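import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from cyanomine import phylo

from oracles import best_topology_least_squares


class TestPoissonDistance:
    def test_identical_sequences_are_distance_zero(self):
        assert phylo.poisson_distance("MKEL", "MKEL") == 0.0

    @pytest.mark.parametrize("p,expected", [(0.2, 0.22314), (0.1, 0.10536)])
    def test_closed_forms(self, p, expected):
        n = 100
        k = int(p * n)
        a = "A" * n
        b = "C" * k + "A" * (n - k)
        assert phylo.poisson_distance(a, b) == pytest.approx(expected, abs=1e-5)

    def test_pairwise_gap_deletion(self):
        # gapped columns are excluded before counting mismatches
        assert phylo.p_distance("A-CD", "AAC-") == 0.0
        assert phylo.p_distance("A-CD", "CAC-") == 0.5

    def test_saturation_raises(self):
        with pytest.raises(phylo.SaturationError):
            phylo.poisson_distance("AAAA", "CCCC")
        with pytest.raises(phylo.SaturationError):
            phylo.poisson_distance("----", "AAAA")


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_round_trips(self):
        # tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = phylo.neighbor_joining(DistanceMatrix(d, labels))
        assert np.allclose(phylo.patristic_matrix(tree, labels), d, atol=1e-9)
        assert phylo.bipartitions(tree) == {frozenset({"C", "D"})}

    def _additive_five_taxon(self, seed):
        """A random additive 5-taxon matrix plus its generating cherries."""
        rng = np.random.default_rng(seed)
        labels = ["A", "B", "C", "D", "E"]
        perm = list(rng.permutation(labels))
        c1, c2 = frozenset(perm[:2]), frozenset(perm[2:4])
        pend = {l: float(rng.uniform(0.5, 3.0)) for l in labels}
        int1, int2 = float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.5, 2.0))

        def dist(x, y):
            d = pend[x] + pend[y]
            if frozenset({x, y}) in (c1, c2):
                return d
            d += (int1 if (x in c1 or y in c1) else 0.0)
            d += (int2 if (x in c2 or y in c2) else 0.0)
            return d

        mat = np.zeros((5, 5))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i != j:
                    mat[i, j] = dist(x, y)
        return labels, mat, {c1, c2}

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_five_taxon_topology_matches_exhaustive_least_squares(self, seed):
        labels, mat, cherries = self._additive_five_taxon(seed)
        tree = phylo.neighbor_joining(DistanceMatrix(mat, labels))
        assert np.allclose(phylo.patristic_matrix(tree, labels), mat, atol=1e-9)
        nj_cherries = set()
        for part in phylo.bipartitions(tree):
            nj_cherries.add(part if len(part) == 2 else frozenset(labels) - part)
        dist = {}
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    dist[(x, y)] = mat[i, j]
        oracle = set(best_topology_least_squares(labels, dist))
        assert nj_cherries == cherries == oracle

    def test_three_taxa_resolved_consistently(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = phylo.neighbor_joining(DistanceMatrix(d, ["A", "B", "C"]))
        assert np.allclose(phylo.patristic_matrix(tree, ["A", "B", "C"]), d)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(DistanceMatrix(np.array([[0.0, 1], [1, 0]]), ["A", "B"]))


class TestMidpointRoot:
    def test_symmetric_quartet_roots_on_central_edge(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float)
        rooted = phylo.midpoint_root(phylo.neighbor_joining(DistanceMatrix(d, labels)))

        def tipset(node):
            return frozenset(t.name for t in node.tips()) or frozenset({node.name})

        assert {tipset(c) for c in rooted.children} == {
            frozenset({"A", "B"}), frozenset({"C", "D"})
        }
        for tip in rooted.tips():
            assert rooted.distance(tip) == pytest.approx(2.0)

    def test_long_pendant_edge_attracts_the_root(self):
        # caterpillar with one very long pendant edge: midpoint sits on it
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 2, 3, 21],
            [2, 0, 3, 21],
            [3, 3, 0, 20],
            [21, 21, 20, 0],
        ], dtype=float)
        rooted = phylo.midpoint_root(phylo.neighbor_joining(DistanceMatrix(d, labels)))
        # longest path (A-D or B-D) = 21; root equidistant from its deepest tips
        longest = 21.0
        deepest = max(rooted.distance(t) for t in rooted.tips())
        assert deepest == pytest.approx(longest / 2)
        assert any(child.is_tip() and child.name == "D" for child in rooted.children)

    def test_all_zero_lengths_warns_and_keeps_arbitrary_root(self, caplog):
        labels = ["A", "B", "C"]
        d = np.zeros((3, 3))
        tree = phylo.neighbor_joining(DistanceMatrix(d, labels))
        with caplog.at_level("WARNING"):
            rooted = phylo.midpoint_root(tree)
        assert sorted(t.name for t in rooted.tips()) == labels


class TestBootstrap:
    def _split_alignment(self):
        # 50 informative columns (AACC pattern) + 50 shared columns
        s_ab = "A" * 50 + "G" * 50
        s_cd = "C" * 50 + "G" * 50
        return [("t1", s_ab), ("t2", s_ab), ("t3", s_cd), ("t4", s_cd)]

    def test_clean_split_supported_at_100pct(self):
        tree = phylo.bootstrap_support(self._split_alignment(), replicates=50, seed=1)
        supports = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
        assert supports and all(s == 100 for s in supports)

    def test_noise_alignment_has_weak_mean_support(self):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        means = []
        for seed in (1, 2, 3, 4, 5):
            rng = np.random.default_rng(seed)
            aln = [
                (f"t{i}", "".join(aas[j] for j in rng.integers(0, 20, 300)))
                for i in range(8)
            ]
            tree = phylo.bootstrap_support(aln, replicates=50, seed=seed)
            sup = [n.support for n in tree.non_tips(include_self=False) if hasattr(n, "support")]
            means.append(np.mean(sup))
        assert np.mean(means) < 80

    def test_supports_invariant_to_taxon_order(self):
        aln = self._split_alignment()
        t1 = phylo.bootstrap_support(aln, replicates=30, seed=3)
        t2 = phylo.bootstrap_support(aln[::-1], replicates=30, seed=3)

        def support_map(tree):
            out = {}
            for n in tree.non_tips(include_self=False):
                if hasattr(n, "support"):
                    out[frozenset(t.name for t in n.tips())] = n.support
            return out

        m1, m2 = support_map(t1), support_map(t2)
        universe = frozenset(n for n, _ in aln)

        def canon(m):
            return {(s if "t1" not in s else universe - s): v for s, v in m.items()}

        assert canon(m1) == canon(m2)

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            phylo.bootstrap_support(self._split_alignment(), replicates=5, seed=None)


class TestAlignProteins:
    def test_identical_sequences_align_without_gaps(self):
        seqs = [("a", "MKELVW"), ("b", "MKELVW"), ("c", "MKELVW")]
        aligned = phylo.align_proteins(seqs)
        assert all(s == "MKELVW" for _, s in aligned)

    def test_degapped_rows_reproduce_inputs(self):
        seqs = [("a", "MKELVWPLFNNA"), ("b", "MKELPLFNNA"), ("c", "MKELVWPLF")]
        aligned = phylo.align_proteins(seqs)
        assert [n for n, _ in aligned] == ["a", "b", "c"]
        lengths = {len(s) for _, s in aligned}
        assert len(lengths) == 1
        for (name, gapped), (_, original) in zip(aligned, seqs):
            assert gapped.replace("-", "") == original

    def test_newick_export_parses(self):
        aln = [("a", "MKEL"), ("b", "MKEI"), ("c", "MWEL")]
        tree = phylo.neighbor_joining(phylo.distance_matrix(aln))
        nwk = phylo.to_newick(tree)
        assert nwk.endswith(";") and "a" in nwk

    def test_phylip_export(self):
        aln = [("a", "MKEL"), ("b", "MKEI"), ("c", "MWEL")]
        dm = phylo.distance_matrix(aln)
        out = phylo.phylip_matrix(dm)
        assert out.splitlines()[0] == "3"
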