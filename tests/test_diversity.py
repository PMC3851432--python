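"""Panel filtering, per-locus diversity statistics and neighbor joining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualmark.diversity import (
    GenotypePanel,
    PanelCall,
    binary_matrix,
    filter_panel_calls,
    locus_stats,
    neighbor_joining,
    panel_stats,
    read_newick,
    similarity_matrix,
    write_newick,
)
from dualmark.simulate import simulate_genotype_panel


def call(a1, a2, depth=25, quality=40.0, reads=None):
    alleles = (min(a1, a2), max(a1, a2))
    if reads is None:
        reads = (
            {a1: depth} if a1 == a2 else {alleles[0]: depth // 2, alleles[1]: depth - depth // 2}
        )
    return PanelCall(alleles=alleles, depth=depth, quality=quality, reads_per_allele=reads)


def make_panel(genos, loci=None):
    """genos: {locus: {sample: PanelCall}}"""
    loci = loci or sorted(genos)
    samples = sorted({s for g in genos.values() for s in g})
    calls = {(l, s): c for l, g in genos.items() for s, c in g.items()}
    return GenotypePanel(loci=list(loci), samples=samples, calls=calls)


class TestFilterPanelCalls:
    def test_boundaries(self):
        panel = make_panel(
            {
                "L1": {
                    "s1": call("A", "G", depth=16, quality=31.0, reads={"A": 4, "G": 4}),
                    "s2": call("A", "G", depth=15, quality=40.0),   # depth over 15 strict
                    "s3": call("A", "G", depth=20, quality=30.0),   # quality strict
                    "s4": call("A", "G", depth=20, quality=40.0, reads={"A": 3, "G": 17}),
                }
            }
        )
        out = filter_panel_calls(panel)
        assert set(k[1] for k in out.calls) == {"s1"}

    def test_under_called_locus_excluded_from_stats(self):
        panel = make_panel(
            {"L1": {"s1": call("A", "G", depth=5), "s2": call("A", "G", depth=5)}}
        )
        assert panel_stats(filter_panel_calls(panel)) == []


class TestLocusStats:
    def test_balanced_biallelic_pic_is_half(self):
        panel = make_panel(
            {"L1": {"s1": call("A", "A"), "s2": call("G", "G")}}
        )
        s = locus_stats(panel, "L1")
        assert s.pic == pytest.approx(0.5)
        assert s.na == 2 and s.ho == 0.0

    def test_monomorphic_locus_all_zero(self):
        panel = make_panel({"L1": {"s1": call("A", "A"), "s2": call("A", "A")}})
        s = locus_stats(panel, "L1")
        assert (s.na, s.ho, s.he, s.pic) == (1, 0.0, 0.0, 0.0)
        assert s.monomorphic

    def test_seven_three_frequencies(self):
        genos = {"s%d" % i: call("A", "A") for i in range(1, 3)}  # 4 A alleles
        genos.update({"s3": call("A", "G"), "s4": call("A", "G")})  # +2 A, 2 G
        genos["s5"] = call("A", "G")  # +1 A, 1 G -> 7 A, 3 G of 10
        panel = make_panel({"L1": genos})
        s = locus_stats(panel, "L1")
        assert s.frequencies["A"] == pytest.approx(0.7)
        assert s.pic == pytest.approx(1 - 0.49 - 0.09)

    def test_all_heterozygous_unbiased_he_exceeds_half(self):
        panel = make_panel({"L1": {f"s{i:02d}": call("A", "G") for i in range(12)}})
        s = locus_stats(panel, "L1")
        assert s.ho == 1.0
        assert s.he == pytest.approx((24 / 23) * 0.5)
        assert s.pic == pytest.approx(0.5)

    @given(
        st.lists(st.sampled_from(["AA", "AG", "GG", "AC", "CC"]), min_size=2, max_size=30)
    )
    @settings(max_examples=150, deadline=None)
    def test_pic_bounded_by_allele_count(self, genostrs):
        panel = make_panel(
            {"L1": {f"s{i}": call(g[0], g[1]) for i, g in enumerate(genostrs)}}
        )
        s = locus_stats(panel, "L1")
        assert 0.0 <= s.pic <= 1.0 - 1.0 / s.na + 1e-12
        assert abs(sum(s.frequencies.values()) - 1) < 1e-12


class TestBinaryMatrix:
    def test_presence_absence_and_masking(self):
        panel = make_panel(
            {
                "L1": {
                    "s1": call("A", "G"),
                    "s2": call("A", "A"),
                    # s3 missing
                },
                "L2": {"s1": call("C", "C"), "s2": call("C", "C"), "s3": call("C", "C")},
            }
        )
        panel.samples = ["s1", "s2", "s3"]
        mat, cols = binary_matrix(panel)
        assert cols == ["L1:A", "L1:G", "L2:C"]
        assert mat[0].tolist() == [1.0, 1.0, 1.0]   # A/G het
        assert mat[1].tolist() == [1.0, 0.0, 1.0]   # A/A hom
        assert bool(mat.mask[2, 0]) and bool(mat.mask[2, 1])
        assert mat[2, 2] == 1.0


class TestSimilarity:
    def test_identical_complementary_and_partial(self):
        m = np.ma.masked_invalid(
            [[1, 0, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 1]]
        )
        sim, dist = similarity_matrix(m)
        assert sim[0, 1] == 1.0 and dist[0, 1] == 0.0
        assert sim[0, 2] == 0.0
        assert sim[0, 3] == 0.75
        assert np.allclose(sim, sim.T) and np.allclose(np.diag(sim), 1.0)

    def test_no_comparable_cells_raises(self):
        m = np.ma.masked_all((2, 3))
        m[0, 0] = 1.0
        m[1, 1] = 1.0
        with pytest.raises(ValueError, match="no comparable"):
            similarity_matrix(m)

    def test_jaccard_ignores_shared_absence(self):
        m = np.ma.masked_invalid([[1, 0, 0, 0], [1, 0, 0, 1]])
        sim, _ = similarity_matrix(m, "jaccard")
        assert sim[0, 1] == pytest.approx(0.5)


def random_tree_distances(n, rng):
    """Additive distances from a random binary tree with known topology.

    Returns (distance matrix, labels, skbio tree) built by random sequential
    attachment with positive branch lengths.
    """
    from skbio import TreeNode

    labels = [f"t{i}" for i in range(n)]
    tree = TreeNode.read(
        iter([f"({labels[0]}:{rng.uniform(0.1, 1):.4f},{labels[1]}:{rng.uniform(0.1, 1):.4f});"])
    )
    leaves = {labels[0], labels[1]}
    for label in labels[2:]:
        target = rng.choice(sorted(leaves))
        node = [t for t in tree.tips() if t.name == target][0]
        stay = TreeNode(name=node.name, length=rng.uniform(0.1, 1.0))
        new = TreeNode(name=label, length=rng.uniform(0.1, 1.0))
        node.name = None
        node.append(stay)
        node.append(new)
        leaves.add(label)
    dm = tree.tip_tip_distances()
    order = [dm.ids.index(l) for l in labels]
    return np.asarray(dm.data)[np.ix_(order, order)], labels, tree


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(d, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: a=(2+3-5)/2=0, b=(2+5-3)/2=2, c=(3+5-2)/2=3
        assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((a:2,b:3):1,(c:4,d:5)): additive distances
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(d, list("abcd"))
        dm = tree.tip_tip_distances()
        for i, x in enumerate("abcd"):
            for j, y in enumerate("abcd"):
                assert dm[x, y] == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_additive_matrices_path_lengths_exact(self, n):
        rng = np.random.default_rng(n)
        d, labels, _ = random_tree_distances(n, rng)
        tree = neighbor_joining(d, labels)
        dm = tree.tip_tip_distances()
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                assert dm[x, y] == pytest.approx(d[i, j], abs=1e-9)

    def test_agrees_with_reference_nj_on_random_matrix(self):
        from skbio.tree import nj as skbio_nj
        from skbio import DistanceMatrix

        rng = np.random.default_rng(0)
        d, labels, _ = random_tree_distances(7, rng)
        ours = neighbor_joining(d, labels)
        ref = skbio_nj(DistanceMatrix(d, labels))
        ours_dm = ours.tip_tip_distances()
        ref_dm = ref.tip_tip_distances()
        for x in labels:
            for y in labels:
                assert ours_dm[x, y] == pytest.approx(ref_dm[x, y], abs=1e-9)

    def test_permutation_invariance_of_topology(self):
        rng = np.random.default_rng(4)
        d, labels, _ = random_tree_distances(6, rng)
        perm = rng.permutation(6)
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        t1 = neighbor_joining(d, labels)
        t2 = neighbor_joining(d2, labels2)
        assert t1.compare_rfd(t2) == 0.0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(d, list("abc"))

    def test_negative_branch_lengths_clamped(self):
        d = np.array(
            [[0, 0.1, 0.4, 0.5], [0.1, 0, 0.5, 0.4], [0.4, 0.5, 0, 0.1], [0.5, 0.4, 0.1, 0]]
        )
        tree = neighbor_joining(d, list("abcd"))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0.0


class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(2)
        d, labels, _ = random_tree_distances(8, rng)
        tree = neighbor_joining(d, labels)
        back = read_newick(write_newick(tree))
        assert tree.compare_rfd(back) == 0.0
        d1, d2 = tree.tip_tip_distances(), back.tip_tip_distances()
        for x in labels:
            for y in labels:
                assert d2[x, y] == pytest.approx(d1[x, y], abs=1e-5)

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError, match="malformed"):
            read_newick("((a:1,b:2;")


class TestPanelToTree:
    def test_disjoint_subpopulations_form_two_clades(self):
        n_loci = 50
        spec = {
            "pop1": (12, np.ones(n_loci)),   # fixed allele 1
            "pop2": (12, np.zeros(n_loci)),  # fixed allele 2
        }
        panel, truth = simulate_genotype_panel(24, n_loci, spec, seed=10)
        mat, _ = binary_matrix(panel)
        _, dist = similarity_matrix(mat)
        tree = neighbor_joining(dist, panel.samples)
        pop1 = {s for s, p in truth.subpop_of.items() if p == "pop1"}
        # some internal edge must split the leaves exactly into pop1 | pop2
        splits = []
        for node in tree.non_tips():
            below = {t.name for t in node.tips()}
            splits.append(below)
        assert any(s == pop1 or s == set(panel.samples) - pop1 for s in splits)

    def test_recovers_simulated_allele_frequencies(self):
        n_loci = 40
        freqs = np.linspace(0.2, 0.8, n_loci)
        panel, _ = simulate_genotype_panel(
            24, n_loci, {"p": (24, freqs)}, seed=3
        )
        stats = panel_stats(panel)
        he = np.mean([s.he for s in stats])
        expected = np.mean(2 * freqs * (1 - freqs)) * (48 / 47)
        assert abs(he - expected) < 0.05
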