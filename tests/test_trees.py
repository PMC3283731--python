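import numpy as np
import pytest

from alnscope import (
    bootstrap_supports,
    build_nj_tree,
    generate_alignment,
    cluster_otus,
    classify_otus,
    k2p_distance_matrix,
    monophyly_report,
    mrca,
    otu_internal_distance,
)
from alnscope.distances import DistanceMatrix
from alnscope.otu import OTU
from alnscope.trees import (
    SingletonDistanceError,
    _tree_splits,
    otu_internal_distance_pairwise,
)

from conftest import clean_cluster_spec, true_partition
from oracles import best_ls_topology, random_additive_matrix, topology_splits


def _dm(labels, d):
    return DistanceMatrix(tuple(labels), np.asarray(d, dtype=float), frozenset())


def _patristic(tree):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return pdm, taxa


def _splits_as_indices(tree, labels):
    index = {lab: i for i, lab in enumerate(labels)}
    out = set()
    n = len(labels)
    for side in _tree_splits(tree):
        ids = frozenset(index[l] for l in side)
        comp = frozenset(range(n)) - ids
        out.add(ids if 0 not in ids else comp)
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        # three-point formulas: x = (d_ab + d_ac - d_bc)/2 etc.
        dm = _dm("abc", [[0, 5, 9], [5, 0, 10], [9, 10, 0]])
        tree = build_nj_tree(dm)
        pdm, taxa = _patristic(tree)
        assert pdm.patristic_distance(taxa["a"], taxa["b"]) == pytest.approx(5)
        assert pdm.patristic_distance(taxa["a"], taxa["c"]) == pytest.approx(9)
        assert pdm.patristic_distance(taxa["b"], taxa["c"]) == pytest.approx(10)

    @pytest.mark.parametrize("variant", ["bionj", "classic_nj"])
    def test_four_taxon_additive_recovery(self, variant):
        # tree ((a:1,b:2):3,(c:4,d:5)) gives this additive matrix
        dm = _dm("abcd", [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]])
        tree = build_nj_tree(dm, variant)
        pdm, taxa = _patristic(tree)
        for i, x in enumerate("abcd"):
            for y in "abcd"[i + 1 :]:
                assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(
                    dm.distance(x, y)
                )
        # canonical split side is the one not containing leaf 0
        assert _splits_as_indices(tree, "abcd") == {frozenset({2, 3})}

    @pytest.mark.parametrize("variant", ["bionj", "classic_nj"])
    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_additive_recovery_vs_least_squares_oracle(self, variant, n):
        rng = np.random.default_rng(100 + n)
        labels = [f"t{i}" for i in range(n)]
        D, true_splits = random_additive_matrix(n, rng)
        tree = build_nj_tree(_dm(labels, D), variant)
        assert _splits_as_indices(tree, labels) == true_splits
        oracle_edges, _ = best_ls_topology(D)
        assert topology_splits(oracle_edges, n) == true_splits
        pdm, taxa = _patristic(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm.patristic_distance(
                    taxa[labels[i]], taxa[labels[j]]
                ) == pytest.approx(D[i, j], abs=1e-9)

    def test_total_length_invariant_to_leaf_order(self):
        rng = np.random.default_rng(8)
        D, _ = random_additive_matrix(6, rng)
        labels = [f"t{i}" for i in range(6)]
        t1 = build_nj_tree(_dm(labels, D))
        perm = rng.permutation(6)
        t2 = build_nj_tree(_dm([labels[i] for i in perm], D[np.ix_(perm, perm)]))
        assert t1.length() == pytest.approx(t2.length())

    def test_equal_distances_tie_broken_deterministically(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = build_nj_tree(_dm("abcd", d))
        t2 = build_nj_tree(_dm("abcd", d))
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_undefined_distance_rejected_naming_pair(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="a~b"):
            build_nj_tree(DistanceMatrix(("a", "b", "c"), d, frozenset()))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            build_nj_tree(_dm("ab", [[0, 1], [1, 0]]))

    def test_agrees_with_independent_nj_implementation(self):
        # cross-check topology against scikit-bio's neighbour joining
        import skbio

        rng = np.random.default_rng(4)
        D, _ = random_additive_matrix(7, rng)
        labels = [f"t{i}" for i in range(7)]
        ours = build_nj_tree(_dm(labels, D), "classic_nj")
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        sk_splits = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < 6:
                comp = frozenset(labels) - side
                sk_splits.add(side if "t0" not in side else comp)
        assert sk_splits == _tree_splits(ours)


class TestMRCAAndInternalDistance:
    @pytest.fixture
    def fixture_tree(self):
        # ((a:1,b:2):3,(c:4,(d:1,e:1):2):1,f:9)
        import dendropy

        return dendropy.Tree.get(
            data="((a:1,b:2):3,(c:4,(d:1,e:1):2):1,f:9);", schema="newick"
        )

    def test_sister_leaves_join_at_parent(self, fixture_tree):
        node = mrca(fixture_tree, {"a", "b"})
        assert {lf.taxon.label for lf in node.leaf_iter()} == {"a", "b"}

    def test_nested_clade(self, fixture_tree):
        node = mrca(fixture_tree, {"c", "d"})
        assert {lf.taxon.label for lf in node.leaf_iter()} == {"c", "d", "e"}

    def test_all_leaves_give_root(self, fixture_tree):
        node = mrca(fixture_tree, set("abcdef"))
        assert len(list(node.leaf_iter())) == 6

    def test_unknown_label_rejected(self, fixture_tree):
        with pytest.raises(KeyError):
            mrca(fixture_tree, {"a", "zzz"})

    def test_internal_distance_is_max_path_to_mrca(self, fixture_tree):
        otu = OTU("OTU1", "d", ("d", "e"), otu_class="multiton")
        assert otu_internal_distance(fixture_tree, otu) == pytest.approx(1.0)
        otu2 = OTU("OTU2", "c", ("c", "d", "e"), otu_class="multiton")
        assert otu_internal_distance(fixture_tree, otu2) == pytest.approx(4.0)

    def test_singleton_internal_distance_undefined(self, fixture_tree):
        with pytest.raises(SingletonDistanceError):
            otu_internal_distance(fixture_tree, OTU("OTU1", "a", ("a",)))

    def test_quasi_singleton_has_zero_internal_distance(self):
        spec = clean_cluster_spec(seed=2, within_divergence=0.0,
                                  between_divergence=0.2)
        aln, _ = generate_alignment(spec)
        dm = k2p_distance_matrix(aln)
        tree = build_nj_tree(dm)
        table = classify_otus(cluster_otus(aln, 0.95), aln)
        quasis = [o for o in table.otus if o.otu_class == "quasi_singleton"]
        assert quasis
        for otu in quasis:
            assert otu_internal_distance(tree, otu) == pytest.approx(0.0, abs=1e-12)

    def test_internal_distance_bounded_by_max_leaf_pair_path(self, planted):
        aln, _ = planted
        tree = build_nj_tree(k2p_distance_matrix(aln))
        table = classify_otus(cluster_otus(aln, 0.95), aln)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for otu in table.otus:
            if otu.size < 2:
                continue
            d_int = otu_internal_distance(tree, otu)
            max_pair = max(
                pdm.patristic_distance(taxa[x], taxa[y])
                for i, x in enumerate(otu.member_ids)
                for y in otu.member_ids[i + 1 :]
            )
            assert d_int <= max_pair + 1e-9

    def test_pairwise_fallback_is_half_max_within_distance(self):
        d = np.array([[0, 0.04, 0.1], [0.04, 0, 0.1], [0.1, 0.1, 0]])
        dm = DistanceMatrix(("a", "b", "c"), d, frozenset())
        otu = OTU("O", "a", ("a", "b"))
        assert otu_internal_distance_pairwise(dm, otu) == pytest.approx(0.02)


class TestBootstrap:
    def test_deep_split_gets_full_support(self):
        spec = clean_cluster_spec(seed=9, n_sequences=12, n_clusters=2)
        aln, truth = generate_alignment(spec)
        sup = bootstrap_supports(aln, replicates=30, seed=1)
        parts = true_partition(truth)
        all_labels = frozenset(aln.ids)
        from alnscope.trees import _canonical_split

        for part in parts:
            key = _canonical_split(part, all_labels)
            assert sup.supports.get(key) == pytest.approx(100.0)

    def test_fixed_seed_reproducible(self):
        spec = clean_cluster_spec(seed=10, n_sequences=10, n_clusters=2)
        aln, _ = generate_alignment(spec)
        a = bootstrap_supports(aln, replicates=10, seed=3)
        b = bootstrap_supports(aln, replicates=10, seed=3)
        assert a.supports == b.supports

    def test_single_replicate_supports_are_binary(self):
        spec = clean_cluster_spec(seed=12, n_sequences=10, n_clusters=2)
        aln, _ = generate_alignment(spec)
        sup = bootstrap_supports(aln, replicates=1, seed=0)
        assert set(sup.supports.values()) <= {0.0, 100.0}


class TestMonophyly:
    def test_planted_clusters_are_monophyletic(self):
        spec = clean_cluster_spec(seed=13, n_sequences=18, n_clusters=3)
        aln, truth = generate_alignment(spec)
        tree = build_nj_tree(k2p_distance_matrix(aln))
        sup = bootstrap_supports(aln, replicates=10, seed=2)
        grouping = {
            sid: f"g{cl}" for sid, cl in truth.cluster_labels.items()
        }
        report = monophyly_report(tree, sup, grouping)
        assert all(g.monophyletic for g in report.groups)
        assert 0 <= report.tree_mean_support <= 100

    def test_interleaved_groups_are_not_monophyletic(self):
        import dendropy

        tree = dendropy.Tree.get(
            data="((a:1,b:1):1,(c:1,d:1):1,(e:1,f:1):1);", schema="newick"
        )
        from alnscope.trees import CladeSupport

        sup = CladeSupport(supports={}, replicates=0, seed=None)
        grouping = {"a": "g1", "c": "g1", "b": "g2", "d": "g2", "e": "g2", "f": "g1"}
        report = monophyly_report(tree, sup, grouping)
        assert not any(g.monophyletic for g in report.groups)

    def test_missing_group_rejected(self):
        import dendropy

        from alnscope.trees import CladeSupport

        tree = dendropy.Tree.get(data="((a:1,b:1):1,c:1,d:1);", schema="newick")
        sup = CladeSupport(supports={}, replicates=0, seed=None)
        with pytest.raises(ValueError, match="no leaves"):
            monophyly_report(tree, sup, {"zzz": "ghost"})
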