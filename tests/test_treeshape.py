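import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

import fatemap as fm
from fatemap.distance import DistanceMatrix
from fatemap.treeshape import read_nexus_characters, read_trees


def tree_from_newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestNbar:
    def test_balanced_16_tips_is_4(self):
        assert fm.nbar(fm.balanced_tree(16)) == 4.0

    def test_caterpillar_14_tips_is_7_43(self):
        assert round(fm.nbar(fm.caterpillar_tree(14)), 2) == 7.43

    def test_two_tip_tree(self):
        assert fm.nbar(fm.caterpillar_tree(2)) == 1.0

    @pytest.mark.parametrize("k", range(1, 7))
    def test_balanced_closed_form(self, k):
        assert fm.nbar(fm.balanced_tree(2**k)) == float(k)

    @pytest.mark.parametrize("n", range(2, 51))
    def test_caterpillar_closed_form(self, n):
        expected = (n - 1) * (n + 2) / (2 * n)
        assert fm.nbar(fm.caterpillar_tree(n)) == pytest.approx(expected)

    def test_polytomy_handled_directly(self):
        tree = tree_from_newick("((a,b,c),d);")
        assert fm.nbar(tree) == pytest.approx((2 + 2 + 2 + 1) / 4)

    def test_single_tip_rejected(self):
        with pytest.raises(ValueError):
            fm.nbar(tree_from_newick("a;"))


def oracle_colless(tree):
    """Independent Colless computation via per-node leaf sets."""
    leafsets = {}
    raw = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[node] = 1
            continue
        kids = node.child_nodes()
        leafsets[node] = sum(leafsets[k] for k in kids)
        if len(kids) == 2:
            raw += abs(leafsets[kids[0]] - leafsets[kids[1]])
    return raw


def all_topologies(labels):
    """Every rooted binary labeled topology, by recursive pairing."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    for k in range(len(rest) + 1):
        for subset in itertools.combinations(rest, k):
            left = [first] + list(subset)
            right = [x for x in rest if x not in subset]
            if not right:
                continue
            for lt in all_topologies(left):
                for rt in all_topologies(right):
                    yield f"({lt},{rt})"


class TestColless:
    def test_balanced_is_zero(self):
        assert fm.colless(fm.balanced_tree(8)).colless_raw == 0

    @pytest.mark.parametrize("n", range(3, 51))
    def test_caterpillar_closed_form(self, n):
        s = fm.colless(fm.caterpillar_tree(n))
        assert s.colless_raw == (n - 1) * (n - 2) // 2
        assert s.colless_normalized == pytest.approx(1.0)

    @pytest.mark.parametrize("n_tips", [4, 5])
    def test_matches_enumeration_oracle(self, n_tips):
        labels = [f"t{i}" for i in range(n_tips)]
        seen = 0
        for newick in set(all_topologies(labels)):
            tree = tree_from_newick(newick + ";")
            assert fm.colless(tree).colless_raw == oracle_colless(tree)
            seen += 1
        # sanity: enumeration covered every rooted labeled topology
        assert seen == fm.count_lineage_histories(n_tips)

    def test_polytomy_rejected_in_strict_mode(self):
        tree = tree_from_newick("((a,b,c),d);")
        with pytest.raises(ValueError, match="resolve"):
            fm.colless(tree)

    def test_polytomy_resolution_is_seeded(self):
        tree = tree_from_newick("((a,b,c,d),(e,f,g));")
        r1 = fm.colless(tree, polytomies="resolve", seed=5)
        r2 = fm.colless(tree, polytomies="resolve", seed=5)
        assert r1 == r2


class TestRandomizeGenotypes:
    def test_per_locus_allele_multiset_preserved(self, small_lineage):
        m = small_lineage.matrix
        rm = fm.randomize_genotypes(m, seed=3)
        for j in range(m.n_loci):
            assert sorted(m.alleles[:, j, :].ravel()) == sorted(
                rm.alleles[:, j, :].ravel()
            )

    def test_seed_reproducible(self, small_lineage):
        a = fm.randomize_genotypes(small_lineage.matrix, seed=4)
        b = fm.randomize_genotypes(small_lineage.matrix, seed=4)
        assert a == b

    def test_single_clone_unchanged(self):
        frame = pd.DataFrame({"L1": ["106/105"]}, index=["a"])
        m = fm.GenotypeMatrix.from_frame(frame)
        assert fm.randomize_genotypes(m, seed=1) == m

    def test_destroys_tissue_signal(self, small_lineage):
        m = small_lineage.matrix
        key = m.meta["tissue"] + m.meta["side"]
        iu, ju = np.triu_indices(m.n_clones, 1)

        def gap(matrix):
            d = fm.distance_matrix(matrix).values[iu, ju]
            same = (key.iloc[iu].to_numpy() == key.iloc[ju].to_numpy())
            return np.nanmean(d[~same]) - np.nanmean(d[same])

        observed_gap = gap(m)
        null_gaps = [
            gap(fm.randomize_genotypes(m, seed=s)) for s in range(15)
        ]
        assert observed_gap > 0
        assert abs(np.mean(null_gaps)) < observed_gap / 3


class TestRecoding:
    def test_monomorphic_locus_all_zero(self):
        frame = pd.DataFrame({"L1": ["106/106"] * 3}, index=list("abc"))
        rec = fm.recode_for_phylogenetics(fm.GenotypeMatrix.from_frame(frame))
        assert (rec.matrix == "0").all().all()

    def test_frequency_ranked_codes(self):
        cells = ["106/106"] * 5 + ["105/105"] * 3 + ["107/107"]
        frame = pd.DataFrame({"L1": cells}, index=[f"c{i}" for i in range(9)])
        rec = fm.recode_for_phylogenetics(fm.GenotypeMatrix.from_frame(frame))
        col = rec.matrix["L1_a"]
        assert col.iloc[0] == "0" and col.iloc[5] == "1" and col.iloc[8] == "2"

    def test_missing_becomes_question_mark(self):
        frame = pd.DataFrame({"L1": ["106/X", "106/106"]}, index=["a", "b"])
        rec = fm.recode_for_phylogenetics(fm.GenotypeMatrix.from_frame(frame))
        assert rec.matrix.loc["a", "L1_b"] == "?"

    def test_more_than_ten_alleles_merged_into_9(self):
        cells = [f"{100 + i}/{100 + i}" for i in range(12)]
        frame = pd.DataFrame({"L1": cells}, index=[f"c{i}" for i in range(12)])
        rec = fm.recode_for_phylogenetics(fm.GenotypeMatrix.from_frame(frame))
        assert set(rec.matrix["L1_a"]) <= set("0123456789")
        assert (rec.matrix["L1_a"] == "9").sum() == 3

    def test_nexus_round_trip(self, small_lineage, tmp_path):
        rec = fm.recode_for_phylogenetics(small_lineage.matrix)
        path = tmp_path / "chars.nex"
        rec.to_nexus(path)
        back = read_nexus_characters(path)
        assert back.shape == rec.matrix.shape
        original = rec.matrix.copy()
        original.columns = range(original.shape[1])
        pd.testing.assert_frame_equal(
            back.sort_index(), original.sort_index(), check_names=False
        )


class TestBuildDistanceTree:
    def test_three_taxon_cherry(self):
        vals = np.array([[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]])
        dm = DistanceMatrix(["a", "b", "c"], vals, np.full((3, 3), 5))
        tree = fm.build_distance_tree(dm)
        a = tree.find_node_with_taxon_label("a")
        b = tree.find_node_with_taxon_label("b")
        assert a.parent_node is b.parent_node

    def test_recovers_ultrametric_topology(self):
        # ultrametric matrix of a balanced 8-taxon tree built from nested
        # divergence heights
        labels = [f"t{i + 1}" for i in range(8)]
        vals = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                # balanced tree: divergence depth = highest differing bit
                level = (max(i, j) ^ min(i, j)).bit_length()
                vals[i, j] = 2.0 * level
        dm = DistanceMatrix(labels, vals, np.full((8, 8), 5))
        tree = fm.build_distance_tree(dm)
        t0 = tree.find_node_with_taxon_label("t1")
        t1 = tree.find_node_with_taxon_label("t2")
        assert t0.parent_node is t1.parent_node
        s = fm.colless(tree)
        assert s.colless_raw == 0  # fully balanced recovered

    def test_undefined_distances_rejected(self):
        vals = np.array([[0, np.nan], [np.nan, 0]])
        dm = DistanceMatrix(["a", "b"], vals, np.zeros((2, 2), int))
        with pytest.raises(ValueError, match="undefined"):
            fm.build_distance_tree(dm)

    def test_label_permutation_equivariance(self, small_lineage):
        dm = fm.distance_matrix(small_lineage.matrix)
        tree1 = fm.build_distance_tree(dm)
        order = np.arange(len(dm.clone_ids))[::-1]
        dm2 = DistanceMatrix(
            [dm.clone_ids[i] for i in order],
            dm.values[np.ix_(order, order)],
            dm.n_usable[np.ix_(order, order)],
        )
        tree2 = fm.build_distance_tree(dm2)
        assert {l.taxon.label for l in tree1.leaf_node_iter()} == {
            l.taxon.label for l in tree2.leaf_node_iter()
        }
        assert fm.colless(tree1).colless_raw == fm.colless(tree2).colless_raw


class TestShapeNullComparison:
    def test_distribution_sizes(self, small_lineage):
        cmp = fm.shape_null_comparison(
            small_lineage.matrix, n_randomizations=12, seed=5
        )
        assert len(cmp.null) == 12
        assert len(cmp.observed) == 1

    def test_randomized_input_shows_no_shift(self, small_lineage):
        rm = fm.randomize_genotypes(small_lineage.matrix, seed=77)
        cmp = fm.shape_null_comparison(rm, n_randomizations=30, seed=78)
        assert cmp.nbar_p > 0.05

    def test_structured_lineage_more_symmetric_than_null(self):
        shifts = []
        for seed in (0, 1, 2):
            m = fm.simulate_lineage(
                fm.SimulationConfig(n_loci=60, cells_per_tissue=8, seed=seed)
            ).matrix
            cmp = fm.shape_null_comparison(m, n_randomizations=25, seed=seed + 50)
            shifts.append(cmp.nbar_shift)
        assert np.mean(shifts) < 0

    def test_external_trees_accepted(self, small_lineage, tmp_path):
        tree = fm.build_distance_tree(fm.distance_matrix(small_lineage.matrix))
        path = tmp_path / "trees.nwk"
        path.write_text(tree.as_string(schema="newick"))
        trees = read_trees(path)
        cmp = fm.shape_null_comparison(
            small_lineage.matrix,
            n_randomizations=10,
            seed=9,
            observed_trees=trees,
        )
        assert len(cmp.observed) == len(trees)
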