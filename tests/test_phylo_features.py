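import numpy as np
import pytest

from microhdf.io_profiles import AbundanceProfile
from microhdf.phylo_features import (
    assemble_views,
    build_taxonomy_tree,
    level_template,
    populate_template,
    postorder_template,
    reconcile_tree,
)
from microhdf.synthetic import SyntheticSpec, simulate
from microhdf.tree import TaxonomyTree


class TestBuildTaxonomyTree:
    def test_shared_genus_topology(self, lineage_profile):
        tree = build_taxonomy_tree(lineage_profile)
        assert tree.n_leaves() == 3
        genus_nodes = [n for n in tree.preorder() if n.rank == "g"]
        assert len(genus_nodes) == 2
        roseburia = next(n for n in genus_nodes if "Roseburia" in n.name)
        assert len(roseburia.children) == 2

    def test_single_species_chain(self):
        prof = AbundanceProfile(
            ["s"], ["k__B|p__F|g__R|s__X"], np.array([[1.0]])
        )
        tree = build_taxonomy_tree(prof)
        node, depth = tree.root, 0
        while node.children:
            assert len(node.children) == 1
            node = node.children[0]
            depth += 1
        assert depth == 4 and node.is_leaf

    def test_conflicting_lineages_error(self):
        prof = AbundanceProfile(
            ["s"],
            ["k__B|g__G1|s__X", "k__B|g__G2|s__X"],
            np.array([[0.5, 0.5]]),
        )
        with pytest.raises(ValueError, match="conflicting lineages"):
            build_taxonomy_tree(prof)

    def test_children_sorted_lexicographically(self, lineage_profile):
        tree = build_taxonomy_tree(lineage_profile)
        for node in tree.preorder():
            names = [c.name for c in node.children]
            assert names == sorted(names)


class TestTemplates:
    def test_level_template_toy(self, toy_tree):
        tmpl = level_template(toy_tree)
        assert tmpl.node_ids == ["R", "C", "E", "A", "B", "D"]
        assert tmpl.include_internal

    def test_postorder_template_toy(self, toy_tree):
        tmpl = postorder_template(toy_tree)
        assert tmpl.node_ids == ["A", "B", "D"]
        assert not tmpl.include_internal

    def test_single_chain(self):
        tree = TaxonomyTree.from_newick("(A)R;")
        assert level_template(tree).node_ids == ["R", "A"]
        assert postorder_template(tree).node_ids == ["A"]

    def test_star_tree(self):
        tree = TaxonomyTree.from_newick("(A,B,C,D)R;")
        assert level_template(tree).node_ids == ["R", "A", "B", "C", "D"]

    def test_mirrored_tree_reverses_groups(self):
        mirrored = TaxonomyTree.from_newick("((D)E,(A,B)C)R;")
        assert postorder_template(mirrored).node_ids == ["D", "A", "B"]

    def test_permutation_stability(self):
        spec = SyntheticSpec(n_taxa=30, n_case=3, n_control=3, seed=5)
        profile, _, _, _ = simulate(spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(profile.taxon_ids))
        shuffled = AbundanceProfile(
            profile.sample_ids,
            [profile.taxon_ids[i] for i in perm],
            profile.values[:, perm],
        )
        t1 = build_taxonomy_tree(profile)
        t2 = build_taxonomy_tree(shuffled)
        assert level_template(t1).node_ids == level_template(t2).node_ids
        assert postorder_template(t1).node_ids == postorder_template(t2).node_ids

    def test_postorder_is_permutation_of_taxa(self):
        spec = SyntheticSpec(n_taxa=25, n_case=3, n_control=3, seed=6)
        profile, _, tree, _ = simulate(spec)
        assert sorted(postorder_template(tree).node_ids) == sorted(profile.taxon_ids)


class TestPopulateTemplate:
    def test_level_row_with_clade_sums(self, toy_tree, toy_profile):
        tmpl = level_template(toy_tree)
        mat = populate_template(toy_profile, toy_tree, tmpl)
        np.testing.assert_allclose(mat.values, [[1.0, 0.8, 0.2, 0.5, 0.3, 0.2]])

    def test_postorder_row_is_reordering(self, toy_tree, toy_profile):
        tmpl = postorder_template(toy_tree)
        mat = populate_template(toy_profile, toy_tree, tmpl)
        np.testing.assert_allclose(mat.values, [[0.5, 0.3, 0.2]])

    def test_all_zero_sample(self, toy_tree):
        prof = AbundanceProfile(["s"], ["A", "B", "D"], np.zeros((1, 3)))
        mat = populate_template(prof, toy_tree, level_template(toy_tree))
        np.testing.assert_array_equal(mat.values, np.zeros((1, 6)))

    def test_template_tree_mismatch(self, toy_tree, toy_profile):
        other = TaxonomyTree.from_newick("((X,Y)Z)W;")
        tmpl = level_template(other)
        with pytest.raises(ValueError, match="not in tree"):
            populate_template(toy_profile, toy_tree, tmpl)

    def test_hierarchical_consistency_on_synthetic(self):
        spec = SyntheticSpec(n_taxa=40, n_case=4, n_control=4, seed=2)
        profile, _, tree, _ = simulate(spec)
        tmpl = level_template(tree)
        mat = populate_template(profile, tree, tmpl)
        col = dict(zip(tmpl.node_ids, range(len(tmpl))))
        for node in tree.preorder():
            if node.children:
                child_sum = sum(mat.values[:, col[c.id]] for c in node.children)
                np.testing.assert_allclose(mat.values[:, col[node.id]], child_sum)
        # root column equals total abundance (1 after normalization)
        np.testing.assert_allclose(mat.values[:, col[tree.root.id]], 1.0)


class TestAssembleViews:
    def test_mode_O_identity(self, toy_tree, toy_profile):
        X, names, feats = assemble_views(toy_profile, None, None, "O")
        np.testing.assert_array_equal(X, toy_profile.values)
        assert names == ["raw:A", "raw:B", "raw:D"]
        assert feats == ["A", "B", "D"]

    def test_mode_OLP_width(self, toy_tree, toy_profile):
        mL = populate_template(toy_profile, toy_tree, level_template(toy_tree))
        mP = populate_template(toy_profile, toy_tree, postorder_template(toy_tree))
        X, names, _ = assemble_views(toy_profile, mL, mP, "O+L+P")
        assert X.shape == (1, 3 + 6 + 3)
        assert names[3].startswith("lvl:") and names[9].startswith("post:")

    def test_sample_mismatch_error(self, toy_tree, toy_profile):
        mL = populate_template(toy_profile, toy_tree, level_template(toy_tree))
        mL.sample_ids = ["other"]
        with pytest.raises(ValueError, match="sample-id mismatch"):
            assemble_views(toy_profile, mL, None, "O+L")

    def test_unknown_mode(self, toy_profile):
        with pytest.raises(ValueError, match="unknown view mode"):
            assemble_views(toy_profile, None, None, "O+Q")


class TestReconcileTree:
    def test_prunes_and_appends(self):
        prof = AbundanceProfile(
            ["s"], ["k__B|s__X", "k__B|s__Y"], np.array([[0.5, 0.5]])
        )
        # tree knows X and a stranger Z; Y is missing
        tree = TaxonomyTree.from_newick("((s__X,s__Z)g,(s__W)h)r;")
        with pytest.warns(UserWarning, match="absent from the supplied tree"):
            out = reconcile_tree(tree, prof)
        leaf_ids = {l.id for l in out.leaves()}
        assert leaf_ids == {"k__B|s__X", "k__B|s__Y"}
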