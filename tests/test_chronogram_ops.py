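"""Ultrametricity checks, mean-path smoothing, rescaling and grafting."""

import math

import pytest

from fishtol.chronogram_ops import (
    check_ultrametric,
    graft_clade,
    node_ages,
    rescale_to_age,
    smooth_to_ultrametric,
)
from fishtol.exceptions import (
    LabelCollisionError,
    NegativeStemError,
    NonMonophyleticAttachmentError,
    TreeValidationError,
)
from fishtol.synthetic_data import simulate_backbone, simulate_donor
from fishtol.tree_io import parse_newick


class TestCheckUltrametric:
    def test_cherry_is_ultrametric(self):
        ok, dev = check_ultrametric(parse_newick("(A:1,B:1);"))
        assert ok and dev == 0.0

    def test_unequal_cherry_deviation(self):
        """Leaf depths 1 and 1.2: both deviate 0.1 from the mean depth 1.1."""
        ok, dev = check_ultrametric(parse_newick("(A:1,B:1.2);"), rel_tol=1e-6)
        assert not ok
        assert dev == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_simulated_trees_exactly_ultrametric(self, seed):
        tree = simulate_backbone(40, seed=seed)
        ok, _ = check_ultrametric(tree, rel_tol=1e-9)
        assert ok

    def test_missing_lengths_error(self):
        with pytest.raises(TreeValidationError):
            check_ultrametric(parse_newick("((A:1,B:1),C:2);"))


class TestSmoothing:
    def test_fixed_point_on_ultrametric_input(self):
        tree = simulate_backbone(25, seed=7)
        smoothed = smooth_to_ultrametric(tree)
        before = {frozenset(tree.leafset(n)): a for n, a in node_ages(tree).items()}
        after = {frozenset(smoothed.leafset(n)): a for n, a in node_ages(smoothed).items()}
        for clade, age in before.items():
            assert after[clade] == pytest.approx(age, abs=1e-12)

    def test_hand_worked_example(self):
        """((A:1,B:1):1,C:3): child-averaged root height (2+3)/2 = 2.5; the AB
        ancestor sits at 2.5 * 1/(1+1) = 1.25."""
        smoothed = smooth_to_ultrametric(parse_newick("((A:1,B:1):1,C:3);"))
        ages = node_ages(smoothed)
        by_clade = {smoothed.leafset(n): a for n, a in ages.items()}
        assert by_clade[frozenset("ABC")] == pytest.approx(2.5)
        assert by_clade[frozenset("AB")] == pytest.approx(1.25)
        assert check_ultrametric(smoothed, rel_tol=1e-9)[0]

    def test_ages_monotone_root_to_leaf(self):
        donor, _ = simulate_donor(30, crown_age=80.0, rate_noise_sigma=0.4, seed=3)
        smoothed = smooth_to_ultrametric(donor)
        ages = node_ages(smoothed)
        for nd in smoothed.nodes():
            for ch in nd.child_nodes():
                if ch.edge.length > 0:
                    assert ages[ch] < ages[nd]
                else:
                    assert ages[ch] == pytest.approx(ages[nd])

    def test_idempotent(self):
        donor, _ = simulate_donor(20, crown_age=50.0, rate_noise_sigma=0.3, seed=5)
        once = smooth_to_ultrametric(donor)
        twice = smooth_to_ultrametric(once)
        assert twice.canonical_form() == once.canonical_form()

    def test_topology_preserved(self):
        donor, _ = simulate_donor(20, crown_age=50.0, rate_noise_sigma=0.3, seed=6)
        smoothed = smooth_to_ultrametric(donor)
        orig = {donor.leafset(n) for n in donor.nodes()}
        new = {smoothed.leafset(n) for n in smoothed.nodes()}
        assert orig == new

    def test_recovery_improves_as_noise_shrinks(self):
        """Smoothing + rescaling recovers true node ages; error grows with sigma."""
        rmse = {}
        for sigma in (0.0, 0.3):
            errs = []
            for seed in range(20):
                donor, truth = simulate_donor(
                    25, crown_age=100.0, rate_noise_sigma=sigma, seed=seed
                )
                est = rescale_to_age(smooth_to_ultrametric(donor), 100.0)
                ages = {est.leafset(n): a for n, a in node_ages(est).items()}
                errs.extend(
                    (ages[clade] - true) ** 2
                    for clade, true in truth.items()
                    if len(clade) > 1
                )
            rmse[sigma] = math.sqrt(sum(errs) / len(errs))
        assert rmse[0.0] < 1e-9
        assert rmse[0.3] > rmse[0.0]

    def test_single_leaf_rejected(self):
        with pytest.raises(TreeValidationError):
            smooth_to_ultrametric(parse_newick("A:1;"))


class TestRescale:
    def test_linear_scaling(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        scaled = rescale_to_age(tree, 100.0)
        ages = node_ages(scaled)
        assert max(ages.values()) == pytest.approx(100.0, rel=1e-9)
        ab = scaled.mrca({"A", "B"})
        assert ages[ab] == pytest.approx(50.0, rel=1e-9)

    def test_identity_at_current_height(self):
        tree = simulate_backbone(15, root_age=200.0, seed=2)
        scaled = rescale_to_age(tree, 200.0)
        assert scaled.canonical_form() == tree.canonical_form()

    def test_all_node_ages_scale_by_ratio(self):
        tree = simulate_backbone(30, root_age=300.0, seed=4)
        scaled = rescale_to_age(tree, 150.0)
        before = {tree.leafset(n): a for n, a in node_ages(tree).items()}
        after = {scaled.leafset(n): a for n, a in node_ages(scaled).items()}
        for clade, age in before.items():
            assert after[clade] == pytest.approx(age * 0.5, rel=1e-9)

    def test_composition_collapses(self):
        tree = simulate_backbone(12, seed=9)
        twice = rescale_to_age(rescale_to_age(tree, 77.0), 50.0)
        once = rescale_to_age(tree, 50.0)
        assert twice.canonical_form(9) == once.canonical_form(9)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(TreeValidationError, match="smooth"):
            rescale_to_age(parse_newick("(A:1,B:2);"), 10.0)


class TestGraft:
    def test_hand_constructed_graft(self):
        """Replacing clade {A,B} (crown 10) with a 3-tip donor keeps height 20."""
        backbone = parse_newick("((A:10,B:10):10,C:20);")
        donor = parse_newick("((x:1,y:1):1,z:2);")
        donor = rescale_to_age(donor, 5.0)  # any ultrametric shape works
        out = graft_clade(backbone, {"A", "B"}, donor)  # crown age from backbone
        assert sorted(out.leaf_labels) == ["C", "x", "y", "z"]
        ages = node_ages(out)
        assert max(ages.values()) == pytest.approx(20.0)
        crown = out.mrca({"x", "y", "z"})
        assert ages[crown] == pytest.approx(10.0)
        assert check_ultrametric(out, rel_tol=1e-9)[0]

    def test_grafting_identical_clade_is_identity(self):
        import dendropy

        from fishtol.tree_io import Phylogeny

        backbone = simulate_backbone(20, seed=11)
        clades = [
            n for n in backbone.nodes()
            if not n.is_leaf() and n is not backbone.root
            and len(backbone.leafset(n)) >= 3
        ]
        tips = backbone.leafset(clades[0])
        clone = backbone.copy()
        sub = next(n for n in clone.nodes() if clone.leafset(n) == tips)
        sub.parent_node.remove_child(sub)
        sub.edge.length = None
        donor = Phylogeny(dendropy.Tree(seed_node=sub))
        out = graft_clade(backbone, tips, donor)
        assert out.canonical_form(6) == backbone.canonical_form(6)

    def test_tip_conservation_and_outside_ages_untouched(self):
        backbone = simulate_backbone(30, seed=13)
        clades = [
            n for n in backbone.nodes()
            if not n.is_leaf() and n is not backbone.root
            and 3 <= len(backbone.leafset(n)) <= 10
        ]
        tips = backbone.leafset(clades[0])
        donor, _ = simulate_donor(12, crown_age=10.0, seed=14, label_prefix="N")
        out = graft_clade(backbone, tips, donor)
        expected = (set(backbone.leaf_labels) - tips) | set(donor.leaf_labels)
        assert set(out.leaf_labels) == expected
        # branch structure outside the replaced clade is untouched:
        # root-to-node depths are bit-identical
        bb_depths = backbone.depths()
        before = {backbone.leafset(n): d for n, d in bb_depths.items()}
        out_depths = out.depths()
        donor_tips = set(donor.leaf_labels)
        for n, d in out_depths.items():
            clade = out.leafset(n)
            if clade in before and not (clade & donor_tips):
                assert d == before[clade]

    def test_negative_stem_error_and_squeeze(self):
        backbone = parse_newick("((A:10,B:10):10,C:20);")
        donor, _ = simulate_donor(3, crown_age=10.0, seed=1, label_prefix="n")
        with pytest.raises(NegativeStemError):
            graft_clade(backbone, {"A", "B"}, donor, crown_age=25.0)
        with pytest.warns(UserWarning, match="squeez"):
            out = graft_clade(backbone, {"A", "B"}, donor, crown_age=25.0, squeeze=True)
        ages = node_ages(out)
        crown = out.mrca(set(donor.leaf_labels))
        assert ages[crown] == pytest.approx(0.99 * 20.0)

    def test_non_monophyletic_selector(self):
        backbone = parse_newick("((A:10,B:10):10,(C:10,D:10):10);")
        donor, _ = simulate_donor(3, crown_age=5.0, seed=2, label_prefix="n")
        with pytest.raises(NonMonophyleticAttachmentError) as err:
            graft_clade(backbone, {"A", "C"}, donor)
        assert err.value.displaced == ("B", "D")

    def test_label_collision_rejected(self):
        backbone = parse_newick("((A:10,B:10):10,C:20);")
        donor = rescale_to_age(parse_newick("(C:1,y:1);"), 5.0)
        with pytest.raises(LabelCollisionError):
            graft_clade(backbone, {"A", "B"}, donor)

    def test_named_clade_selector(self):
        backbone = parse_newick("((A:10,B:10)Target:10,C:20);")
        donor, _ = simulate_donor(4, crown_age=8.0, seed=3, label_prefix="n")
        out = graft_clade(backbone, "Target", donor)
        assert set(out.leaf_labels) == {"C"} | set(donor.leaf_labels)

    def test_donor_root_support_kept_else_backbone(self):
        backbone = parse_newick("((A:10,B:10)88:10,C:20);")
        donor = rescale_to_age(parse_newick("(x:1,y:1)77;"), 5.0)
        out = graft_clade(backbone, {"A", "B"}, donor)
        assert out.mrca({"x", "y"}).support == 77.0
        donor2 = rescale_to_age(parse_newick("(p:1,q:1);"), 5.0)
        out2 = graft_clade(backbone, {"A", "B"}, donor2)
        assert out2.mrca({"p", "q"}).support == 88.0
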