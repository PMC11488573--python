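"""Tree parsing, pruning, grafting and patristic distances."""

import numpy as np
import pytest

from nfixdiv import (
    TaxonRecord,
    graft_missing,
    parse_newick,
    patristic_matrix,
    prune_to_taxa,
)
from conftest import dendropy_distances, random_newick


class TestParse:
    def test_worked_example_sizes(self, abc_tree):
        assert abc_tree.n_tips == 3
        assert abc_tree.total_branch_length == pytest.approx(5.0)

    def test_single_tip(self):
        t = parse_newick("(A:1);")
        assert t.tip_labels == ["A"]
        assert t.total_branch_length == pytest.approx(1.0)

    def test_malformed_reports_position(self):
        with pytest.raises(ValueError, match="column"):
            parse_newick("((A:1,B:1:1,C:2);")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            parse_newick("((A,B):1,C:2);")

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            parse_newick("((A:1,B:-1):1,C:2);")

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_whitespace_underscore_equivalent(self):
        t = parse_newick("(('Vicia sepium':1,Vicia_cracca:1):1,C:2);")
        assert t.has_tip("Vicia sepium") and t.has_tip("Vicia_sepium")

    def test_zero_length_branches_preserved(self):
        t = parse_newick("((A:0,B:1):1,C:2);")
        assert t.total_branch_length == pytest.approx(4.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_topology_and_lengths(self, seed):
        rng = np.random.default_rng(seed)
        nwk = random_newick(rng, 50)
        t1 = parse_newick(nwk)
        t2 = parse_newick(t1.to_newick())
        assert set(t1.tip_labels) == set(t2.tip_labels)
        # bipartition-free comparison: all pairwise distances identical
        d1 = t1.patristic_distances()
        d2 = t2.patristic_distances().loc[d1.index, d1.columns]
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-9)


class TestPrune:
    def test_identity(self, abc_tree):
        p = prune_to_taxa(abc_tree, {"A", "B", "C"})
        assert p.total_branch_length == pytest.approx(5.0)

    def test_path_length_preserved(self, abc_tree):
        p = prune_to_taxa(abc_tree, {"A", "C"})
        assert p.patristic_distances().loc["A", "C"] == pytest.approx(4.0)

    def test_unknown_taxon_listed(self, abc_tree):
        with pytest.raises(KeyError, match="X"):
            prune_to_taxa(abc_tree, {"A", "X"})

    @pytest.mark.parametrize("seed", range(8))
    def test_distances_preserved_random(self, seed):
        rng = np.random.default_rng(100 + seed)
        nwk = random_newick(rng, 30)
        tree = parse_newick(nwk)
        keep = sorted(rng.choice(tree.tip_labels, size=12, replace=False))
        pruned = prune_to_taxa(tree, keep)
        oracle = dendropy_distances(nwk)
        got = pruned.patristic_distances()
        for i, a in enumerate(keep):
            for b in keep[i + 1:]:
                assert got.loc[a, b] == pytest.approx(oracle[(a, b)], abs=1e-9)

    def test_total_length_shrinks(self):
        rng = np.random.default_rng(7)
        tree = parse_newick(random_newick(rng, 25))
        sub = prune_to_taxa(tree, tree.tip_labels[:10])
        assert sub.total_branch_length <= tree.total_branch_length + 1e-12


class TestPatristic:
    def test_worked_example(self, abc_tree):
        D = patristic_matrix(abc_tree, ["A", "B", "C"])
        assert D.loc["A", "B"] == pytest.approx(2.0)
        assert D.loc["A", "C"] == pytest.approx(4.0)

    def test_single_taxon_zero(self, abc_tree):
        D = patristic_matrix(abc_tree, ["A"])
        assert D.shape == (1, 1) and D.iloc[0, 0] == 0.0

    def test_empty_errors(self, abc_tree):
        with pytest.raises(ValueError):
            patristic_matrix(abc_tree, [])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        nwk = random_newick(rng, 30)
        tree = parse_newick(nwk)
        D = tree.patristic_distances()
        oracle = dendropy_distances(nwk)
        for (a, b), d in oracle.items():
            assert D.loc[a, b] == pytest.approx(d, abs=1e-9)
        M = D.to_numpy()
        assert np.allclose(M, M.T) and np.allclose(np.diag(M), 0.0)


def _records_for(tree, extra):
    """Trait records covering existing tips plus the extras to graft."""
    recs = []
    for lab in tree.tip_labels:
        g = lab.split("_")[0]
        recs.append(TaxonRecord(lab, g, f"Fam_{g[0]}", False))
    recs.extend(extra)
    return recs


class TestGraft:
    def test_existing_species_noop(self, abc_tree):
        recs = [TaxonRecord("A", "A", "FamA", False)]
        assert graft_missing(abc_tree, recs) is abc_tree

    def test_single_congener_cherry_depth(self):
        # one congeneric tip at depth 100: new tip must come out at depth 100
        tree = parse_newick("(Vicia_cracca:100,Quercus_robur:100);")
        recs = _records_for(
            tree, [TaxonRecord("Vicia_sepium", "Vicia", "Fab", True)]
        )
        out = graft_missing(tree, recs)
        assert out.has_tip("Vicia_sepium")
        assert out.tip_depths()["Vicia_sepium"] == pytest.approx(100.0)
        # cherry: the two congeners are each other's closest relatives
        D = out.patristic_distances()
        assert D.loc["Vicia_sepium", "Vicia_cracca"] == pytest.approx(100.0)

    def test_genus_crown_polytomy(self):
        tree = parse_newick(
            "((Vicia_a:50,Vicia_b:50):50,Quercus_r:100);"
        )
        recs = _records_for(tree, [TaxonRecord("Vicia_c", "Vicia", "Fab", True)])
        out = graft_missing(tree, recs)
        D = out.patristic_distances()
        # attached inside the genus crown: distance to congeners = 100
        assert D.loc["Vicia_c", "Vicia_a"] == pytest.approx(100.0)
        assert D.loc["Vicia_c", "Quercus_r"] == pytest.approx(200.0)

    def test_family_level_fallback(self):
        tree = parse_newick("(Vicia_a:80,Quercus_r:80);")
        recs = _records_for(
            tree, [TaxonRecord("Lathyrus_p", "Lathyrus", "Fam_V", True)]
        )
        out = graft_missing(tree, recs)
        assert out.has_tip("Lathyrus_p")
        assert out.tip_depths()["Lathyrus_p"] == pytest.approx(80.0)

    def test_unplaceable_listed(self):
        tree = parse_newick("(Vicia_a:80,Quercus_r:80);")
        recs = _records_for(
            tree, [TaxonRecord("Poa_annua", "Poa", "Poaceae", False)]
        )
        with pytest.raises(KeyError, match="Poa_annua"):
            graft_missing(tree, recs)

    def test_ultrametricity_preserved_on_simulated_tree(self):
        from nfixdiv import simulate_tree

        tree = simulate_tree(100, 42)
        labs = tree.tip_labels
        genera = {lab: lab.split("_")[0] for lab in labs}
        recs = [
            TaxonRecord(lab, genera[lab], "FamX", False) for lab in labs
        ]
        # invent 10 new congeners of random existing tips
        rng = np.random.default_rng(0)
        for i, anchor in enumerate(rng.choice(labs, size=10, replace=False)):
            recs.append(
                TaxonRecord(f"{genera[anchor]}_new{i}", genera[anchor], "FamX", False)
            )
        out = graft_missing(tree, recs)
        assert out.n_tips == 110
        d = out.tip_depths()
        assert d.max() - d.min() <= 1e-9

    def test_graft_then_prune_roundtrip_exact(self):
        rng = np.random.default_rng(5)
        nwk = random_newick(rng, 20, ultrametric=True)
        tree = parse_newick(nwk)
        labs = tree.tip_labels
        recs = _records_for(
            tree, [TaxonRecord(f"{labs[3].split('_')[0]}_x", labs[3].split("_")[0],
                               f"Fam_{labs[3][0]}", False)]
        )
        grafted = graft_missing(tree, recs)
        back = prune_to_taxa(grafted, labs)
        d0 = tree.patristic_distances()
        d1 = back.patristic_distances().loc[d0.index, d0.columns]
        np.testing.assert_array_equal(d0.to_numpy(), d1.to_numpy())

    def test_order_independent(self):
        tree = parse_newick("((Vicia_a:50,Vicia_b:50):50,Quercus_r:100);")
        new = [
            TaxonRecord("Vicia_c", "Vicia", "Fab", True),
            TaxonRecord("Vicia_d", "Vicia", "Fab", True),
        ]
        recs = _records_for(tree, [])
        out1 = graft_missing(tree, recs + new)
        out2 = graft_missing(tree, recs + new[::-1])
        d1 = out1.patristic_distances()
        d2 = out2.patristic_distances().loc[d1.index, d1.columns]
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-12)
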