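import numpy as np
import pytest

from xspecies_expr.datamodel import ExpressionMatrix
from xspecies_expr.phylo import (
    DistanceMatrix,
    bootstrap_support,
    neighbour_joining,
    pca_with_ellipses,
    spearman_distance,
)

from conftest import make_matrix
from oracles import nj_oracle, random_additive_matrix


def one_tissue_matrix(vals, n_species):
    return make_matrix(vals, species=[f"s{i}" for i in range(n_species)],
                       tissues=("MAG",), is_log=True)


class TestSpearmanDistance:
    def test_identical_profiles_distance_zero(self):
        vals = np.tile(np.arange(1.0, 6.0)[:, None], (1, 3))
        dm = spearman_distance(one_tissue_matrix(vals, 3))
        np.testing.assert_allclose(dm.d, 0.0, atol=1e-12)

    def test_reversed_profiles_distance_two(self):
        vals = np.column_stack([[1, 2, 3], [3, 2, 1], [1, 2, 3]])
        dm = spearman_distance(one_tissue_matrix(vals.astype(float), 3))
        assert dm.d[0, 1] == pytest.approx(2.0)

    def test_hand_computed_rho(self):
        # (1,2,3,4) vs (1,3,2,4): rho = 0.8 -> distance 0.2
        vals = np.column_stack([[1, 2, 3, 4], [1, 3, 2, 4], [4, 3, 2, 1]])
        dm = spearman_distance(one_tissue_matrix(vals.astype(float), 3))
        assert dm.d[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_constant_profile_errors_naming_group(self):
        vals = np.column_stack([[1, 2, 3], [5, 5, 5], [1, 3, 2]])
        with pytest.raises(ValueError, match="s1"):
            spearman_distance(one_tissue_matrix(vals.astype(float), 3))

    def test_invariant_under_monotone_transform_of_one_group(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 10, size=(30, 4))
        base = spearman_distance(one_tissue_matrix(vals, 4))
        t = vals.copy()
        t[:, 2] = np.exp(t[:, 2] / 3.0)  # strictly increasing
        after = spearman_distance(one_tissue_matrix(t, 4))
        np.testing.assert_allclose(base.d, after.d, atol=1e-12)


class TestNeighbourJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbour_joining(DistanceMatrix(["A", "B", "C"], d))
        bl = tree.branch_lengths()
        assert bl[frozenset({"A"})] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert bl[frozenset({"B"})] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert bl[frozenset({"C"})] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_recovers_random_additive_trees_exactly(self, n_taxa):
        rng = np.random.default_rng(10 + n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(10):
            d, true_bips = random_additive_matrix(labels, rng)
            tree = neighbour_joining(DistanceMatrix(labels, d))
            assert tree.bipartitions() == true_bips
            bips, lengths, resid = nj_oracle(labels, d)
            assert resid <= 1e-9
            got = tree.branch_lengths()
            for key, ln in lengths.items():
                assert got[key] == pytest.approx(ln, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B", "C"], d)

    def test_agrees_with_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(6)]
        d, _ = random_additive_matrix(labels, rng)
        ours = neighbour_joining(DistanceMatrix(labels, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        their_bips = set()
        full = frozenset(labels)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            comp = full - side
            if 2 <= len(side) <= len(labels) - 2:
                their_bips.add(side if len(side) < len(comp) else (
                    comp if len(comp) < len(side)
                    else min(side, comp, key=lambda s: tuple(sorted(s)))))
        assert ours.bipartitions() == {frozenset(b) for b in their_bips}


class TestBootstrapSupport:
    def test_consistent_signal_gives_full_support(self, small_sim):
        m, truth, _, _ = small_sim
        from xspecies_expr.datamodel import log_transform

        sub = log_transform(m).subset_tissue("MAG")
        tree = bootstrap_support(sub, ("species",), n_boot=50, seed=0)
        assert set(tree.supports()) == truth.species_tree.bipartitions()

    def test_single_replicate_supports_are_zero_or_hundred(self, small_sim):
        from xspecies_expr.datamodel import log_transform

        sub = log_transform(small_sim[0]).subset_tissue("TESTIS")
        tree = bootstrap_support(sub, ("species",), n_boot=1, seed=3)
        assert set(tree.supports().values()) <= {0, 100}

    def test_requires_positive_n_boot(self, small_sim):
        from xspecies_expr.datamodel import log_transform

        with pytest.raises(ValueError):
            bootstrap_support(log_transform(small_sim[0]), ("species",), n_boot=0, seed=0)


class TestPca:
    def test_two_mirrored_samples_pc1_explains_everything(self):
        vals = np.column_stack([np.arange(10.0), -np.arange(10.0)])
        m = make_matrix(vals, species=["s1"], is_log=True)
        res = pca_with_ellipses(m, group_by=("species",))
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_explained_fractions_non_increasing_and_bounded(self, small_sim):
        from xspecies_expr.datamodel import log_transform

        res = pca_with_ellipses(log_transform(small_sim[0]))
        evf = res.explained_variance_fraction
        assert (np.diff(evf) <= 1e-12).all()
        assert evf.sum() <= 1.0 + 1e-9

    def test_ellipse_radius_matches_chi2_quantile(self, small_sim):
        from xspecies_expr.datamodel import log_transform

        res = pca_with_ellipses(log_transform(small_sim[0]), group_by=("tissue",))
        _, _, radius = next(iter(res.ellipses.values()))
        assert radius == pytest.approx(np.sqrt(5.991), abs=5e-3)

    def test_small_groups_warn_and_omit_ellipse(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.uniform(0, 5, size=(20, 4)), species=["s1", "s2"], is_log=True)
        with pytest.warns(UserWarning, match="ellipse omitted"):
            res = pca_with_ellipses(m, group_by=("species", "tissue"))
        assert res.ellipses == {}
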