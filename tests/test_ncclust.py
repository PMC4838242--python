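"""Discriminant morphospace and dendrogram: oracles and invariances."""

import numpy as np
import pytest
from scipy.linalg import eigh

from nestmorph.io import NestGrouping, group_by_nest
from nestmorph.ncclust import (
    LDScores,
    build_dendrogram,
    fit_nest_lda,
    nest_centroids,
    project_scores,
)
from nestmorph.registry import TRAIT_CODES

from conftest import make_narrow_table, make_table


def _jittered_table(rng, n=12, base=700.0, nests=None):
    traits = np.full((n, 22), base) + rng.normal(0, 1.0, size=(n, 22))
    return make_table(traits, nests=nests)


class TestFitNestLDA:
    def test_single_informative_trait(self, rng):
        # two nests differ only in CL; every other trait constant
        traits = np.full((10, 22), 700.0)
        cl = TRAIT_CODES.index("CL")
        traits[:5, cl] = 600 + rng.normal(0, 1, 5)
        traits[5:, cl] = 800 + rng.normal(0, 1, 5)
        table = make_table(traits, nests=["A"] * 5 + ["B"] * 5)
        model = fit_nest_lda(table, group_by_nest(table))
        lead = model.axis_loadings[:, 0]
        others = np.delete(lead, cl)
        assert abs(lead[cl]) > 1e-3
        assert np.all(np.abs(others) < 1e-8 * abs(lead[cl]))

    def test_matches_brute_force_generalized_eigenproblem(self, rng):
        # 10 specimens, 3 traits, 3 nests
        X = rng.normal(700, 30, size=(10, 3))
        nests = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
        table = make_narrow_table(X, ["CL", "CW", "SL"], nests=nests)
        model = fit_nest_lda(table, group_by_nest(table), regularization="none")
        grand = X.mean(axis=0)
        Sw = np.zeros((3, 3))
        Sb = np.zeros((3, 3))
        for n in ("A", "B", "C"):
            sub = X[[i for i, v in enumerate(nests) if v == n]]
            Sw += (sub - sub.mean(0)).T @ (sub - sub.mean(0))
            d = sub.mean(0) - grand
            Sb += len(sub) * np.outer(d, d)
        evals, evecs = eigh(Sb, Sw)
        order = np.argsort(evals)[::-1]
        for j in range(model.n_axes):
            got = model.axis_loadings[:, j]
            want = evecs[:, order[j]]
            if want[np.argmax(np.abs(want))] < 0:
                want = -want
            np.testing.assert_allclose(got, want, atol=1e-8)
            assert model.eigenvalues[j] == pytest.approx(evals[order[j]], abs=1e-8)

    def test_axis_count_bounded(self, study_dataset):
        table = study_dataset.table
        model = fit_nest_lda(table, group_by_nest(table))
        assert model.n_axes <= 22
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)

    def test_singular_scatter_without_regularization_advises_shrinkage(self):
        # all singleton nests: zero within-nest scatter
        rng = np.random.default_rng(0)
        table = _jittered_table(rng, n=8)
        with pytest.raises(Exception, match="shrink|singular"):
            fit_nest_lda(table, group_by_nest(table), regularization="none")

    def test_duplicated_specimens_in_nest_are_fine(self, rng):
        traits = np.full((6, 22), 700.0) + rng.normal(0, 5, size=(6, 22))
        traits[1] = traits[0]  # exact duplicate pair in nest A
        table = make_table(traits, nests=["A", "A", "B", "B", "C", "C"])
        model = fit_nest_lda(table, group_by_nest(table))
        assert model.n_axes >= 1

    def test_fewer_than_two_nests_errors(self, rng):
        table = _jittered_table(rng, n=4, nests=["A"] * 4)
        with pytest.raises(ValueError):
            fit_nest_lda(table, group_by_nest(table))


class TestProjectScores:
    def test_training_projection_reproduces_group_means(self, rng):
        table = _jittered_table(rng, n=12, nests=list("AABBCCDDEEFF"))
        grouping = group_by_nest(table)
        model = fit_nest_lda(table, grouping)
        scores = project_scores(model, table)
        cents = nest_centroids(scores, grouping)
        for i, nest in enumerate(model.group_ids):
            j = cents.ids.index(nest)
            np.testing.assert_allclose(
                cents.scores[j], model.group_means[i], atol=1e-8
            )

    def test_duplicated_row_gets_identical_scores(self, rng):
        traits = np.full((8, 22), 700.0) + rng.normal(0, 3, size=(8, 22))
        traits[-1] = traits[0]
        table = make_table(traits, nests=list("AABBCCDD"))
        model = fit_nest_lda(table, group_by_nest(table))
        scores = project_scores(model, table)
        np.testing.assert_allclose(scores.scores[0], scores.scores[-1], atol=1e-12)

    def test_matches_hand_matrix_product(self, rng):
        table = _jittered_table(rng, n=10, nests=list("AABBCCDDEE"))
        model = fit_nest_lda(table, group_by_nest(table))
        scores = project_scores(model, table)
        hand = (table.trait_matrix() - model.grand_mean) @ model.axis_loadings
        np.testing.assert_allclose(scores.scores, hand, atol=1e-10)

    def test_trait_mismatch_errors(self, rng):
        table = _jittered_table(rng, n=6, nests=list("AABBCC"))
        model = fit_nest_lda(table, group_by_nest(table))
        object.__setattr__ if False else None
        model.trait_order = tuple(reversed(model.trait_order))
        with pytest.raises(ValueError):
            project_scores(model, table)


class TestNestCentroids:
    def test_singleton_nest_equals_specimen(self):
        scores = LDScores(["a", "b"], np.array([[1.0, 2.0], [3.0, 4.0]]))
        cents = nest_centroids(scores, NestGrouping({"n1": ["a"], "n2": ["b"]}))
        np.testing.assert_array_equal(cents.scores, scores.scores)

    def test_symmetric_pair_centers_at_origin(self):
        scores = LDScores(["a", "b"], np.array([[2.0, -1.0], [-2.0, 1.0]]))
        cents = nest_centroids(scores, NestGrouping({"n": ["a", "b"]}))
        np.testing.assert_allclose(cents.scores, 0.0, atol=1e-15)

    def test_five_member_mean_matches_direct_sum(self, rng):
        vals = rng.normal(size=(5, 3))
        scores = LDScores(list("abcde"), vals)
        cents = nest_centroids(scores, NestGrouping({"n": list("abcde")}))
        np.testing.assert_allclose(cents.scores[0], vals.sum(0) / 5, atol=1e-12)


class TestDendrogram:
    def test_two_leaves_single_merge_height(self):
        cents = LDScores(["a", "b"], np.array([[0.0, 0.0], [3.0, 4.0]]))
        d = build_dendrogram(cents, "average")
        assert d.merges.shape[0] == 1
        assert d.merges[0, 2] == pytest.approx(5.0)  # Euclidean distance

    def test_ward_merge_sequence_hand_computed(self):
        # 4 planar points: two tight pairs far apart
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        cents = LDScores(list("abcd"), pts)
        d = build_dendrogram(cents, "ward")
        heights = sorted(d.merges[:, 2])
        # pair merges at Euclidean distance 1; final Ward merge joins the
        # two pair-centroids at sqrt(2*Δ²) = sqrt(2)*10 with Δ the
        # centroid separation (Ward height for equal-size pairs)
        assert heights[0] == pytest.approx(1.0, abs=1e-10)
        assert heights[1] == pytest.approx(1.0, abs=1e-10)
        assert heights[2] == pytest.approx(np.sqrt(2.0) * 10.0, abs=1e-10)

    def test_leaf_labels_carry_identifier(self, rng):
        table = _jittered_table(rng, n=6, nests=list("ABCDEF"))
        grouping = group_by_nest(table)
        model = fit_nest_lda(table, grouping)
        cents = nest_centroids(project_scores(model, table), grouping)
        d = build_dendrogram(cents, "ward", {n: f"?-{n}" for n in cents.ids})
        assert d.n_leaves == 6
        assert all(lbl == f"?-{leaf}" for leaf, lbl in zip(d.leaves, d.labels))
        assert d.merges.shape[0] == 5

    def test_single_observation_errors(self):
        with pytest.raises(ValueError):
            build_dendrogram(LDScores(["a"], np.array([[1.0]])), "ward")

    def test_newick_roundtrip_topology_and_heights(self, rng):
        dendropy = pytest.importorskip("dendropy")
        pts = rng.normal(size=(7, 3))
        cents = LDScores([f"n{i}" for i in range(7)], pts)
        d = build_dendrogram(cents, "ward")
        tree = dendropy.Tree.get(data=d.newick(), schema="newick")
        assert len(tree.leaf_nodes()) == 7
        # ultrametric: every root-to-leaf path equals the root height
        root_h = d.merges[:, 2].max()
        for leaf in tree.leaf_nodes():
            dist = leaf.distance_from_root()
            assert dist == pytest.approx(root_h, abs=1e-9)


class TestInvariances:
    def test_column_rescaling_leaves_centroid_distances(self, rng):
        table = _jittered_table(rng, n=14, nests=list("AABBCCDDEEFFGG"))
        grouping = group_by_nest(table)

        def dists(t):
            model = fit_nest_lda(t, grouping, regularization="auto")
            cents = nest_centroids(project_scores(model, t), grouping)
            from scipy.spatial.distance import pdist
            return pdist(cents.scores)

        d0 = dists(table)
        scaled = table.data.copy()
        scaled["EL"] = scaled["EL"] * 7.5
        from nestmorph.io import SpecimenTable
        d1 = dists(SpecimenTable(scaled, registry=table.registry))
        np.testing.assert_allclose(d0, d1, atol=1e-6)

    def test_row_permutation_changes_nothing(self, rng):
        table = _jittered_table(rng, n=12, nests=list("AABBCCDDEEFF"))
        grouping = group_by_nest(table)
        model = fit_nest_lda(table, grouping)
        perm = rng.permutation(12)
        from nestmorph.io import SpecimenTable
        shuffled = SpecimenTable(
            table.data.iloc[perm].reset_index(drop=True), registry=table.registry
        )
        model2 = fit_nest_lda(shuffled, group_by_nest(shuffled))
        np.testing.assert_allclose(
            model.axis_loadings, model2.axis_loadings, atol=1e-8
        )
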