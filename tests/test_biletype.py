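"""Ward.D2 linkage against an exhaustive oracle, tree cutting, the biletype
sweep, sub-biletyping, genus co-clustering and cluster-score ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from sklearn.metrics import adjusted_rand_score

from biletyper.biletype import (
    biletype_sweep,
    cluster_score_roc,
    cut_tree,
    genus_coclusters,
    sub_biletype,
    transform_features,
    ward_d2_linkage,
)
from biletyper.data import AbundanceTable, CohortMetadata
from biletyper.markers import auc_mann_whitney, rank_genera_by_auc
from biletyper.simulate import generate_cohort, SyntheticCohortConfig
from tests.conftest import make_metadata
from tests.oracles import ward_oracle


class TestWardLinkage:
    def test_two_samples_merge_at_their_distance(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree = ward_d2_linkage(pts)
        assert tree.merges.shape == (1, 4)
        assert tree.merges[0, 2] == pytest.approx(5.0)

    def test_two_tight_pairs_merge_within_pairs_first(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        tree = ward_d2_linkage(pts)
        first_two = {frozenset(tree.merges[i, :2].astype(int)) for i in range(2)}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_matches_exhaustive_recomputation_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = rng.integers(3, 9)
            pts = rng.normal(size=(n, rng.integers(1, 4)))
            ours = ward_d2_linkage(pts).merges
            oracle = ward_oracle(pts)
            np.testing.assert_array_equal(ours[:, :2], oracle[:, :2])
            np.testing.assert_allclose(ours[:, 2], oracle[:, 2], atol=1e-9)
            np.testing.assert_array_equal(ours[:, 3], oracle[:, 3])

    def test_matches_scipy_ward_heights(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(12, 4))
        ours = ward_d2_linkage(pts).merges
        theirs = scipy_linkage(pts, method="ward")
        np.testing.assert_allclose(np.sort(ours[:, 2]), np.sort(theirs[:, 2]), atol=1e-9)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            pts = rng.normal(size=(rng.integers(3, 15), 3))
            h = ward_d2_linkage(pts).merges[:, 2]
            assert (np.diff(h) >= -1e-12).all()

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ward_d2_linkage(np.zeros((1, 2)))


class TestCutTree:
    def _tree(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1], [20.0]])
        return ward_d2_linkage(pts, leaf_ids=list("abcde"))

    def test_extreme_cuts(self):
        tree = self._tree()
        assert set(cut_tree(tree, 1).values()) == {0}
        assert sorted(cut_tree(tree, 5).values()) == [0, 1, 2, 3, 4]

    def test_two_pairs_instance(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        tree = ward_d2_linkage(pts, leaf_ids=list("abcd"))
        part = cut_tree(tree, 2)
        assert part["a"] == part["b"] != part["c"] == part["d"]

    def test_cuts_are_nested_refinements(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(10, 2))
        tree = ward_d2_linkage(pts)
        for k in range(2, 11):
            coarse = cut_tree(tree, k - 1)
            fine = cut_tree(tree, k)
            # every fine cluster sits inside exactly one coarse cluster
            mapping = {}
            for leaf, c in fine.items():
                mapping.setdefault(c, set()).add(coarse[leaf])
            assert all(len(parents) == 1 for parents in mapping.values())

    def test_out_of_range_k_rejected(self):
        tree = self._tree()
        with pytest.raises(ValueError):
            cut_tree(tree, 6)


class TestBiletypeSweep:
    def test_recovers_planted_case_control_partition(
        self, default_cohort, default_ranking
    ):
        table, records, truth = default_cohort
        res = biletype_sweep(
            table.relative(), records, default_ranking, n_label_permutations=199, seed=2
        )
        assert res.confident
        part = [res.partition[s] for s in table.sample_ids]
        assert adjusted_rand_score(truth.group, part) >= 0.9
        # B is the case-enriched side
        b_groups = [g for g, p in zip(truth.group, part) if p == "B"]
        assert np.mean(np.array(b_groups) == "CCA") > 0.5
        assert res.association["p_value"] <= 0.05

    def test_partitions_ignore_phenotype_labels_given_the_ranking(
        self, default_cohort, default_ranking
    ):
        """With the ranking held fixed, permuting group labels changes the
        association statistics but not a single per-k partition."""
        table, records, _ = default_cohort
        rel = table.relative()
        res = biletype_sweep(rel, records, default_ranking,
                             n_label_permutations=99, seed=0)
        rng = np.random.default_rng(0)
        groups = [r.group for r in records]
        shuffled = list(rng.permutation(groups))
        permuted = [
            CohortMetadata(sample_id=r.sample_id, group=g)
            for r, g in zip(records, shuffled)
        ]
        res_perm = biletype_sweep(rel, permuted, default_ranking,
                                  n_label_permutations=99, seed=0)
        pd.testing.assert_frame_equal(
            res.sweep_trace[["k", "size_0", "size_1"]],
            res_perm.sweep_trace[["k", "size_0", "size_1"]],
        )

    def test_force_k_overrides_the_selection(self, default_cohort, default_ranking):
        table, records, _ = default_cohort
        res = biletype_sweep(
            table.relative(), records, default_ranking,
            n_label_permutations=99, seed=0, force_k=17,
        )
        assert res.chosen_k == 17
        assert len(res.feature_taxa) == 17

    def test_invariant_to_sample_and_taxon_order(self, default_cohort, default_ranking):
        table, records, _ = default_cohort
        rel = table.relative()
        res = biletype_sweep(rel, records, default_ranking,
                             n_label_permutations=99, seed=3)
        rng = np.random.default_rng(1)
        cols = list(rng.permutation(rel.sample_ids))
        rows = list(rng.permutation(rel.taxon_ids))
        shuffled = AbundanceTable(rel.data.loc[rows, cols], kind="relative")
        res2 = biletype_sweep(shuffled, records, default_ranking,
                              n_label_permutations=99, seed=3)
        assert res.chosen_k == res2.chosen_k
        assert res.partition == res2.partition


class TestSubBiletype:
    def test_recovers_aggressive_subgroup(self, default_cohort, default_ranking):
        table, records, truth = default_cohort
        res = biletype_sweep(
            table.relative(), records, default_ranking, n_label_permutations=99, seed=2
        )
        res = sub_biletype(table.relative(), records, res)
        b = res.samples_in("B")
        aggr = dict(zip(truth.sample_ids, truth.aggressive))
        true_sub = ["agg" if aggr[s] else "other" for s in b]
        got = [res.sub_partition[s] for s in b]
        assert adjusted_rand_score(true_sub, got) >= 0.7
        assert res.sub_rule == "advanced_stage_fraction"
        # B1 carries the higher advanced-stage fraction among staged samples
        stages = {r.sample_id: r.advanced_stage for r in records}
        fr = {}
        for lab in ("B1", "B2"):
            staged = [stages[s] for s in b if res.sub_partition[s] == lab
                      and stages[s] is not None]
            fr[lab] = np.mean(staged)
        assert fr["B1"] > fr["B2"]

    def test_without_stage_metadata_falls_back_to_size_rule(
        self, default_cohort, default_ranking
    ):
        table, records, _ = default_cohort
        res = biletype_sweep(
            table.relative(), records, default_ranking, n_label_permutations=99, seed=2
        )
        stripped = [
            CohortMetadata(sample_id=r.sample_id, group=r.group) for r in records
        ]
        res = sub_biletype(table.relative(), stripped, res)
        assert res.sub_rule == "smaller_cluster"
        sizes = pd.Series(res.sub_partition).value_counts()
        assert sizes["B1"] <= sizes["B2"]


class TestGenusCoclusters:
    def test_subsignature_genera_cocluster(self, default_cohort, default_ranking):
        table, records, truth = default_cohort
        res = biletype_sweep(
            table.relative(), records, default_ranking, n_label_permutations=99, seed=2
        )
        res = sub_biletype(table.relative(), records, res)
        b1 = [s for s, v in res.sub_partition.items() if v == "B1"]
        feature_taxa = default_ranking.top(17)
        clusters = genus_coclusters(table.relative(), feature_taxa, b1_samples=b1)
        planted = [t for t in truth.subsignature_taxa if t in feature_taxa]
        counts = pd.Series([clusters[t] for t in planted]).value_counts()
        assert counts.max() >= len(planted) - 1  # at most one stray genus

    def test_two_taxa_two_clusters_are_singletons(self, default_cohort):
        table, _, truth = default_cohort
        taxa = truth.signature_taxa[:2]
        clusters = genus_coclusters(table.relative(), taxa, n_clusters=2)
        assert sorted(clusters.values()) == [1, 2]

    def test_more_clusters_than_taxa_rejected(self, default_cohort):
        table, _, truth = default_cohort
        with pytest.raises(ValueError):
            genus_coclusters(table.relative(), truth.signature_taxa[:2], n_clusters=3)


class TestClusterScoreRoc:
    def _toy(self, values_case, values_ctrl):
        n = len(values_case) + len(values_ctrl)
        df = pd.DataFrame(
            {
                f"s{i}": [v, 1.0]
                for i, v in enumerate(list(values_case) + list(values_ctrl))
            },
            index=["marker", "filler"],
        )
        table = AbundanceTable(df, kind="counts")
        records = make_metadata(
            {f"s{i}": ("CCA" if i < len(values_case) else "BBD") for i in range(n)}
        )
        return table, records

    def test_perfect_separation_gives_auc_one(self):
        table, records = self._toy([50, 60, 70], [1, 2, 3])
        res = cluster_score_roc(table, records, ["marker"], "CCA")
        assert res.auc == 1.0
        assert res.roc.iloc[0]["tpr"] <= res.roc.iloc[-1]["tpr"] == 1.0

    def test_constant_marker_gives_auc_half(self):
        table, records = self._toy([5, 5, 5], [5, 5, 5])
        res = cluster_score_roc(table, records, ["marker"], "CCA")
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_mann_whitney_identity(self, default_cohort):
        table, records, truth = default_cohort
        res = cluster_score_roc(
            table.relative(), records, truth.subsignature_taxa, "CCA"
        )
        groups = np.array([r.group for r in records])
        scores = res.scores.to_numpy()
        expected = auc_mann_whitney(scores[groups == "CCA"], scores[groups == "BBD"])
        assert res.auc == expected

    def test_empty_taxon_set_rejected(self, default_cohort):
        table, records, _ = default_cohort
        with pytest.raises(ValueError):
            cluster_score_roc(table.relative(), records, [], "CCA")
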