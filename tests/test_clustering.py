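"""Ward clustering, elbow selection and cluster profiling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taskrt.clustering import (
    LinkageTree,
    cut_tree,
    elbow_select,
    profile_clusters,
    run_clustering,
    ward_linkage,
)
from taskrt.data_model import ItemMeta, TaskDataset
from taskrt.synthetic import ClusterSpec, GenerativeConfig, generate, inject_clusters, study_like_config


def brute_force_ward(X: np.ndarray) -> np.ndarray:
    """Greedy Ward agglomeration by literally recomputing the total
    within-cluster sum of squares for every candidate merge; heights use
    the Ward.D2 convention sqrt(2 * delta SSE)."""

    def sse(idx: list[int]) -> float:
        pts = X[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters: dict[int, list[int]] = {i: [i] for i in range(len(X))}
    next_id = len(X)
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                delta = sse(clusters[a] + clusters[b]) - sse(clusters[a]) - sse(clusters[b])
                if best is None or delta < best[0] - 1e-13:
                    best = (delta, a, b)
        delta, a, b = best
        merged = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, np.sqrt(2.0 * max(delta, 0.0)), len(merged)))
        clusters[next_id] = merged
        next_id += 1
    return np.array([(m[0], m[1], m[2], m[3]) for m in merges])


class TestWardLinkage:
    def test_two_points_merge_at_their_distance(self):
        X = np.array([[0.0, 0.0], [1.2, 1.6]])
        tree = ward_linkage(X)
        assert tree.merges[0, 2] == pytest.approx(2.0)

    def test_identical_rows_merge_at_zero(self):
        X = np.ones((6, 3))
        tree = ward_linkage(X)
        assert np.allclose(tree.heights(), 0.0)

    @pytest.mark.parametrize("J", [3, 4, 5, 6, 7])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_variance_oracle(self, J, seed):
        """Merge heights agree with the brute-force SSE oracle for all
        small inputs (spec-level equivalence for J <= 7)."""
        rng = np.random.default_rng(100 * J + seed)
        X = rng.normal(size=(J, 3))
        tree = ward_linkage(X)
        oracle = brute_force_ward(X)
        assert np.allclose(np.sort(tree.heights()), np.sort(oracle[:, 2]), atol=1e-9)
        assert np.allclose(tree.heights(), oracle[:, 2], atol=1e-9)

    def test_five_points_in_2d_against_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 2)) * 3
        tree = ward_linkage(X)
        oracle = brute_force_ward(X)
        assert np.allclose(tree.heights(), oracle[:, 2], atol=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(4, 12))
    def test_monotone_merge_heights(self, seed, J):
        """Ward merge heights are non-decreasing on arbitrary inputs."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(J, 4)) * rng.uniform(0.1, 10)
        h = ward_linkage(X).heights()
        assert np.all(np.diff(h) >= -1e-9)

    def test_non_finite_entries_rejected(self):
        X = np.ones((4, 2))
        X[1, 1] = np.nan
        with pytest.raises(ValueError):
            ward_linkage(X)


def _fake_tree(last_heights: list[float], n_leaves: int = 16) -> LinkageTree:
    """A linkage matrix whose final merge heights are as given."""
    n_merges = n_leaves - 1
    heights = np.concatenate(
        [np.linspace(0.0, min(last_heights) / 2, n_merges - len(last_heights)),
         np.sort(last_heights)]
    )
    merges = np.zeros((n_merges, 4))
    merges[:, 2] = heights
    merges[:, 3] = 2
    return LinkageTree(merges=merges, n_leaves=n_leaves)


class TestElbowSelect:
    def test_hand_worked_curvature_example(self):
        """Heights 10, 9, 2, 1.5, 1 for K = 2..6: curvature peaks when 3
        clusters collapse to 2, so K* = 3."""
        tree = _fake_tree([10, 9, 2, 1.5, 1])
        sel = elbow_select(tree, k_max=5)
        assert sel.k == 3
        assert not sel.no_clear_elbow

    def test_linear_decay_warns_and_returns_smallest_k(self):
        tree = _fake_tree([6, 5, 4, 3, 2, 1])
        with pytest.warns(UserWarning, match="no clear elbow"):
            sel = elbow_select(tree, k_max=6)
        assert sel.k == 2
        assert sel.no_clear_elbow

    def test_three_separated_blobs_always_recovered(self):
        """sigma = 0.1 blobs with centers 10 apart: K* = 3 in 50/50 seeds."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
            X = np.vstack([c + 0.1 * rng.standard_normal((15, 2)) for c in centers])
            hits += elbow_select(ward_linkage(X)).k == 3
        assert hits == 50

    def test_requires_enough_leaves(self):
        with pytest.raises(ValueError):
            elbow_select(_fake_tree([3, 2, 1], n_leaves=8), k_max=10)


class TestCutTree:
    def test_single_cluster_and_singletons(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 2))
        tree = ward_linkage(X)
        assert set(cut_tree(tree, 1)) == {1}
        assert sorted(cut_tree(tree, 9)) == list(range(1, 10))

    def test_labels_ordered_by_size(self):
        rng = np.random.default_rng(2)
        X = np.vstack(
            [np.zeros((10, 2)), 20 + np.zeros((3, 2))]
        ) + 0.01 * rng.standard_normal((13, 2))
        labels = cut_tree(ward_linkage(X), 2)
        assert (labels[:10] == 1).all() and (labels[10:] == 2).all()

    def test_permutation_invariance_up_to_relabeling(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(size=(8, 3)), 15 + rng.normal(size=(8, 3))])
        perm = rng.permutation(16)
        l1 = cut_tree(ward_linkage(X), 2)
        l2 = cut_tree(ward_linkage(X[perm]), 2)
        assert adjusted_rand_score(l1[perm], l2) == 1.0

    def test_out_of_range_k(self):
        tree = ward_linkage(np.random.default_rng(4).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, 6)


class TestRecovery:
    def test_planted_study_preset_recovers_three_clusters(self):
        """The 12/222/211 planted timing profiles are found: the elbow
        picks K = 3 and the labels match the truth well."""
        from sklearn.metrics import adjusted_rand_score

        dataset, truth = generate(
            study_like_config(seed=42, covariates=False, clusters=True)
        )
        result = run_clustering(dataset)
        assert result.k == 3
        assert sorted(p.size for p in result.profiles) == sorted(
            np.bincount(truth.cluster_labels)[1:].tolist()
        ) or adjusted_rand_score(truth.cluster_labels, result.labels) > 0.8

    def test_adjusted_rand_recovery_with_unit_offsets(self):
        """Three planted timing profiles whose pairwise log-RT offsets
        exceed 1.0 on every item are recovered with adjusted Rand >= 0.9."""
        from sklearn.metrics import adjusted_rand_score

        dataset, truth = generate(
            study_like_config(seed=302, covariates=False, clusters=True)
        )
        labels = cut_tree(ward_linkage(dataset.T), 3)
        assert adjusted_rand_score(truth.cluster_labels, labels) >= 0.9


class TestProfiles:
    def test_cluster_sizes_sum_to_j(self, study_data):
        dataset, _ = study_data
        result = run_clustering(dataset, k=4)
        assert sum(p.size for p in result.profiles) == dataset.J

    def test_planted_offset_reflected_in_mean_rt(self):
        """A +1.0 log offset on one item raises that cluster's mean RT by
        a factor e within 10%."""
        cfg = GenerativeConfig(J=3000, I=11, seed=14)
        dataset, _ = generate(cfg)
        offsets = [0.0] * 11
        offsets[7] = 1.0
        shifted, labels = inject_clusters(
            dataset, ClusterSpec(proportions=[0.5], offsets=[offsets]), seed=15
        )
        profiles = profile_clusters(shifted, labels)
        by_label = {p.label: p for p in profiles}
        ratio = by_label[1].mean_rt[7] / by_label[0].mean_rt[7]
        assert ratio == pytest.approx(np.e, rel=0.10)

    def test_singleton_cluster_has_undefined_ci(self, tiny_dataset):
        labels = np.array([1, 1, 1, 2])
        profiles = profile_clusters(tiny_dataset, labels)
        assert profiles[1].size == 1
        assert profiles[1].score_ci is None
        assert np.isfinite(profiles[1].mean_task_score)

    def test_slow_cluster_is_slow_and_less_accurate_on_simulation_item(self):
        """In the planted study preset the small slow cluster shows an
        elevated simulation-item mean RT and lower accuracy there."""
        dataset, truth = generate(
            study_like_config(seed=21, covariates=False, clusters=True)
        )
        profiles = profile_clusters(dataset, truth.cluster_labels)
        by_label = {p.label: p for p in profiles}
        slow, fast, moderate = by_label[1], by_label[2], by_label[3]
        assert slow.size == 12
        assert slow.mean_rt[7] > moderate.mean_rt[7] > fast.mean_rt[7]
        assert slow.item_prop_correct[7] < min(
            fast.item_prop_correct[7], moderate.item_prop_correct[7]
        )

    def test_cluster_result_round_trip(self, tmp_path, study_data):
        from taskrt.data_model import load_results, save_results

        dataset, _ = study_data
        result = run_clustering(dataset, k=3)
        loaded = load_results(save_results(result, tmp_path / "clusters.json"))
        assert np.array_equal(loaded.labels, result.labels)
        assert loaded.k == result.k
        assert [p.size for p in loaded.profiles] == [p.size for p in result.profiles]
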