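"""Clustering and explained-variance tests, including exhaustive-search
oracles on tiny frame sets and planted-cohort recovery."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from capdyn.datatypes import ClusterSolution, FramePool, VarianceCurve
from capdyn.extraction import (DegenerateVectorWarning, build_caps,
                               build_variance_curve, cap_spatial_correlation,
                               concatenate_subjects, correlation_distance,
                               explained_variance, kmeans_corr,
                               select_optimal_k)


def make_pool(frames, groups=None):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[0]
    groups = groups if groups is not None else ["WT"] * n
    prov = pd.DataFrame({"subject_id": ["s1"] * n, "group": groups,
                         "frame_index": np.arange(n)})
    return FramePool(frames=frames, provenance=prov)


def brute_force_best_2partition(frames):
    """Exhaustive minimum of the clustering objective over all 2-partitions
    (centroid = member mean, correlation distance)."""
    n = len(frames)
    best = np.inf
    for bits in range(1, 2 ** (n - 1)):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        if mask.all():
            continue
        obj = 0.0
        for part in (mask, ~mask):
            centre = frames[part].mean(axis=0)
            obj += sum(correlation_distance(f, centre) ** 2
                       for f in frames[part])
        best = min(best, obj)
    return best


class TestCorrelationDistance:
    @pytest.mark.parametrize("u, v, expected", [
        ((1, 2, 3), (2, 4, 6), 0.0),
        ((1, 2, 3), (3, 2, 1), 2.0),
        ((1, 0, -1), (0, 1, -1), 0.5),  # hand-computed r = 0.5
    ])
    def test_known_values(self, u, v, expected):
        assert correlation_distance(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gives_neutral_distance(self):
        with pytest.warns(DegenerateVectorWarning):
            assert correlation_distance((1.0, 1.0, 1.0), (1, 2, 3)) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            correlation_distance((1, 2, 3), (1, 2))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.normal(size=(2, 12))
        d = correlation_distance(u, v)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(correlation_distance(v, u), abs=1e-12)


class TestKmeans:
    def test_recovers_two_anticorrelated_groups_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        frames = np.array([base * s + rng.normal(scale=0.05, size=10)
                           for s in (1, 1, 1, 1, -1, -1, -1, -1)])
        sol = kmeans_corr(make_pool(frames), 2, seed=0, n_replicates=5)
        assert len(set(sol.labels[:4])) == 1
        assert len(set(sol.labels[4:])) == 1
        assert sol.labels[0] != sol.labels[4]

    def test_objective_matches_exhaustive_search(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=6)
        frames = np.array([base + rng.normal(scale=0.3, size=6)
                           for _ in range(4)] +
                          [-base + rng.normal(scale=0.3, size=6)
                           for _ in range(4)])
        sol = kmeans_corr(make_pool(frames), 2, seed=0, n_replicates=20)
        best = brute_force_best_2partition(frames)
        assert sol.objective == pytest.approx(best, abs=1e-9)

    def test_k_equals_n_gives_zero_objective(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(6, 8))
        sol = kmeans_corr(make_pool(frames), 6, seed=0, n_replicates=10)
        assert sol.objective < 1e-12
        assert np.array_equal(np.sort(sol.sizes), np.ones(6))

    def test_invalid_k(self):
        pool = make_pool(np.random.default_rng(3).normal(size=(5, 6)))
        with pytest.raises(ValueError):
            kmeans_corr(pool, 6)
        with pytest.raises(ValueError):
            kmeans_corr(pool, 1)

    def test_deterministic_and_ordered_by_size(self):
        rng = np.random.default_rng(4)
        frames = rng.normal(size=(30, 10))
        a = kmeans_corr(make_pool(frames), 3, seed=5)
        b = kmeans_corr(make_pool(frames), 3, seed=5)
        assert np.array_equal(a.labels, b.labels)
        assert np.all(np.diff(a.sizes) <= 0)


class TestExplainedVariance:
    def test_hand_worked_decomposition(self):
        """Frames (1,0,-1),(2,0,-2),(-1,0,1) in clusters {1,2},{3}:
        members correlate perfectly with their centroids (V_w = 0) and the
        two centroids are anti-correlated with the global centroid direction
        for cluster 2 only, giving V_B = (2*0 + 1*4)/3 = 4/3, EV = 1."""
        frames = np.array([[1, 0, -1], [2, 0, -2], [-1, 0, 1]], dtype=float)
        labels = np.array([1, 1, 2])
        centroids = np.array([[1.5, 0, -1.5], [-1, 0, 1]])
        sol = ClusterSolution(k=2, labels=labels, centroids=centroids,
                              sizes=np.array([2, 1]), objective=0.0)
        v_w, v_b, ev = explained_variance(make_pool(frames), sol)
        assert v_w == pytest.approx(0.0, abs=1e-12)
        assert v_b == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert ev == pytest.approx(1.0, abs=1e-12)

    def test_single_cluster_explains_nothing(self):
        rng = np.random.default_rng(5)
        frames = rng.normal(size=(7, 9))
        sol = ClusterSolution(k=1, labels=np.ones(7, dtype=int),
                              centroids=frames.mean(axis=0)[None, :],
                              sizes=np.array([7]), objective=0.0)
        v_w, v_b, ev = explained_variance(make_pool(frames), sol)
        assert v_b == pytest.approx(0.0, abs=1e-12)
        assert ev == pytest.approx(0.0, abs=1e-12)

    def test_singleton_clusters_explain_everything(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(size=(5, 8))
        sol = kmeans_corr(make_pool(frames), 5, seed=0, n_replicates=10)
        _, _, ev = explained_variance(make_pool(frames), sol)
        assert ev == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_bounds_on_random_pools(self, k):
        rng = np.random.default_rng(7)
        pool = make_pool(rng.normal(size=(40, 12)))
        sol = kmeans_corr(pool, k, seed=k)
        v_w, v_b, ev = explained_variance(pool, sol)
        assert v_w >= 0 and v_b >= 0
        assert 0.0 <= ev <= 1.0

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(8)
        pool = make_pool(rng.normal(size=(20, 10)),
                         groups=["WT"] * 10 + ["HET"] * 10)
        sol = kmeans_corr(pool, 3, seed=0)
        perm = np.array([3, 1, 2])  # relabel 1->3, 2->1, 3->2
        permuted = ClusterSolution(
            k=3, labels=perm[sol.labels - 1],
            centroids=sol.centroids[np.argsort(perm)],
            sizes=sol.sizes[np.argsort(perm)], objective=sol.objective)
        _, _, ev_a = explained_variance(pool, sol)
        _, _, ev_b = explained_variance(pool, permuted)
        assert ev_a == pytest.approx(ev_b, abs=1e-12)
        caps_a = {c.combined.tobytes() for c in build_caps(pool, sol)}
        caps_b = {c.combined.tobytes() for c in build_caps(pool, permuted)}
        assert caps_a == caps_b


class TestModelSelection:
    def test_gain_rule_on_synthetic_curve(self):
        ks = np.arange(2, 7)
        ev = np.array([0.20, 0.32, 0.323, 0.325, 0.326])
        curve = VarianceCurve(ks=ks, v_w=1 - ev, v_b=ev,
                              explained_variance=ev,
                              fractional_gain=np.concatenate(
                                  [[np.nan], np.diff(ev)]))
        assert select_optimal_k(curve) == 3
        assert curve.saturated

    def test_differencing(self):
        ev = np.array([0.20, 0.40, 0.52, 0.523, 0.525])
        gains = np.diff(ev)
        assert np.allclose(gains, [0.20, 0.12, 0.003, 0.002], atol=1e-12)

    def test_unsaturated_curve_falls_back_to_k_max(self):
        ks = np.arange(2, 6)
        ev = np.array([0.1, 0.2, 0.3, 0.4])
        curve = VarianceCurve(ks=ks, v_w=1 - ev, v_b=ev,
                              explained_variance=ev,
                              fractional_gain=np.concatenate(
                                  [[np.nan], np.diff(ev)]))
        with pytest.warns(UserWarning, match="did not saturate"):
            assert select_optimal_k(curve) == 5
        assert not curve.saturated

    def test_curve_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        pool = make_pool(rng.normal(size=(40, 10)))
        a = build_variance_curve(pool, 2, 4, seed=1, n_replicates=2)
        b = build_variance_curve(pool, 2, 4, seed=1, n_replicates=2)
        assert np.array_equal(a.explained_variance, b.explained_variance)


class TestCaps:
    def test_identical_frames_give_that_frame(self):
        frame = np.array([1.0, -2.0, 3.0, 0.5])
        pool = make_pool(np.tile(frame, (6, 1)),
                         groups=["WT", "WT", "WT", "HET", "HET", "HET"])
        sol = ClusterSolution(k=1, labels=np.ones(6, dtype=int),
                              centroids=frame[None, :],
                              sizes=np.array([6]), objective=0.0)
        caps = build_caps(pool, sol)
        assert np.allclose(caps[1].combined, frame)

    def test_combined_is_weighted_mean_of_group_maps(self):
        rng = np.random.default_rng(10)
        pool = make_pool(rng.normal(size=(10, 6)),
                         groups=["WT"] * 7 + ["HET"] * 3)
        sol = kmeans_corr(pool, 2, seed=0)
        for cap in build_caps(pool, sol):
            counts = cap.member_counts
            maps = cap.group_maps
            if any(m is None for m in maps.values()):
                continue
            weighted = (counts["WT"] * maps["WT"] +
                        counts["HET"] * maps["HET"]) / sum(counts.values())
            assert np.allclose(cap.combined, weighted, atol=1e-12)

    def test_group_with_no_frames_flagged_missing(self):
        pool = make_pool(np.vstack([np.tile([1., 0., -1.], (3, 1)),
                                    np.tile([-1., 0., 1.], (3, 1))]),
                         groups=["WT"] * 3 + ["HET"] * 3)
        sol = ClusterSolution(k=2, labels=np.array([1, 1, 1, 2, 2, 2]),
                              centroids=np.array([[1., 0., -1.],
                                                  [-1., 0., 1.]]),
                              sizes=np.array([3, 3]), objective=0.0)
        caps = build_caps(pool, sol)
        assert caps[1].group_maps["HET"] is None
        assert caps[1].member_counts["HET"] == 0

    def test_spatial_correlation_endpoints(self):
        rng = np.random.default_rng(11)
        cap = rng.normal(size=20)
        assert cap_spatial_correlation(cap, cap) == pytest.approx(1.0)
        assert cap_spatial_correlation(cap, -cap) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            cap_spatial_correlation(cap, cap, mask=np.zeros(20, dtype=bool))


class TestConcatenation:
    def test_provenance_and_stacking(self, atlas_tiny):
        from capdyn.datatypes import ImageSeries
        rng = np.random.default_rng(12)
        mask = atlas_tiny.brain_mask
        series = [ImageSeries(rng.normal(size=(10, mask.sum())), 0.5, mask,
                              subject_id=f"s{i}", group="WT")
                  for i in range(2)]
        pool = concatenate_subjects(series, atlas_tiny.analysis_mask)
        assert pool.n_frames == 20
        assert list(pool.provenance["subject_id"][:10]) == ["s0"] * 10
        assert list(pool.provenance["frame_index"][:10]) == list(range(10))
        single = concatenate_subjects(series[:1], atlas_tiny.analysis_mask)
        cols = atlas_tiny.analysis_mask[mask]
        assert np.array_equal(single.frames, series[0].data[:, cols])

    def test_mask_mismatch_raises(self, atlas_tiny):
        from capdyn.datatypes import ImageSeries
        rng = np.random.default_rng(13)
        m1 = atlas_tiny.brain_mask
        m2 = m1.copy()
        m2[0, 0, 0] = False
        a = ImageSeries(rng.normal(size=(5, m1.sum())), 0.5, m1, "a", "WT")
        b = ImageSeries(rng.normal(size=(5, m2.sum())), 0.5, m2, "b", "WT")
        with pytest.raises(ValueError, match="mask mismatch"):
            concatenate_subjects([a, b], atlas_tiny.analysis_mask)


class TestPlantedRecovery:
    def test_selected_k_matches_truth(self, recovery_result):
        assert recovery_result["selected_k"] == recovery_result["k_true"]
        ev = recovery_result["curve"].explained_variance
        gains = recovery_result["curve"].fractional_gain
        k_true = recovery_result["k_true"]
        ks = recovery_result["curve"].ks
        assert np.all(gains[ks > k_true] < 0.005)

    def test_frame_labels_recovered(self, recovery_result):
        assert recovery_result["ari"] > 0.9

    def test_caps_match_planted_patterns(self, atlas_small, lownoise_cohort):
        """Noise-free pools: each CAP reproduces its planted pattern to
        spatial correlation > 0.999."""
        from capdyn import generate_cohort, make_model
        model = make_model(atlas_small, k_true=4, n_frames=100,
                           group_sizes=(2, 2), noise_sd=0.0, seed=3)
        cohort = generate_cohort(model, atlas_small, seed=3)
        pool = concatenate_subjects(cohort.subjects,
                                    atlas_small.analysis_mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateVectorWarning)
            sol = kmeans_corr(pool, 4, seed=0, n_replicates=5)
            caps = build_caps(pool, sol)
        sel = atlas_small.analysis_mask[atlas_small.brain_mask]
        patterns = model.patterns[:, sel]
        for cap in caps:
            best = max(cap_spatial_correlation(cap.combined, p)
                       for p in patterns)
            assert best > 0.999

    def test_planted_anticorrelated_pair_detected(self, atlas_small):
        from capdyn.synthetic import make_patterns
        patterns = make_patterns(atlas_small, 4, seed=0)
        sel = atlas_small.analysis_mask[atlas_small.brain_mask]
        r = cap_spatial_correlation(patterns[0, sel], patterns[1, sel])
        assert r <= -0.9
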