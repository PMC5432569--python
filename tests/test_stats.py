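import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from hypolith.errors import ValidationError
from hypolith.io import SiteMetadata
from hypolith.stats import (DissimilarityMatrix, bray_curtis, classical_mds,
                            cluster_groups, dissimilarity_matrix,
                            fit_pc_vs_climate, kruskal_stress, nmds,
                            remove_pc_outliers)
from hypolith.trflp import CommunityProfile


def profile(sid, abundances):
    return CommunityProfile(sample_id=sid, abundances=dict(abundances))


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        a = [0.2, 0.3, 0.5]
        assert bray_curtis(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_one(self):
        assert bray_curtis([1, 0, 0], [0, 0.5, 0.5]) == pytest.approx(1.0)

    def test_half_overlap_hand_value(self):
        assert bray_curtis([0.5, 0.5, 0], [0.5, 0, 0.5]) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            a = rng.uniform(0, 1, size=8)
            b = rng.uniform(0, 1, size=8)
            d = bray_curtis(a, b)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(b, a))

    def test_both_zero_raises(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])


class TestDissimilarityMatrix:
    def test_identical_samples_zero_off_diagonal(self):
        p = {100.0: 0.4, 200.0: 0.6}
        dm = dissimilarity_matrix([profile("a", p), profile("b", p)])
        assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_oracle(self, rng):
        # well-separated shared bins so alignment is the identity
        bins = [100.0, 150.0, 200.0, 250.0]
        profiles = []
        raw = []
        for i in range(3):
            v = rng.dirichlet(np.ones(4))
            raw.append(v)
            profiles.append(profile(f"s{i}", dict(zip(bins, v))))
        dm = dissimilarity_matrix(profiles)
        for i, j in itertools.combinations(range(3), 2):
            expected = 1 - 2 * np.minimum(raw[i], raw[j]).sum() / (
                raw[i].sum() + raw[j].sum())
            assert dm.matrix[i, j] == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self, small_bundle, rng):
        bins = [100.0, 160.0, 220.0]
        profiles = [profile(f"s{i}", dict(zip(bins, rng.dirichlet(np.ones(3)))))
                    for i in range(4)]
        dm = dissimilarity_matrix(profiles)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)

    def test_cross_sample_alignment_merges_nearby_bins(self):
        # 100.0 vs 100.6 are the same fragment seen with size-call error
        dm = dissimilarity_matrix([profile("a", {100.0: 1.0}),
                                   profile("b", {100.6: 1.0})])
        assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_samples_raise(self):
        with pytest.raises(ValidationError):
            dissimilarity_matrix([profile("a", {100.0: 1.0})])


def oracle_upgma_partition(d, cutoff):
    """Brute-force group-average agglomeration, cutting at the first merge
    whose height exceeds the cutoff."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(clusters) > 1:
        (i, j), h = min(dist.items(), key=lambda kv: kv[1])
        if h > cutoff:
            break
        a, b = clusters[i], clusters[j]
        merged = a + b
        new_clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        new_clusters.append(merged)
        clusters = new_clusters
        dist = {}
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                pairs = [d[p, q] for p in clusters[x] for q in clusters[y]]
                dist[(x, y)] = float(np.mean(pairs))
    return {frozenset(c) for c in clusters}


class TestClusterGroups:
    def test_clear_separation(self):
        m = np.array([[0.0, 0.1, 0.9],
                      [0.1, 0.0, 0.9],
                      [0.9, 0.9, 0.0]])
        groups = cluster_groups(DissimilarityMatrix(["A", "B", "C"], m))
        assert groups["A"] == groups["B"] != groups["C"]

    def test_all_distant_all_singletons(self):
        m = np.full((4, 4), 0.9)
        np.fill_diagonal(m, 0.0)
        groups = cluster_groups(DissimilarityMatrix(list("abcd"), m))
        assert len(set(groups.values())) == 4

    def test_matches_brute_force_upgma(self, rng):
        for _ in range(10):
            n = 5
            vec = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
            m = squareform(vec)
            ids = [f"s{i}" for i in range(n)]
            got = cluster_groups(DissimilarityMatrix(ids, m), cutoff=0.40)
            got_partition = {
                frozenset(i for i, s in enumerate(ids) if got[s] == g)
                for g in set(got.values())
            }
            assert got_partition == oracle_upgma_partition(m, 0.40)

    def test_labels_deterministic_by_first_member(self):
        m = np.array([[0.0, 0.9, 0.1],
                      [0.9, 0.0, 0.9],
                      [0.1, 0.9, 0.0]])
        groups = cluster_groups(DissimilarityMatrix(["x", "y", "z"], m))
        assert groups["x"] == 1  # first sample anchors group 1


class TestNMDS:
    def test_embeddable_four_points_near_zero_stress(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.2, 1.1]])
        d = squareform(pdist(pts))
        res = nmds(d, n_starts=4, seed=0)
        assert res.stress < 0.01

    def test_stress_history_non_increasing(self, rng):
        n = 8
        d = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        res = nmds(d, n_starts=5, seed=1)
        assert all(a >= b - 1e-12 for a, b in
                   zip(res.stress_history, res.stress_history[1:]))

    def test_stress_invariant_under_rotation_reflection(self, rng):
        n = 7
        d = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        res = nmds(d, n_starts=3, seed=2)
        dvec = squareform(d, checks=False)
        theta = 1.1
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        flip = np.array([[-1.0, 0.0], [0.0, 1.0]])
        s0 = kruskal_stress(dvec, res.coordinates)
        assert kruskal_stress(dvec, res.coordinates @ rot) == pytest.approx(s0, rel=1e-6)
        assert kruskal_stress(dvec, res.coordinates @ flip) == pytest.approx(s0, rel=1e-6)

    def test_beats_metric_mds_baseline(self, rng):
        for trial in range(3):
            n = 6
            d = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
            res = nmds(d, n_starts=4, seed=trial)
            baseline = kruskal_stress(squareform(d, checks=False),
                                      classical_mds(d, 2))
            assert res.stress <= baseline + 1e-12

    def test_degenerate_matrix_warns_not_converged(self):
        m = np.full((5, 5), 0.5)
        np.fill_diagonal(m, 0.0)
        with pytest.warns(UserWarning, match="degenerate"):
            res = nmds(m, n_starts=2, seed=0)
        assert not res.converged
        assert res.coordinates.shape == (5, 2)

    def test_reproducible_given_seed(self, rng):
        n = 6
        d = squareform(rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))
        r1 = nmds(d, n_starts=4, seed=42)
        r2 = nmds(d, n_starts=4, seed=42)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValidationError):
            nmds(np.zeros((2, 2)), k=2)


class TestOutlierRemoval:
    def test_order_of_magnitude_rule(self):
        pc = {"h1": 2.0, "h2": 2.0, "h3": 2.0, "x": 30.0, "c1": 3.0}
        labels = {"h1": "hot", "h2": "hot", "h3": "hot", "x": "hot",
                  "c1": "cold"}
        retained, excluded = remove_pc_outliers(pc, labels)
        assert excluded == ["x"] and "x" not in retained

    def test_moderate_value_retained(self):
        pc = {"a": 2.0, "b": 2.5, "c": 5.0}
        labels = {"a": "d", "b": "d", "c": "d"}
        _, excluded = remove_pc_outliers(pc, labels)
        assert excluded == []

    def test_all_equal_none_excluded(self):
        pc = {f"s{i}": 1.5 for i in range(6)}
        labels = {f"s{i}": "loc" for i in range(6)}
        _, excluded = remove_pc_outliers(pc, labels)
        assert excluded == []

    def test_sole_location_member_kept(self):
        pc = {"a": 50.0, "b": 2.0, "c": 2.0}
        labels = {"a": "lonely", "b": "d", "c": "d"}
        _, excluded = remove_pc_outliers(pc, labels)
        assert excluded == []

    def test_infinite_pc_always_excluded(self):
        pc = {"a": math.inf, "b": 2.0, "c": 2.0}
        labels = {"a": "d", "b": "d", "c": "d"}
        retained, excluded = remove_pc_outliers(pc, labels)
        assert excluded == ["a"]


def meta(sid, g, mm=100.0, tmin=-10.0, tmax=20.0):
    return SiteMetadata(site_id=sid, koppen="BWk", map_mm=mm, tmin_c=tmin,
                        tmax_c=tmax, growing_season_d=g)


class TestRegression:
    def test_perfect_collinearity(self):
        pc = {f"s{i}": 3.0 - 0.02 * g for i, g in enumerate([0, 20, 40, 60, 80])}
        md = {f"s{i}": meta(f"s{i}", g) for i, g in enumerate([0, 20, 40, 60, 80])}
        fit = fit_pc_vs_climate(pc, md)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-10
        assert fit.slope == pytest.approx(-0.02)

    def test_matches_normal_equation_oracle(self, rng):
        gs = [0.0, 15.0, 33.0, 60.0, 92.0]
        ys = rng.uniform(0.5, 3.0, size=5)
        pc = {f"s{i}": y for i, y in enumerate(ys)}
        md = {f"s{i}": meta(f"s{i}", g) for i, g in enumerate(gs)}
        fit = fit_pc_vs_climate(pc, md)
        x = np.column_stack([np.ones(5), gs])
        beta = np.linalg.solve(x.T @ x, x.T @ ys)
        assert fit.intercept == pytest.approx(beta[0])
        assert fit.slope == pytest.approx(beta[1])
        assert fit.r_squared == pytest.approx(fit.r ** 2, abs=1e-12)

    def test_signed_r_squared_carries_correlation_sign(self):
        gs = [0, 25, 50, 75, 100]
        pc = {f"s{i}": 3.0 - 0.01 * g + 0.001 * i for i, g in enumerate(gs)}
        md = {f"s{i}": meta(f"s{i}", g) for i, g in enumerate(gs)}
        fit = fit_pc_vs_climate(pc, md)
        assert fit.r < 0 and fit.signed_r_squared < 0
        assert abs(fit.signed_r_squared) == pytest.approx(fit.r_squared)

    def test_zero_variance_predictor_raises(self):
        pc = {"a": 1.0, "b": 2.0, "c": 3.0}
        md = {k: meta(k, 50.0) for k in pc}
        with pytest.raises(ValidationError):
            fit_pc_vs_climate(pc, md)

    @pytest.mark.parametrize("predictor", ["map_mm", "tmin_c", "tmax_c"])
    def test_alternative_predictors(self, predictor, rng):
        md = {f"s{i}": meta(f"s{i}", g=10.0 * i, mm=50.0 + 30 * i,
                            tmin=-20.0 + 4 * i, tmax=10.0 + 4 * i)
              for i in range(6)}
        pc = {k: float(v) for k, v in
              zip(md, rng.uniform(0.5, 3.0, size=6))}
        fit = fit_pc_vs_climate(pc, md, predictor=predictor)
        assert fit.predictor == predictor and fit.n == 6
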