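"""Spin permutations, variogram surrogates, and permutation tests."""

import numpy as np
import pytest

from ltcov._rng import child_rng
from ltcov.covariance import CovarianceMatrix
from ltcov.nulls import (
    NullDistribution,
    anova_spin,
    apply_spin_to_matrix,
    correlation_test,
    jsd_similarity,
    smoothed_variogram,
    spin_permutation,
    variogram_surrogates,
    within_between_type_test,
)
from ltcov.surface import VertexMap
from tests.conftest import fibonacci_sphere, sphere_distances


def smooth_sphere_map(rng, D, ell=20.0):
    x = np.exp(-D / ell) @ rng.normal(size=len(D))
    return (x - x.mean()) / x.std()


class TestNullDistribution:
    def test_p_value_convention_never_zero(self):
        nd = NullDistribution(10.0, np.zeros(99), "two-sided")
        assert nd.p_value == pytest.approx(1 / 100)

    def test_two_sided_counts_magnitudes(self):
        nd = NullDistribution(0.5, np.array([-0.6, 0.4, -0.2, 0.55]), "two-sided")
        assert nd.p_value == pytest.approx(3 / 5)

    def test_greater_tail(self):
        nd = NullDistribution(1.0, np.array([0.5, 1.5, 0.9]), "greater")
        assert nd.p_value == pytest.approx(2 / 4)


class TestSpinPermutation:
    def test_rotations_assign_every_parcel(self, centroid_cloud):
        coords, _ = centroid_cloud
        perms = spin_permutation(coords, 20, seed=0)
        assert perms.shape == (20, len(coords))
        assert perms.min() >= 0 and perms.max() < len(coords)

    def test_seed_determinism(self, centroid_cloud):
        coords, _ = centroid_cloud
        assert np.array_equal(spin_permutation(coords, 5, seed=3),
                              spin_permutation(coords, 5, seed=3))

    def test_bijective_variant_is_a_permutation(self, centroid_cloud):
        coords, _ = centroid_cloud
        perms = spin_permutation(coords, 3, seed=1, bijective=True)
        for p in perms:
            assert len(np.unique(p)) == len(coords)

    def test_off_sphere_centroids_rejected(self):
        coords = fibonacci_sphere(50)
        coords[0] *= 1.5
        with pytest.raises(ValueError, match="sphere"):
            spin_permutation(coords, 2)

    def test_spins_preserve_spatial_autocorrelation(self, centroid_cloud):
        coords, D = centroid_cloud
        rng = child_rng(0, "sa")
        x = smooth_sphere_map(rng, D)
        _, g_emp, (pi, pj), which, _ = smoothed_variogram(x, D)
        counts = np.bincount(which)

        def sse(m):
            v = 0.5 * (m[pi] - m[pj]) ** 2
            g = np.bincount(which, weights=v)[counts > 0] / counts[counts > 0]
            return ((g - g_emp) ** 2).sum()

        perms = spin_permutation(coords, 50, seed=2)
        spin_sse = np.mean([sse(x[p]) for p in perms])
        shuffle_sse = np.mean([sse(x[rng.permutation(len(x))]) for _ in range(50)])
        assert spin_sse < 0.5 * shuffle_sse

    def test_matrix_conjugation_preserves_symmetry(self, centroid_cloud):
        coords, D = centroid_cloud
        rng = np.random.default_rng(0)
        m = rng.normal(size=D.shape)
        m = m + m.T
        perm = spin_permutation(coords, 1, seed=0)[0]
        spun = apply_spin_to_matrix(m, perm)
        assert np.allclose(spun, spun.T)


class TestVariogramSurrogates:
    def test_constant_map_gives_near_constant_surrogates(self, centroid_cloud):
        _, D = centroid_cloud
        ens = variogram_surrogates(np.full(len(D), 3.0), D, 10, seed=0)
        assert np.abs(ens.beta).max() < 1e-12
        assert np.allclose(ens.maps.std(axis=1), 0.0, atol=1e-6)

    def test_surrogates_match_variogram_better_than_shuffles(self):
        # dense sampling (300 centroids) with a 40 mm correlation length keeps
        # the empirical variogram well away from the flat shuffle baseline;
        # summarized by the median because the per-map ratio is heavy-tailed
        D = sphere_distances(fibonacci_sphere(300))
        rng = child_rng(1, "vario")
        ratios = []
        for rep in range(20):
            x = smooth_sphere_map(rng, D, ell=40.0)
            ens = variogram_surrogates(x, D, 50, seed=3 + rep)
            _, g_emp, (pi, pj), which, _ = smoothed_variogram(x, D)
            counts = np.bincount(which)

            def sse(m):
                v = 0.5 * (m[pi] - m[pj]) ** 2
                g = np.bincount(which, weights=v)[counts > 0] / counts[counts > 0]
                return ((g - g_emp) ** 2).sum()

            sur = np.mean([sse(m) for m in ens.maps])
            shuf = np.mean([sse(x[rng.permutation(len(x))]) for _ in range(50)])
            ratios.append(sur / shuf)
        assert np.median(ratios) < 0.5

    def test_surrogates_uncorrelated_with_original(self, centroid_cloud):
        _, D = centroid_cloud
        rng = child_rng(2, "vario")
        x = smooth_sphere_map(rng, D, ell=8.0)  # short correlation length
        ens = variogram_surrogates(x, D, 100, seed=4)
        rs = [abs(np.corrcoef(m, x)[0, 1]) for m in ens.maps]
        assert np.mean(rs) < 0.15

    def test_degenerate_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            variogram_surrogates(np.arange(40.0), np.ones((40, 40)), 5)

    def test_seed_determinism(self, centroid_cloud):
        _, D = centroid_cloud
        x = smooth_sphere_map(child_rng(3, "v"), D)
        a = variogram_surrogates(x, D, 8, seed=9)
        b = variogram_surrogates(x, D, 8, seed=9)
        assert np.array_equal(a.maps, b.maps)


class TestCorrelationTest:
    def test_self_correlation_minimal_p(self, centroid_cloud):
        coords, D = centroid_cloud
        x = smooth_sphere_map(child_rng(0, "c"), D)
        nd = correlation_test(x, x, null_source="spin", n_perm=99, seed=0,
                              sphere_coords=coords)
        assert nd.observed == pytest.approx(1.0)
        assert nd.p_value == pytest.approx(1 / 100)

    def test_undefined_edges_excluded_matches_hand_calc(self, centroid_cloud):
        coords, _ = centroid_cloud
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 4))
        x = 0.5 * (x + x.T)
        y = rng.normal(size=(4, 4))
        y = 0.5 * (y + y.T)
        x[3, 1] = x[1, 3] = np.nan  # one undefined edge
        nd = correlation_test(x, y, level="matrix", n_perm=10, seed=0,
                              sphere_coords=fibonacci_sphere(4))
        i, j = np.tril_indices(4, k=-1)
        keep = [k for k in range(6) if not (i[k] == 3 and j[k] == 1)]
        xe, ye = x[i, j][keep], y[i, j][keep]
        expected = np.corrcoef(xe, ye)[0, 1]
        assert nd.observed == pytest.approx(expected, abs=1e-12)
        assert len(keep) == 5

    def test_spearman_variant(self, centroid_cloud):
        coords, D = centroid_cloud
        x = smooth_sphere_map(child_rng(1, "c"), D)
        y = np.exp(2 * x)
        nd = correlation_test(x, y, method="spearman", n_perm=10, seed=0,
                              sphere_coords=coords)
        assert nd.observed == pytest.approx(1.0)

    def test_type_one_error_calibrated_spin(self, centroid_cloud):
        coords, D = centroid_cloud
        perms = spin_permutation(coords, 300, seed=0)
        rng = child_rng(5, "calib")
        rejections = 0
        reps = 100
        for _ in range(reps):
            x = smooth_sphere_map(rng, D)
            y = smooth_sphere_map(rng, D)
            nd = correlation_test(x, y, permutations=perms)
            rejections += nd.p_value <= 0.05
        assert 0.0 <= rejections / reps <= 0.11


class TestAnovaSpin:
    def test_f_matches_textbook_oracle(self, centroid_cloud):
        coords, _ = centroid_cloud
        groups = np.repeat([0, 1, 2], 40)
        values = groups.astype(float) + np.tile([0.0, 0.1, -0.1, 0.05], 30)
        f_null, _ = anova_spin(values, groups, n_perm=20, seed=0,
                               sphere_coords=coords)
        k, n = 3, 120
        means = [values[groups == g].mean() for g in range(3)]
        grand = values.mean()
        ss_between = sum(40 * (m - grand) ** 2 for m in means)
        ss_within = sum(((values[groups == g] - means[g]) ** 2).sum() for g in range(3))
        f_expected = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert f_null.observed == pytest.approx(f_expected, rel=1e-10)

    def test_post_hoc_pair_count_and_bonferroni(self, centroid_cloud):
        coords, D = centroid_cloud
        rng = child_rng(0, "anova")
        values = smooth_sphere_map(rng, D)
        groups = rng.integers(0, 4, size=len(values))
        f_null, post = anova_spin(values, groups, n_perm=30, seed=0,
                                  sphere_coords=coords)
        assert len(post) == 6  # C(4, 2)
        for res in post.values():
            assert res["p_bonferroni"] == pytest.approx(
                min(1.0, res["p_uncorrected"] * 6))

    def test_tiny_group_excluded_with_warning(self, centroid_cloud):
        coords, D = centroid_cloud
        values = smooth_sphere_map(child_rng(1, "anova"), D)
        groups = np.zeros(len(values), dtype=int)
        groups[:60] = 1
        groups[0] = 2  # singleton group
        with pytest.warns(UserWarning, match="fewer than 2"):
            f_null, post = anova_spin(values, groups, n_perm=10, seed=0,
                                      sphere_coords=coords)
        assert len(post) == 1

    def test_calibration_under_null(self, centroid_cloud):
        coords, D = centroid_cloud
        perms = spin_permutation(coords, 200, seed=1)
        rng = child_rng(2, "anova-calib")
        groups = np.repeat(np.arange(4), len(D) // 4)
        rejections = 0
        reps = 60
        for _ in range(reps):
            values = smooth_sphere_map(rng, D)
            f_null, _ = anova_spin(values, groups, permutations=perms)
            rejections += f_null.p_value <= 0.05
        assert rejections / reps <= 0.15


class TestWithinBetweenTypes:
    def test_hand_computed_four_parcel_delta(self, centroid_cloud):
        v = np.array([
            [np.nan, 0.9, 0.1, 0.2],
            [0.9, np.nan, 0.3, 0.4],
            [0.1, 0.3, np.nan, 0.8],
            [0.2, 0.4, np.nan, np.nan],
        ])
        v[3, 2] = 0.8
        labels = np.array(["a", "a", "b", "b"])
        res = within_between_type_test(CovarianceMatrix(v), labels, n_perm=5,
                                       seed=0, sphere_coords=fibonacci_sphere(4))
        between = np.mean([0.1, 0.2, 0.3, 0.4])
        assert res["a"].observed == pytest.approx(0.9 - between)
        assert res["b"].observed == pytest.approx(0.8 - between)
        assert res["overall"].observed == pytest.approx(
            np.mean([0.9, 0.8]) - between)

    def test_block_structure_detected(self, centroid_cloud):
        coords, _ = centroid_cloud
        P = len(coords)
        labels = np.array(["t1"] * (P // 2) + ["t2"] * (P - P // 2))
        same = labels[:, None] == labels[None, :]
        v = np.where(same, 1.0, -1.0) + np.random.default_rng(0).normal(
            scale=0.01, size=(P, P))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, np.nan)
        res = within_between_type_test(CovarianceMatrix(v), labels, n_perm=100,
                                       seed=0, sphere_coords=coords)
        assert res["overall"].observed > 1.5
        assert res["overall"].p_value == pytest.approx(1 / 101)

    def test_single_type_rejected(self, centroid_cloud):
        coords, _ = centroid_cloud
        v = np.zeros((len(coords), len(coords)))
        with pytest.raises(ValueError, match="2 types"):
            within_between_type_test(CovarianceMatrix(v),
                                     np.zeros(len(coords)), sphere_coords=coords)


class TestJsdSimilarity:
    def test_identical_and_disjoint_distributions(self, small_dataset):
        parc = small_dataset["parcellation"]
        V = len(parc.labels)
        # build a map whose values are identical within parcel pairs and
        # disjoint across one particular pair
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, V)
        p0, p1, p2 = parc.included[:3]
        values[parc.members(p0)] = rng.uniform(0, 0.1, len(parc.members(p0)))
        values[parc.members(p1)] = rng.uniform(0.9, 1.0, len(parc.members(p1)))
        values[parc.members(p2)] = values[parc.members(p0)][0]  # degenerate same bin
        sim = jsd_similarity(VertexMap(values), parc, n_bins=16)
        assert sim[p0, p1] == pytest.approx(0.0, abs=1e-12)  # disjoint supports
        assert sim[p0, p0] == 1.0
        assert np.allclose(sim, sim.T, equal_nan=True)

    def test_identical_distributions_similarity_one(self, small_dataset):
        parc = small_dataset["parcellation"]
        values = np.zeros(len(parc.labels))
        # same constant everywhere: every parcel's histogram is identical
        sim = jsd_similarity(VertexMap(values + 0.5), parc, n_bins=8)
        inc = parc.included
        assert np.allclose(sim[np.ix_(inc, inc)], 1.0)

    def test_small_parcels_undefined(self, small_dataset):
        parc = small_dataset["parcellation"]
        rng = np.random.default_rng(1)
        values = rng.normal(size=len(parc.labels))
        mask = np.ones(len(values), dtype=bool)
        p0 = parc.included[0]
        mask[parc.members(p0)[3:]] = False  # leave < 5 valid vertices
        sim = jsd_similarity(VertexMap(values, mask), parc)
        assert np.isnan(sim[p0]).all()
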