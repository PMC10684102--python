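"""Covariance machinery: partial correlation, LTC/MPC/LIC, fusion, homogeneity."""

import numpy as np
import pytest
from scipy.stats import rankdata

from ltcov.covariance import (
    CovarianceMatrix,
    RelativeLaminarMap,
    build_ltc,
    build_profile_covariance,
    fuse_matrices,
    intraregional_homogeneity,
    laminar_intensity,
    profile_partial_correlation,
    relative_thickness,
)
from ltcov.synthetic import IntensityProfileMap, LaminarThicknessMap


def residual_partial_oracle(x, y, z):
    """Independent route: correlation of least-squares residuals on z."""
    def resid(v):
        A = np.column_stack([np.ones_like(z), z])
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    rx, ry = resid(np.asarray(x, float)), resid(np.asarray(y, float))
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestRelativeThickness:
    def test_uniform_layers(self):
        lam = LaminarThicknessMap(np.ones((4, 6)))
        rel = relative_thickness(lam)
        assert np.allclose(rel.fractions, 1 / 6)

    def test_arithmetic(self):
        lam = LaminarThicknessMap(np.array([[0.2, 0.4, 0.6, 0.2, 0.4, 0.2]]))
        rel = relative_thickness(lam)
        assert np.allclose(rel.fractions, [[0.1, 0.2, 0.3, 0.1, 0.2, 0.1]])

    def test_rows_sum_to_one(self, small_dataset):
        rel = relative_thickness(small_dataset["laminar"])
        assert np.allclose(rel.fractions[rel.valid_mask].sum(axis=1), 1.0)


class TestPartialCorrelation:
    def test_identical_profiles(self):
        x = np.array([1.0, 2.0, 5.0, 3.0, 0.5, 4.0])
        z = np.array([2.0, 2.5, 1.0, 4.0, 3.0, 0.0])
        assert profile_partial_correlation(x, x, z) == pytest.approx(1.0)

    def test_negated_profiles(self):
        x = np.array([1.0, 2.0, 5.0, 3.0, 0.5, 4.0])
        z = np.array([2.0, 2.5, 1.0, 4.0, 3.0, 0.0])
        assert profile_partial_correlation(x, -x, z) == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_residual_regression_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 6))
        r = profile_partial_correlation(x, y, z)
        assert r == pytest.approx(residual_partial_oracle(x, y, z), abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            profile_partial_correlation(np.ones(6), np.arange(6.0), np.arange(6.0) ** 2)

    def test_collinear_with_covariate_rejected(self):
        z = np.arange(6.0)
        with pytest.raises(ValueError, match="collinear"):
            profile_partial_correlation(2 * z + 1, np.random.default_rng(0).normal(size=6), z)


class TestBuildLtc:
    def test_matches_elementwise_oracle_on_20_parcels(self):
        rng = np.random.default_rng(42)
        profiles = rng.dirichlet(np.ones(6) * 20, size=20)
        cov = build_ltc(profiles)
        covariate = profiles.mean(axis=0)
        for i in range(20):
            for j in range(i):
                r = residual_partial_oracle(profiles[i], profiles[j], covariate)
                assert cov.values[i, j] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_fisher_z_of_half(self):
        assert np.arctanh(0.5) == pytest.approx(np.log(3) / 2)

    def test_diagonal_undefined(self):
        rng = np.random.default_rng(0)
        cov = build_ltc(rng.dirichlet(np.ones(6), size=10))
        assert np.isnan(np.diag(cov.values)).all()

    def test_identical_profiles_are_maximally_similar(self):
        rng = np.random.default_rng(1)
        profiles = rng.dirichlet(np.ones(6) * 5, size=8)
        profiles[3] = profiles[5]  # a duplicated laminar profile
        cov = build_ltc(profiles)
        off = cov.values[np.isfinite(cov.values)]
        assert cov.values[5, 3] == pytest.approx(off.max())

    def test_symmetry_and_reorder_invariance(self):
        rng = np.random.default_rng(7)
        profiles = rng.dirichlet(np.ones(6) * 10, size=15)
        cov = build_ltc(profiles)
        assert np.allclose(cov.values, cov.values.T, atol=1e-10, equal_nan=True)
        perm = rng.permutation(15)
        cov_p = build_ltc(profiles[perm])
        assert np.allclose(cov_p.values, cov.values[np.ix_(perm, perm)],
                           atol=1e-10, equal_nan=True)

    def test_pearson_and_euclidean_metrics(self):
        rng = np.random.default_rng(3)
        profiles = rng.dirichlet(np.ones(6) * 10, size=12)
        pear = build_ltc(profiles, metric="pearson")
        r = np.corrcoef(profiles)
        assert pear.values[2, 1] == pytest.approx(np.arctanh(r[2, 1]))
        euc = build_ltc(profiles, metric="euclidean")
        assert euc.values[2, 1] == pytest.approx(
            -np.linalg.norm(profiles[2] - profiles[1]))
        assert not euc.fisher_z

    def test_too_few_parcels_rejected(self):
        with pytest.raises(ValueError, match="3"):
            build_ltc(np.random.default_rng(0).dirichlet(np.ones(6), size=2))


class TestProfileCovariance:
    def test_exactly_scaled_profiles_are_collinear_with_covariate(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        scales = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        profiles = scales[:, None] * base[None, :]
        with pytest.raises(ValueError, match="collinear"):
            build_profile_covariance(profiles)

    def test_near_scaled_profiles_maximal_under_pearson(self):
        # under plain correlation, profiles identical up to scale are
        # maximally and uniformly similar; the partial metric instead
        # removes the shared component (their residuals are just noise)
        rng = np.random.default_rng(0)
        base = rng.normal(size=50)
        scales = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        profiles = scales[:, None] * base[None, :] + rng.normal(scale=1e-4, size=(5, 50))
        cov = build_ltc(profiles, metric="pearson")
        off = cov.values[np.isfinite(cov.values)]
        assert (off > np.arctanh(0.999)).all()
        partial = build_profile_covariance(profiles)
        off_p = partial.values[np.isfinite(partial.values)]
        assert np.abs(np.tanh(off_p)).max() < 0.9  # shared part controlled away

    def test_shares_ltc_machinery(self):
        rng = np.random.default_rng(5)
        profiles = rng.normal(size=(10, 50))
        a = build_profile_covariance(profiles)
        b = build_ltc(profiles, metric="partial")
        assert np.allclose(a.values, b.values, equal_nan=True)

    def test_requires_enough_depths(self):
        with pytest.raises(ValueError, match="10"):
            build_profile_covariance(np.random.default_rng(0).normal(size=(5, 4)))


class TestLaminarIntensity:
    def _map(self, profile, depths=None):
        D = profile.shape[1]
        depths = (np.arange(D) + 0.5) / D if depths is None else depths
        return IntensityProfileMap(profile, depths)

    def test_constant_profile(self):
        rel = RelativeLaminarMap(np.full((1, 6), 1 / 6))
        prof = self._map(np.full((1, 50), 2.5))
        out = laminar_intensity(prof, rel)
        assert np.allclose(out, 2.5)

    def test_recovers_piecewise_constant_levels(self):
        levels = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.5])
        fractions = np.array([[0.1, 0.15, 0.25, 0.1, 0.2, 0.2]])
        rel = RelativeLaminarMap(fractions)
        D = 500  # dense depth sampling keeps boundary interpolation error small
        depths = (np.arange(D) + 0.5) / D
        bounds = np.concatenate([[0], np.cumsum(fractions[0])])
        layer = np.clip(np.searchsorted(bounds, depths, side="right") - 1, 0, 5)
        prof = self._map(levels[layer][None, :], depths)
        out = laminar_intensity(prof, rel)
        assert np.allclose(out[0], levels, atol=0.05)

    def test_single_sample_is_midpoint(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=(1, 50))
        rel = RelativeLaminarMap(np.full((1, 6), 1 / 6))
        out = laminar_intensity(self._map(profile), rel, samples_per_layer=1)
        depths = (np.arange(50) + 0.5) / 50
        mid = (np.arange(6) + 0.5) / 6
        expected = np.interp(mid, depths, profile[0])
        assert np.allclose(out[0], expected)


class TestFuseMatrices:
    def _cov(self, values):
        v = np.asarray(values, dtype=float)
        np.fill_diagonal(v, np.nan)
        return CovarianceMatrix(0.5 * (v + v.T), kind="ltc")

    def test_self_fusion_gives_identical_halves(self):
        rng = np.random.default_rng(0)
        m = self._cov(rng.normal(size=(6, 6)))
        fused = fuse_matrices(m, m)
        assert np.allclose(fused[:, :6], fused[:, 6:], equal_nan=True)

    def test_halves_share_value_range(self):
        rng = np.random.default_rng(1)
        a = self._cov(rng.normal(size=(8, 8)))
        b = self._cov(10 + 5 * rng.normal(size=(8, 8)))
        fused = fuse_matrices(a, b)
        left, right = fused[:, :8], fused[:, 8:]
        assert np.nanmin(left) == pytest.approx(np.nanmin(right))
        assert np.nanmax(left) == pytest.approx(np.nanmax(right))

    def test_mismatched_parcels_rejected(self):
        a = self._cov(np.random.default_rng(0).normal(size=(5, 5)))
        b = self._cov(np.random.default_rng(0).normal(size=(6, 6)))
        with pytest.raises(ValueError, match="parcel"):
            fuse_matrices(a, b)

    def test_gradient_of_self_fusion_matches_matrix_gradient(self):
        from scipy.stats import spearmanr

        from ltcov.gradients import GradientEmbedding

        rng = np.random.default_rng(2)
        profiles = rng.dirichlet(np.ones(6) * 10, size=30)
        ltc = build_ltc(profiles)
        fused = fuse_matrices(ltc, ltc)
        g_m = GradientEmbedding(n_components=2, sparsity=0.0).fit(ltc).gradients_
        # rank transform is monotone, so the fused self-embedding must order
        # parcels like the raw-matrix embedding
        ranked = np.full_like(ltc.values, np.nan)
        mask = np.isfinite(ltc.values)
        ranked[mask] = rankdata(ltc.values[mask])
        g_f = GradientEmbedding(n_components=2, sparsity=0.0).fit(ranked).gradients_
        rho = abs(spearmanr(g_m[:, 0], g_f[:, 0]).statistic)
        assert rho > 0.95


class TestIntraregionalHomogeneity:
    def test_hand_computed_two_region_score(self):
        # 4 vertices, regions {0,1} and {2,3}; hand-computed over 6 edges
        v = np.array([
            [np.nan, 0.8, 0.1, 0.2],
            [0.8, np.nan, 0.3, 0.4],
            [0.1, 0.3, np.nan, 0.9],
            [0.2, 0.4, 0.9, np.nan],
        ])
        cov = CovarianceMatrix(v, kind="ltc")
        scores = intraregional_homogeneity(cov, np.array([0, 0, 1, 1]))
        assert scores[0] == pytest.approx(0.8 - np.mean([0.1, 0.2, 0.3, 0.4]))
        assert scores[1] == pytest.approx(0.9 - np.mean([0.1, 0.2, 0.3, 0.4]))

    def test_coherent_region_scores_positive(self):
        rng = np.random.default_rng(0)
        profiles = rng.dirichlet(np.ones(6) * 5, size=30)
        profiles[:10] = profiles[0] + rng.normal(scale=1e-3, size=(10, 6))
        cov = build_ltc(profiles)
        labels = np.repeat([0, 1, 2], 10)
        scores = intraregional_homogeneity(cov, labels)
        assert scores[0] > 0.5

    def test_permuted_labels_score_near_zero_on_average(self):
        rng = np.random.default_rng(1)
        profiles = rng.dirichlet(np.ones(6) * 5, size=24)
        cov = build_ltc(profiles)
        labels = np.repeat([0, 1, 2], 8)
        means = []
        for _ in range(200):
            perm = rng.permutation(24)
            scores = intraregional_homogeneity(cov, labels[perm])
            means.append(np.mean(list(scores.values())))
        spread = np.std(means)
        assert abs(np.mean(means)) < 3 * spread / np.sqrt(len(means)) + 1e-3

    def test_tiny_region_undefined(self):
        v = np.random.default_rng(0).normal(size=(5, 5))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, np.nan)
        scores = intraregional_homogeneity(CovarianceMatrix(v), np.array([0, 0, 0, 0, 1]))
        assert np.isnan(scores[1])
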