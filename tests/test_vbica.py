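import numpy as np
import pytest
from scipy.linalg import subspace_angles

from fdtica import (
    VimConfig,
    VimModel,
    axis_magnitudes,
    compute_elbo,
    feature_matrix,
    fit_vbica_mm,
    init_model,
    responsibilities,
    sample_ica_mixture,
    standardize,
    vb_sweep,
)
from conftest import amari_distance, make_ica_truth


class TestStandardize:
    def test_columns_become_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 2.0, size=(200, 3))
        Z, _ = standardize(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_inverse_round_trip(self):
        from fdtica.vbica import destandardize

        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4)) * [1, 10, 0.1, 3] + [0, -5, 2, 100]
        Z, params = standardize(X)
        assert np.allclose(destandardize(Z, params), X, atol=1e-10)

    def test_zero_variance_column_named(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        X[:, 2] = np.arange(10)
        with pytest.raises(ValueError, match="1"):
            standardize(X)

    def test_default_fdt_pipeline_is_53_dimensional(self, small_cohort):
        X, has_age = feature_matrix(small_cohort)
        assert has_age and X.shape[1] == 53
        Z, _ = standardize(X)
        assert Z.shape[1] == 53


class TestInit:
    def test_different_seeds_differ(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(100, 6))
        m1 = init_model(Z, VimConfig(K=2, L_max=3, seed=0), np.random.default_rng(0))
        m2 = init_model(Z, VimConfig(K=2, L_max=3, seed=1), np.random.default_rng(1))
        assert not np.allclose(m1.clusters[0].m_mu, m2.clusters[0].m_mu)

    def test_single_cluster_mean_is_data_mean(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(80, 5))
        m = init_model(Z, VimConfig(K=1, L_max=2), np.random.default_rng(4))
        assert np.allclose(m.clusters[0].m_mu, Z.mean(axis=0), atol=0.05)

    def test_elbo_finite_at_init(self):
        rng = np.random.default_rng(5)
        Z = rng.normal(size=(60, 5))
        m = init_model(Z, VimConfig(K=2, L_max=2), np.random.default_rng(6))
        assert np.isfinite(compute_elbo(m, Z))

    def test_k_exceeding_n_rejected(self):
        Z = np.random.default_rng(7).normal(size=(4, 5))
        with pytest.raises(ValueError):
            init_model(Z, VimConfig(K=5, L_max=2), np.random.default_rng(0))


def _elbo_monotone(trace, rel=1e-6):
    t = np.asarray(trace)
    return np.all(np.diff(t) >= -rel * np.abs(t[:-1]) - 1e-9)


class TestSweepAndFit:
    @pytest.mark.parametrize("K,L,m,init", [(1, 3, 3, "kmeans"), (2, 2, 1, "kmeans"),
                                            (3, 2, 2, "random")])
    def test_elbo_never_decreases(self, K, L, m, init):
        rng = np.random.default_rng(8)
        truth = make_ica_truth(rng, K=max(K, 1), D=8, L=2,
                               means=[[6 * k] * 8 for k in range(max(K, 1))])
        X, _, _ = sample_ica_mixture(truth, 250, seed=9)
        Z, _ = standardize(X)
        fit = fit_vbica_mm(Z, VimConfig(K=K, L_max=L, m=m, n_iterations=40,
                                        seed=10, init=init))
        assert _elbo_monotone(fit.model.elbo_trace)

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(11)
        Z = rng.normal(size=(120, 6))
        cfg = VimConfig(K=2, L_max=3, m=2, n_iterations=25, seed=42)
        t1 = fit_vbica_mm(Z, cfg).model.elbo_trace
        t2 = fit_vbica_mm(Z, cfg).model.elbo_trace
        assert t1 == t2

    def test_infinite_tolerance_stops_after_one_sweep(self):
        Z = np.random.default_rng(12).normal(size=(60, 5))
        fit = fit_vbica_mm(Z, VimConfig(K=1, L_max=2, n_iterations=100,
                                        convergence_tol=np.inf, seed=0))
        assert fit.converged and fit.n_sweeps_run == 1

    def test_dimension_mismatch_rejected(self):
        Z = np.random.default_rng(13).normal(size=(60, 5))
        model = fit_vbica_mm(Z, VimConfig(K=1, L_max=2, n_iterations=3, seed=0)).model
        with pytest.raises(ValueError):
            vb_sweep(model, Z[:, :4])

    def test_gaussian_source_limit_matches_pca_subspace(self):
        """With m=1 the model is a Bayesian factor analyser: its strong axes
        must span the leading principal subspace."""
        rng = np.random.default_rng(14)
        B = np.linalg.qr(rng.standard_normal((10, 2)))[0]
        X = rng.standard_normal((200, 2)) @ (B * [4.0, 3.0]).T \
            + 0.3 * rng.standard_normal((200, 10))
        fit = fit_vbica_mm(X, VimConfig(K=1, L_max=5, m=1, n_iterations=200, seed=15))
        mags = axis_magnitudes(fit.model, 0)
        top2 = fit.model.clusters[0].mA[:, np.argsort(-mags)[:2]]
        Xc = X - X.mean(axis=0)
        pca2 = np.linalg.svd(Xc, full_matrices=False)[2][:2].T
        assert np.degrees(subspace_angles(top2, pca2)).max() < 5.0

    def test_nongaussian_source_recovery_amari(self):
        rng = np.random.default_rng(16)
        truth = make_ica_truth(rng, K=1, D=6, L=2, mix_scale=3.0, noise_sd=0.3)
        X, _, _ = sample_ica_mixture(truth, 2000, seed=17)
        best = max((fit_vbica_mm(X, VimConfig(K=1, L_max=4, m=3, n_iterations=250,
                                              seed=s)) for s in (0, 1, 2)),
                   key=lambda f: f.final_elbo)
        mags = axis_magnitudes(best.model, 0)
        A2 = best.model.clusters[0].mA[:, np.argsort(-mags)[:2]]
        assert amari_distance(A2, truth.mixing[0]) < 0.15


class TestResponsibilities:
    @pytest.fixture(scope="class")
    @staticmethod
    def two_cluster_fit():
        rng = np.random.default_rng(18)
        truth = make_ica_truth(rng, K=2, D=6, L=2, means=[[0] * 6, [9] * 6])
        X, z, _ = sample_ica_mixture(truth, 400, seed=19)
        Z, std = standardize(X)
        fit = fit_vbica_mm(Z, VimConfig(K=2, L_max=3, m=3, n_iterations=60, seed=20))
        return fit, Z, std, truth

    def test_rows_sum_to_one(self, two_cluster_fit):
        fit, Z, _, _ = two_cluster_fit
        r = responsibilities(fit.model, Z[:50])
        assert np.allclose(r.sum(axis=1), 1.0, atol=1e-10)
        assert np.all((r >= 0) & (r <= 1))

    def test_point_at_cluster_mean_is_confident(self, two_cluster_fit):
        fit, Z, _, _ = two_cluster_fit
        mus = np.stack([c.m_mu for c in fit.model.clusters])
        r = responsibilities(fit.model, mus)
        assert r[0, 0] > 0.99 and r[1, 1] > 0.99

    def test_single_cluster_is_all_ones(self):
        Z = np.random.default_rng(21).normal(size=(50, 4))
        fit = fit_vbica_mm(Z, VimConfig(K=1, L_max=2, n_iterations=5, seed=0))
        r = responsibilities(fit.model, Z)
        assert np.allclose(r, 1.0)


class TestAxisMagnitudes:
    def test_zero_column_scores_zero_and_scaling_doubles(self):
        Z = np.random.default_rng(22).normal(size=(100, 5))
        fit = fit_vbica_mm(Z, VimConfig(K=1, L_max=3, n_iterations=10, seed=1))
        c = fit.model.clusters[0]
        c.mA[:, 0] = 0.0
        mags = axis_magnitudes(fit.model, 0)
        assert mags[0] == 0.0
        c.mA[:, 1] *= 2.0
        assert axis_magnitudes(fit.model, 0)[1] == pytest.approx(2 * mags[1])

    def test_strong_directions_dominate(self):
        rng = np.random.default_rng(23)
        truth = make_ica_truth(rng, K=1, D=10, L=2, mix_scale=4.0, noise_sd=0.2)
        X, _, _ = sample_ica_mixture(truth, 1000, seed=24)
        fit = fit_vbica_mm(X, VimConfig(K=1, L_max=8, m=3, n_iterations=150, seed=2))
        mags = np.sort(axis_magnitudes(fit.model, 0))[::-1]
        assert mags[0] > 5 * mags[2] and mags[1] > 5 * mags[2]


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        Z = np.random.default_rng(25).normal(size=(80, 6))
        fit = fit_vbica_mm(Z, VimConfig(K=2, L_max=3, m=2, n_iterations=15, seed=3))
        fit.model.standardization = {"center": np.zeros(6), "scale": np.ones(6)}
        path = tmp_path / "model.json"
        fit.model.save(path)
        again = VimModel.load(path)
        assert again.config == fit.model.config
        assert again.elbo_trace == fit.model.elbo_trace
        for a, b in zip(fit.model.clusters, again.clusters):
            for name in VimModel._ARRAYS:
                assert np.array_equal(getattr(a, name), getattr(b, name)), name
        assert np.array_equal(again.pi_conc, fit.model.pi_conc)
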